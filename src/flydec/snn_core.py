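"""Clock-driven simulation engine for small leaky integrate-and-fire circuits.

The engine integrates populations of LIF point neurons with forward Euler,
connects them through signed, optionally plastic synapse groups, and records
spikes.  Within each step the order of operations is fixed: integrate
membrane potentials, detect threshold crossings, queue synaptic currents for
the next step, apply plasticity, record.  All quantities are dimensionless
except time, which is in milliseconds.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LIFConfig",
    "STDPConfig",
    "NeuronPopulation",
    "SynapseGroup",
    "SpikeRecord",
    "Network",
    "SimulationError",
    "lif_step",
    "stdp_delta",
]


class SimulationError(RuntimeError):
    """Raised when the simulation reaches an invalid state."""


@dataclass(frozen=True)
class LIFConfig:
    """Leaky integrate-and-fire parameters.

    The membrane obeys ``tau_m dv/dt = -v + R I``; a neuron crossing
    ``v_th`` spikes and is instantaneously reset to ``v_r``.
    """

    v_th: float = 0.1
    v_r: float = 0.0
    tau_m: float = 20.0  # ms
    R: float = 1.0

    def __post_init__(self) -> None:
        if not self.v_th > self.v_r:
            raise ValueError("v_th must exceed v_r")
        if self.tau_m <= 0:
            raise ValueError("tau_m must be positive")
        if self.R <= 0:
            raise ValueError("R must be positive")


@dataclass(frozen=True)
class STDPConfig:
    """Exponential pair-based STDP window parameters."""

    a_plus: float = 0.925
    a_minus: float = 0.9
    tau_plus: float = 20.0  # ms
    tau_minus: float = 20.0  # ms

    def __post_init__(self) -> None:
        for name in ("a_plus", "a_minus", "tau_plus", "tau_minus"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def lif_step(
    v: np.ndarray, cfg: LIFConfig, synaptic_current: np.ndarray, dt: float
) -> tuple[np.ndarray, np.ndarray]:
    """Advance membrane potentials one forward-Euler step.

    Returns ``(v_new, spiked)`` where ``spiked`` is a boolean indicator of
    neurons that crossed threshold; those entries of ``v_new`` are already
    reset to ``v_r``.  Pure function used both by :class:`Network` and by
    closed-form consistency tests.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    i_total = np.asarray(synaptic_current, dtype=float)
    v_new = v + (dt / cfg.tau_m) * (cfg.R * i_total - v)
    # single-reduce finiteness probe: the sum is NaN/Inf iff some element is
    if not math.isfinite(float(v_new.sum())):
        if not np.all(np.isfinite(i_total)):
            raise SimulationError("non-finite input current")
        raise SimulationError("non-finite membrane potential")
    spiked = v_new >= cfg.v_th
    v_new = np.where(spiked, cfg.v_r, v_new)
    return v_new, spiked


def stdp_delta(delta_t: float, cfg: STDPConfig) -> float:
    """Weight change for a pre/post spike pair separated by ``delta_t`` ms.

    ``delta_t > 0`` means the postsynaptic neuron fired after the presynaptic
    one (causal pair) and yields potentiation ``A+ exp(-dt/tau+)``;
    ``delta_t < 0`` yields depression ``-A- exp(-|dt|/tau-)``.  Simultaneous
    spikes (``delta_t == 0``) produce no change; the caller is expected to
    filter them.
    """
    if delta_t > 0:
        return cfg.a_plus * float(np.exp(-delta_t / cfg.tau_plus))
    if delta_t < 0:
        return -cfg.a_minus * float(np.exp(delta_t / cfg.tau_minus))
    return 0.0


class NeuronPopulation:
    """A homogeneous group of LIF neurons.

    ``tie_break=True`` marks winner-take-all readout layers (the two
    behaviour neurons): if several neurons of such a population cross
    threshold on the same step, a single one (chosen uniformly with the
    model RNG) emits the spike and the rest are held below threshold, which
    lets the mutual inhibition established on the next step decide the
    competition instead of leaving two symmetric neurons in lock-step.
    """

    def __init__(self, label: str, size: int, *, tie_break: bool = False):
        if size < 1:
            raise ValueError("population size must be positive")
        self.label = label
        self.size = size
        self.tie_break = tie_break
        self.v = np.zeros(size)
        self.i_ext = np.zeros(size)
        self.i_syn = np.zeros(size)  # queued current, delivered this step
        self.last_spike_time = np.full(size, -np.inf)

    def reset_state(self) -> None:
        self.v[:] = 0.0
        self.i_syn[:] = 0.0
        self.last_spike_time[:] = -np.inf


EXCITATORY = 1
INHIBITORY = -1


class SynapseGroup:
    """Signed connection matrix between two populations.

    ``W`` stores non-negative magnitudes; ``sign`` determines whether
    delivered current is positive (excitatory) or negative (inhibitory).
    ``mask`` restricts connectivity (ones = connected); plastic groups are
    updated by the post-spike-triggered STDP rule and hard-clipped to
    ``[w_min, w_max]`` after every update.
    """

    def __init__(
        self,
        pre: NeuronPopulation,
        post: NeuronPopulation,
        weight: float | np.ndarray,
        *,
        sign: int = EXCITATORY,
        plastic: bool = False,
        stdp: STDPConfig | None = None,
        mask: np.ndarray | None = None,
        w_min: float = 0.0,
        w_max: float = 10.0,
        soft_bounds: bool = False,
    ):
        if sign not in (EXCITATORY, INHIBITORY):
            raise ValueError("sign must be +1 (excitatory) or -1 (inhibitory)")
        self.pre = pre
        self.post = post
        self.sign = sign
        self.plastic = plastic
        self.stdp = stdp if stdp is not None else STDPConfig()
        self.w_min = float(w_min)
        self.w_max = float(w_max)
        self.soft_bounds = bool(soft_bounds)
        self.mask = (
            np.ones((pre.size, post.size))
            if mask is None
            else np.asarray(mask, dtype=float)
        )
        if self.mask.shape != (pre.size, post.size):
            raise ValueError("mask shape mismatch")
        W = np.asarray(weight, dtype=float)
        if W.ndim == 0:
            W = np.full((pre.size, post.size), float(W))
        if W.shape != (pre.size, post.size):
            raise ValueError("weight shape mismatch")
        self.W = np.clip(W, self.w_min, self.w_max) * self.mask

    def clip(self) -> None:
        np.clip(self.W, self.w_min, self.w_max, out=self.W)
        self.W *= self.mask


class SpikeRecord:
    """Spike times per (population label, neuron index)."""

    def __init__(self) -> None:
        self._times: dict[str, list[tuple[float, int]]] = {}

    def add(self, label: str, t: float, indices: np.ndarray) -> None:
        rows = self._times.setdefault(label, [])
        for idx in np.flatnonzero(indices):
            rows.append((t, int(idx)))

    def spikes(self, label: str, neuron: int | None = None) -> list[float]:
        rows = self._times.get(label, [])
        return [t for t, i in rows if neuron is None or i == neuron]

    def counts(self, label: str, size: int) -> np.ndarray:
        out = np.zeros(size, dtype=int)
        for _, i in self._times.get(label, []):
            out[i] += 1
        return out

    def labels(self) -> list[str]:
        return sorted(self._times)

    def n_spikes(self) -> int:
        return sum(len(v) for v in self._times.values())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SpikeRecord):
            return NotImplemented
        return self._times == other._times

    def to_csv(self, path) -> None:
        """One row per spike: time_ms, population, neuron_id."""
        rows = [
            (t, label, i)
            for label, pairs in self._times.items()
            for t, i in pairs
        ]
        rows.sort(key=lambda r: (r[0], r[1], r[2]))
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["time_ms", "population", "neuron_id"])
            w.writerows(rows)


@dataclass
class Network:
    """A set of wired populations stepped on a common clock."""

    lif: LIFConfig = field(default_factory=LIFConfig)
    populations: dict[str, NeuronPopulation] = field(default_factory=dict)
    synapses: list[SynapseGroup] = field(default_factory=list)

    def add_population(self, pop: NeuronPopulation) -> NeuronPopulation:
        if pop.label in self.populations:
            raise ValueError(f"duplicate population label {pop.label!r}")
        self.populations[pop.label] = pop
        return pop

    def connect(self, group: SynapseGroup) -> SynapseGroup:
        for pop in (group.pre, group.post):
            if self.populations.get(pop.label) is not pop:
                raise ValueError(
                    f"synapse references population {pop.label!r} "
                    "not added to the network"
                )
        self.synapses.append(group)
        return group

    def reset_state(self) -> None:
        for pop in self.populations.values():
            pop.reset_state()

    def step(self, t: float, dt: float, rng: np.random.Generator) -> dict[str, np.ndarray]:
        """Advance every population by ``dt``; returns spike indicators.

        ``t`` is the time at the *end* of the step, i.e. spikes detected here
        are stamped ``t``.
        """
        spikes: dict[str, np.ndarray] = {}
        for pop in self.populations.values():
            try:
                v_new, spiked = lif_step(
                    pop.v, self.lif, pop.i_ext + pop.i_syn, dt
                )
            except SimulationError as err:
                raise SimulationError(f"{err} in population {pop.label!r}") from err
            if pop.tie_break and spiked.sum() > 1:
                winners = np.flatnonzero(spiked)
                keep = rng.choice(winners)
                held = spiked.copy()
                held[keep] = False
                # losers are held just below threshold instead of spiking;
                # the winner's mutual inhibition lands next step and decides
                v_new[held] = np.nextafter(self.lif.v_th, -np.inf)
                spiked = np.zeros_like(spiked)
                spiked[keep] = True
            pop.v = v_new
            pop.last_spike_time = np.where(spiked, t, pop.last_spike_time)
            spikes[pop.label] = spiked
        # queue currents for the next step; spikes deliver fixed-charge
        # impulses (current w * 1ms / dt for one step), which equals the
        # one-step pulse of magnitude w at the default dt = 1 ms and keeps
        # synaptic efficacy independent of the integration step
        for pop in self.populations.values():
            pop.i_syn[:] = 0.0
        for g in self.synapses:
            pre_sp = spikes[g.pre.label]
            if pre_sp.any():
                g.post.i_syn += g.sign * (g.W.T @ pre_sp.astype(float)) / dt
        # plasticity: triggered by postsynaptic spikes, each pairing with the
        # most recent presynaptic spike on the synapse (causal branch)
        for g in self.synapses:
            if not g.plastic:
                continue
            post_sp = spikes[g.post.label]
            if not post_sp.any():
                continue
            delta_t = t - g.pre.last_spike_time  # >= 0
            valid = np.isfinite(delta_t) & (delta_t > 0)
            if not valid.any():
                continue
            ltp = np.where(
                valid, g.stdp.a_plus * np.exp(-delta_t / g.stdp.tau_plus), 0.0
            )
            if g.soft_bounds:
                # multiplicative weight dependence: potentiation tapers as
                # the weight approaches its upper bound
                g.W[:, post_sp] += (
                    ltp[:, None] * (1.0 - g.W[:, post_sp] / g.w_max)
                )
            else:
                g.W[:, post_sp] += ltp[:, None]
            g.clip()
        return spikes

    def run(
        self,
        duration: float,
        dt: float,
        rng: np.random.Generator | int | None = None,
        record: list[str] | None = None,
    ) -> SpikeRecord:
        """Run for ``duration`` ms and record spikes.

        Deterministic given the RNG seed: randomness enters only through
        winner-take-all tie breaks.
        """
        if dt <= 0:
            raise ValueError("dt must be positive")
        n_steps = int(round(duration / dt))
        if abs(n_steps * dt - duration) > 1e-9:
            raise ValueError("duration must be a multiple of dt")
        if not isinstance(rng, np.random.Generator):
            rng = np.random.default_rng(rng)
        labels = record if record is not None else list(self.populations)
        rec = SpikeRecord()
        for k in range(n_steps):
            t = (k + 1) * dt
            spikes = self.step(t, dt, rng)
            for label in labels:
                if spikes[label].any():
                    rec.add(label, t, spikes[label])
        return rec
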