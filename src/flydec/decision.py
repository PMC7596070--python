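"""The choice phase: pathway routing, first-spike readout and gain-gating.

A conflict monitor compares the summed memory weights from the active input
channels to the two behaviour neurons.  A clear difference means the fast
linear pathway can decide; otherwise the nonlinear mushroom-body pathway is
engaged, where an externally activated dopamine neuron transiently silences
the APL interneurons (letting both cues through while spike-timing
plasticity imprints their relative saliency onto the visual->KC weights)
and, once the dopamine window closes, APL feedback inhibition suppresses
the weaker cue.  The 2-s choice phase is divided into sub-trials; each
sub-trial's first behaviour spike casts one vote and the preference index
is the normalized vote difference.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .circuits import Model
from .stimulus import VisualPattern, competitive_filter

__all__ = [
    "GatingSchedule",
    "DecisionOutcome",
    "conflict_monitor",
    "preference_index",
    "choose",
    "cue_probabilities",
    "gain_gate",
]


@dataclass(frozen=True)
class GatingSchedule:
    """External dopamine activation at choice onset."""

    da_duration: float = 100.0  # ms
    da_drive: float = 3.0       # external current while active

    def __post_init__(self) -> None:
        if self.da_duration < 0:
            raise ValueError("da_duration must be non-negative")


@dataclass
class DecisionOutcome:
    """Aggregated result of one choice phase."""

    pathway: str                  # "linear" | "nonlinear"
    t1: int
    t2: int
    pi: float
    subtrial_choices: list[int]
    undecided: bool = False      # no spike in any sub-trial

    def to_json(self) -> str:
        return json.dumps({
            "pathway": self.pathway,
            "t1": self.t1,
            "t2": self.t2,
            "pi": self.pi,
            "subtrial_choices": self.subtrial_choices,
            "undecided": self.undecided,
        })


def conflict_monitor(model: Model, filtered_input: np.ndarray) -> str:
    """Route to the linear pathway iff ``|s1 - s2| > th``.

    ``s1``/``s2`` sum the CC memory weights from the active (nonzero)
    filtered channels onto each behaviour neuron; a difference at or below
    the threshold means the linear memory cannot separate the choices and
    the nonlinear pathway is engaged.
    """
    s1, s2 = model.monitor_sums(filtered_input)
    return "linear" if abs(s1 - s2) > model.config.th else "nonlinear"


def preference_index(t1: int, t2: int) -> float:
    """``PI = (t1 - t2) / (t1 + t2)``; +1 = always stay, -1 = always avoid."""
    if t1 + t2 <= 0:
        raise ValueError("preference index undefined without any choice")
    return (t1 - t2) / (t1 + t2)


def choose(
    model: Model,
    current: VisualPattern,
    other: VisualPattern,
    duration: float | None = None,
    schedule: GatingSchedule | None = None,
    rng: np.random.Generator | None = None,
    force_pathway: str | None = None,
) -> DecisionOutcome:
    """Run the choice phase on ``current`` presented against ``other``.

    The phase is split into sub-trials (membrane state reset in between;
    default 20 x 100 ms).  Within each sub-trial the first behaviour spike
    casts the vote.  A silent sub-trial is an indifferent one: indifferent
    sub-trials alternate their votes between the two behaviours (starting
    side drawn once with the RNG), so a fully indifferent phase spends
    equal time on both behaviours and scores PI = 0.  Memory weights are
    frozen; the gating connections of the nonlinear pathway stay plastic
    and the dopamine neuron is driven externally for the first
    ``da_duration`` ms of the phase.
    """
    if rng is None:
        rng = model.rng
    cfg = model.config
    proto = cfg.protocol
    if duration is None:
        duration = proto.choice_duration
    if schedule is None:
        schedule = GatingSchedule(proto.da_duration, proto.da_drive)

    filtered = competitive_filter(current, other)
    pathway = force_pathway or conflict_monitor(model, filtered)
    if pathway not in ("linear", "nonlinear"):
        raise ValueError(f"unknown pathway {pathway!r}")

    if pathway == "linear":
        net, _ = model.linear_network()
    else:
        net, _ = model.nonlinear_network()
    net.populations["visual"].i_ext = proto.input_gain * filtered

    dt = proto.dt_choice
    n_sub = int(round(duration / proto.subtrial))
    steps_per_sub = int(round(proto.subtrial / dt))
    da_pop = net.populations.get("da")
    # phasic DA is triggered by the occurrence of conflicting cues; a fully
    # cancelled (all-zero) input presents no cue and leaves DA silent
    has_input = bool(np.any(filtered > 0))

    votes: list[int] = []
    any_spike = False
    n_silent = 0
    silent_start = int(rng.integers(1, 3))
    t_global = 0.0
    for _ in range(n_sub):
        net.reset_state()
        first: int | None = None
        for _k in range(steps_per_sub):
            t_global += dt
            if da_pop is not None:
                drive_on = (
                    pathway == "nonlinear"
                    and model.da_on
                    and has_input
                    and t_global <= schedule.da_duration
                )
                da_pop.i_ext[:] = schedule.da_drive if drive_on else 0.0
            spikes = net.step(t_global, dt, rng)
            out = spikes["output"]
            if first is None and out.any():
                first = int(np.flatnonzero(out)[0]) + 1
        if first is None:
            # indifferent sub-trial: alternate sides for equal dwell time
            first = 1 + (silent_start + n_silent) % 2
            n_silent += 1
        else:
            any_spike = True
        votes.append(first)

    t1 = votes.count(1)
    t2 = votes.count(2)
    return DecisionOutcome(
        pathway=pathway,
        t1=t1,
        t2=t2,
        pi=preference_index(t1, t2),
        subtrial_choices=votes,
        undecided=not any_spike,
    )


def cue_probabilities(spike_counts) -> np.ndarray:
    """Normalize per-cue spike counts to follow-probabilities
    ``p_i = t_i / sum_j t_j``."""
    t = np.asarray(spike_counts, dtype=float)
    total = t.sum()
    if total <= 0:
        raise ValueError("cue probabilities undefined for all-zero counts")
    if np.any(t < 0):
        raise ValueError("spike counts must be non-negative")
    return t / total


def gain_gate(
    model: Model,
    cues: np.ndarray,
    window: float | None = None,
    schedule: GatingSchedule | None = None,
    rng: np.random.Generator | None = None,
    variant: str = "nonlinear",
) -> np.ndarray:
    """Per-cue spike counts over a fixed window under a circuit variant.

    ``variant`` selects the counting layer and circuit: ``"linear"`` counts
    the CC input layer (plain relay of the visual drive); ``"only-apl"``
    counts KC with APL feedback but no dopamine; ``"nonlinear"`` counts KC
    under the full DA-APL gain-gating loop.  ``cues`` must already be
    normalized to the network input range [1, 20].
    """
    if rng is None:
        rng = model.rng
    cfg = model.config
    proto = cfg.protocol
    if window is None:
        window = proto.gate_window
    if schedule is None:
        schedule = GatingSchedule(proto.da_duration, proto.da_drive)
    cues = np.asarray(cues, dtype=float)

    work = model.copy()
    if work.n_channels != cues.size:
        work = Model(cfg, n_channels=cues.size, seed=model.seed)
    if variant == "linear":
        net, _ = work.linear_network()
        count_label = "cc_input"
    elif variant == "only-apl":
        work.da_on = False
        work.apl_on = True
        net, _ = work.nonlinear_network()
        count_label = "kc"
    elif variant == "nonlinear":
        work.da_on = True
        work.apl_on = True
        net, _ = work.nonlinear_network()
        count_label = "kc"
    else:
        raise ValueError(f"unknown variant {variant!r}")

    net.populations["visual"].i_ext = proto.input_gain * cues
    dt = proto.dt_choice
    n_steps = int(round(window / dt))
    counts = np.zeros(cues.size, dtype=int)
    da_pop = net.populations.get("da")
    for k in range(n_steps):
        t = (k + 1) * dt
        if da_pop is not None:
            drive_on = work.da_on and t <= schedule.da_duration
            da_pop.i_ext[:] = schedule.da_drive if drive_on else 0.0
        spikes = net.step(t, dt, rng)
        counts += spikes[count_label]
    return counts
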