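"""Aversive conditioning: the training phase.

Each visual pattern is presented for one second.  The behaviour neuron that
spikes first fixes the chosen behaviour; choosing to stay with a punished
pattern (behaviour 1) or to leave a safe one (behaviour 2) triggers a
punishment event.  Punishment launches a phasic dopamine trace that decays
exponentially from its peak and, while it lasts, depresses exactly the
feed-forward weights from the currently active input channels onto the
chosen behaviour neuron.  The per-step decrement is ``DA(t) * dt / tau_t``,
so the cumulative depression approximates ``DA_peak`` independently of the
integration step.  Ordinary spike-timing-dependent plasticity runs on the
feed-forward connection throughout, which re-potentiates the surviving
(correct) behaviour within the same episode.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass

import numpy as np

from .circuits import Model
from .stimulus import VisualPattern, competitive_filter

__all__ = ["DATrace", "TrainingEpisode", "da_level", "punish_update",
           "train_pattern", "train_task"]


@dataclass(frozen=True)
class DATrace:
    """Phasic dopamine concentration following a punishment at ``t_pun``."""

    t_pun: float
    peak: float = 10.0
    tau_t: float = 2.0

    def level(self, t: float) -> float:
        return da_level(self, t)


def da_level(trace: DATrace, t: float) -> float:
    """Dopamine concentration ``DA_peak * exp(-(t - t_pun)/tau_t)``."""
    if t < trace.t_pun:
        raise ValueError("dopamine level queried before the punishment time")
    return trace.peak * float(np.exp(-(t - trace.t_pun) / trace.tau_t))


@dataclass
class TrainingEpisode:
    """Outcome of one 1-s presentation of a single pattern."""

    pattern: str
    punished: bool
    chosen_behavior: int  # 1 or 2
    punishment_applied: bool
    t_pun: float | None
    undecided: bool
    s1: float
    s2: float


def _punishment_due(punished: bool, chosen: int) -> bool:
    # staying with a punished pattern, or abandoning a safe one
    return (punished and chosen == 1) or (not punished and chosen == 2)


def punish_update(
    group,
    trace: DATrace | None,
    active: np.ndarray,
    chosen_behavior: int,
    t: float,
    dt: float,
    cutoff: float,
) -> None:
    """One step of dopamine-driven depression on a feed-forward group.

    Decrements the weights from active presynaptic channels onto the chosen
    behaviour neuron by the integral of ``DA(t)/tau_t`` over the step (the
    exact per-step form of the rate ``DA(t) * dt / tau_t``) while the trace
    is above ``cutoff``, so the cumulative decrement approaches ``DA_peak``
    independently of the integration step.  Weights are clipped at their
    lower bound; with no live trace they are unchanged.
    """
    if trace is None:
        return
    if trace.level(t) <= cutoff:
        return
    decrement = trace.level(max(t - dt, trace.t_pun)) - trace.level(t)
    group.W[np.asarray(active, dtype=bool), chosen_behavior - 1] -= decrement
    group.clip()


def train_pattern(
    model: Model,
    pattern: VisualPattern,
    other: VisualPattern,
    punished: bool,
    rng: np.random.Generator | None = None,
) -> TrainingEpisode:
    """Run one training episode and update the model's memory in place.

    The filtered input (competitive subtraction of ``other`` from
    ``pattern``) drives the feed-forward learner; CC and MB apply identical
    updates, so the single simulated matrix is written back to both stores.
    If no behaviour neuron fires within the episode the choice is drawn
    uniformly at random and no plasticity has occurred.
    """
    if rng is None:
        rng = model.rng
    cfg = model.config
    proto = cfg.protocol
    filtered = competitive_filter(pattern, other)
    active = filtered > 0

    net, ff = model.training_network()
    net.populations["visual"].i_ext = proto.input_gain * filtered
    # spontaneous behaviour: the output layer is weakly driven so that some
    # action is always expressed and can be (re-)associated, even when all
    # learned weights onto it have been depressed to the lower bound
    out_pop = net.populations["output"]
    out_pop.i_ext[:] = proto.exploration_drive

    dt = proto.dt_train
    n_steps = int(round(proto.train_duration / dt))
    chosen: int | None = None
    trace: DATrace | None = None
    cutoff = cfg.da.cutoff_frac * cfg.da.peak
    for k in range(n_steps):
        t = (k + 1) * dt
        spikes = net.step(t, dt, rng)
        out = spikes["output"]
        if chosen is None and out.any():
            chosen = int(np.flatnonzero(out)[0]) + 1
            # action selection: the chosen behaviour is executed for the
            # rest of the episode, the alternative is behaviourally
            # suppressed so plasticity binds only the expressed action
            out_pop.i_ext[2 - chosen] = -proto.switch_inhibition
            if _punishment_due(punished, chosen):
                trace = DATrace(t_pun=t, peak=cfg.da.peak, tau_t=cfg.da.tau_t)
                # behavioural switch: the punished action is abandoned and
                # the alternative is expressed instead
                out_pop.i_ext[chosen - 1] = -proto.switch_inhibition
                out_pop.i_ext[2 - chosen] = proto.exploration_drive
        if trace is not None:
            punish_update(ff, trace, active, chosen, t, dt, cutoff)
    undecided = chosen is None
    if undecided:
        chosen = int(rng.integers(1, 3))

    model.W_cc = ff.W.copy()
    model.W_mb = ff.W.copy()
    s1, s2 = model.monitor_sums(filtered)
    return TrainingEpisode(
        pattern=pattern.name,
        punished=punished,
        chosen_behavior=chosen,
        punishment_applied=trace is not None,
        t_pun=trace.t_pun if trace is not None else None,
        undecided=undecided,
        s1=s1,
        s2=s2,
    )


def train_task(
    model: Model,
    safe: VisualPattern,
    punished: VisualPattern,
    epochs: int = 1,
    rng: np.random.Generator | None = None,
    log_path=None,
) -> list[TrainingEpisode]:
    """Alternate 1-s training episodes on the safe and punished patterns.

    With ``epochs=0`` the model is returned unchanged.  Returns the episode
    log; optionally writes it as CSV.
    """
    if epochs < 0:
        raise ValueError("epochs must be non-negative")
    if rng is None:
        rng = model.rng
    episodes: list[TrainingEpisode] = []
    for _ in range(epochs):
        episodes.append(train_pattern(model, safe, punished, False, rng))
        episodes.append(train_pattern(model, punished, safe, True, rng))
    if log_path is not None:
        _write_log(log_path, episodes)
    return episodes


def _write_log(path, episodes: list[TrainingEpisode]) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["episode", "pattern", "chosen_behavior", "punished",
                    "punishment_applied", "t_pun", "s1", "s2"])
        for i, ep in enumerate(episodes):
            w.writerow([i, ep.pattern, ep.chosen_behavior, ep.punished,
                        ep.punishment_applied, ep.t_pun, ep.s1, ep.s2])
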