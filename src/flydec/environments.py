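"""Desk-scale agent tasks exercising the decision circuits.

Three surrogates for the flying-robot applications: a window-crossing grid
task in which two distance cues compete for the next movement axis, a
single-shot obstacle-avoidance task in which four distance cues compete for
the escape direction, and an online reversal-learning loop in which the
safe/punished contingency between two patterns is repeatedly swapped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .circuits import Model, build_model
from .decision import cue_probabilities, gain_gate
from .stimulus import VisualPattern, normalize_cues
from .training import TrainingEpisode, train_pattern

__all__ = [
    "WindowGrid",
    "ObstacleScene",
    "ReversalProtocol",
    "simulate_window",
    "simulate_obstacle",
    "run_reversal",
]

POLICIES = ("nonlinear", "linear", "uniform")
CORNERS = ("upper-left", "upper-right", "lower-left", "lower-right")


@dataclass(frozen=True)
class WindowGrid:
    """Square grid with the goal (window centre) in the middle cell.

    The two cues are the remaining horizontal (``d1``) and vertical
    (``d2``) distances to the goal; the more salient cue is the longer
    remaining axis.
    """

    width: int = 9
    height: int = 9

    def __post_init__(self) -> None:
        if self.width < 3 or self.height < 3:
            raise ValueError("grid must be at least 3x3")
        if self.width % 2 == 0 or self.height % 2 == 0:
            raise ValueError("grid sides must be odd so the centre exists")

    @property
    def goal(self) -> tuple[int, int]:
        return (self.width // 2, self.height // 2)

    def corner(self, name: str) -> tuple[int, int]:
        if name not in CORNERS:
            raise ValueError(f"unknown corner {name!r}")
        x = 0 if "left" in name else self.width - 1
        y = 0 if "upper" in name else self.height - 1
        return (x, y)


@dataclass(frozen=True)
class ObstacleScene:
    """Distances from the obstacle centre to the four borders of the field
    of view, ordered (left, up, right, down)."""

    d1: float
    d2: float
    d3: float
    d4: float

    def __post_init__(self) -> None:
        if min(self.d1, self.d2, self.d3, self.d4) <= 0:
            raise ValueError("all obstacle distances must be positive")

    @property
    def distances(self) -> np.ndarray:
        return np.array([self.d1, self.d2, self.d3, self.d4], dtype=float)


@dataclass(frozen=True)
class ReversalProtocol:
    """Sequence of contingency blocks.

    Each block assigns the punished role to one of the two patterns;
    consecutive blocks must differ (that is what makes them reversals).
    ``blocks[k]`` is the index (0 or 1) of the punished pattern in block k.
    """

    blocks: tuple[int, ...] = (1, 0, 1)

    def __post_init__(self) -> None:
        if not self.blocks:
            raise ValueError("protocol needs at least one block")
        if any(b not in (0, 1) for b in self.blocks):
            raise ValueError("block entries index one of the two patterns")
        for a, b in zip(self.blocks, self.blocks[1:]):
            if a == b:
                raise ValueError("consecutive blocks must differ")


def _policy_probabilities(
    policy: str, live: np.ndarray, model: Model | None,
    rng: np.random.Generator, cache: dict,
) -> np.ndarray:
    """Probability of following each live cue under a policy."""
    if policy == "uniform":
        return np.full(live.size, 1.0 / live.size)
    key = (policy, tuple(np.round(live, 6)))
    if key not in cache:
        cues = normalize_cues(live)
        variant = "nonlinear" if policy == "nonlinear" else "linear"
        counts = gain_gate(model, cues, rng=rng, variant=variant)
        if counts.sum() == 0:
            cache[key] = np.full(live.size, 1.0 / live.size)
        else:
            cache[key] = cue_probabilities(counts)
    return cache[key]


def simulate_window(
    policy: str,
    start: str,
    trials: int = 16,
    rng: np.random.Generator | int | None = None,
    grid: WindowGrid | None = None,
    model: Model | None = None,
) -> float:
    """Mean steps from a corner to the window centre under a policy.

    At each step the movement axis is drawn from the policy's follow
    probabilities over the live cues (axes with remaining distance zero are
    dead and excluded); the agent then moves one cell toward the goal along
    the drawn axis.  Every step reduces the Manhattan distance by one, so
    the step count is bounded below by the Manhattan distance.
    """
    if policy not in POLICIES:
        raise ValueError(f"unknown policy {policy!r}; expected {POLICIES}")
    if trials < 1:
        raise ValueError("trials must be positive")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    if grid is None:
        grid = WindowGrid()
    if model is None and policy != "uniform":
        model = build_model()
    gx, gy = grid.goal
    x0, y0 = grid.corner(start)
    cache: dict = {}
    totals = []
    for _ in range(trials):
        x, y = x0, y0
        steps = 0
        while (x, y) != (gx, gy):
            d1, d2 = abs(gx - x), abs(gy - y)  # horizontal, vertical
            live_axes = [i for i, d in enumerate((d1, d2)) if d > 0]
            if len(live_axes) == 1:
                axis = live_axes[0]
            else:
                p = _policy_probabilities(
                    policy, np.array([d1, d2], float), model, rng, cache
                )
                axis = int(rng.choice(2, p=p))
            if axis == 0:
                x += np.sign(gx - x)
            else:
                y += np.sign(gy - y)
            steps += 1
        totals.append(steps)
    return float(np.mean(totals))


def simulate_obstacle(
    scene: ObstacleScene,
    variant: str = "nonlinear",
    rng: np.random.Generator | int | None = None,
    model: Model | None = None,
) -> np.ndarray:
    """Follow-probabilities over the four escape directions.

    Normalizes the four distances into the network input range, counts the
    per-cue spikes under the requested circuit variant and converts the
    counts to probabilities.  The nonlinear variant concentrates probability
    on the most salient (largest-distance) cue.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    if model is None:
        model = build_model()
    cues = normalize_cues(scene.distances)
    counts = gain_gate(model, cues, rng=rng, variant=variant)
    return cue_probabilities(counts)


def run_reversal(
    model: Model,
    patterns: tuple[VisualPattern, VisualPattern],
    protocol: ReversalProtocol,
    rng: np.random.Generator | None = None,
    max_episodes_per_block: int = 20,
) -> list[dict]:
    """Online learning across contingency blocks.

    Within each block the two patterns are presented alternately with live
    training updates; a pattern's incorrect choices are counted until it has
    been answered correctly twice in a row.  Returns one record per block
    with the per-pattern incorrect-choice counts.
    """
    if rng is None:
        rng = model.rng
    results = []
    for block_idx, punished_idx in enumerate(protocol.blocks):
        incorrect = [0, 0]
        streak = [0, 0]
        episodes = 0
        while min(streak) < 2 and episodes < max_episodes_per_block:
            for idx in (0, 1):
                if streak[idx] >= 2 and min(streak) >= 2:
                    continue
                pattern = patterns[idx]
                other = patterns[1 - idx]
                punished = idx == punished_idx
                ep: TrainingEpisode = train_pattern(
                    model, pattern, other, punished, rng
                )
                correct_behavior = 2 if punished else 1
                if ep.chosen_behavior == correct_behavior:
                    streak[idx] += 1
                else:
                    streak[idx] = 0
                    incorrect[idx] += 1
                episodes += 1
        results.append({
            "block": block_idx,
            "punished_pattern": patterns[punished_idx].name,
            "incorrect": tuple(incorrect),
            "episodes": episodes,
            "converged": min(streak) >= 2,
        })
    return results
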