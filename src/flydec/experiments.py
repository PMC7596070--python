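"""Named, seeded reproductions of the behavioural experiments.

Each experiment trains and/or probes the model under a published protocol
and returns tidy per-seed results (a pandas DataFrame) plus a JSON-ready
summary.  ``run_experiment`` writes both to disk; re-running with the same
spec reproduces identical files.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .circuits import Model, ModelConfig, build_model, set_nonlinear_gating
from .decision import GatingSchedule, choose, cue_probabilities, gain_gate
from .environments import (
    CORNERS,
    ObstacleScene,
    ReversalProtocol,
    run_reversal,
    simulate_obstacle,
    simulate_window,
)
from .stimulus import encode, normalize_cues, pattern_library, write_pattern_csv
from .training import train_task

__all__ = ["ExperimentSpec", "EXPERIMENTS", "run_experiment",
           "generate_fixtures"]

log = logging.getLogger("flydec")

CONFLICT_CI_GRID = [round(0.1 * k, 1) for k in range(1, 21)]   # 0.1 .. 2.0
CI_GRID = [round(0.1 * k, 1) for k in range(0, 11)]            # 0.0 .. 1.0
DA_DURATIONS = (10.0, 70.0, 100.0, 300.0, 1000.0)


@dataclass(frozen=True)
class ExperimentSpec:
    """A named experiment with its seed and output directory."""

    name: str
    seed: int = 0
    out_dir: str | Path = "results"
    n_seeds: int = 10
    config: ModelConfig = field(default_factory=ModelConfig)

    def __post_init__(self) -> None:
        if self.name not in EXPERIMENTS:
            raise ValueError(
                f"unknown experiment {self.name!r}; valid names: "
                f"{sorted(EXPERIMENTS)}"
            )


def _seeds(spec: ExperimentSpec) -> list[int]:
    # derive per-repeat seeds deterministically from the spec seed
    return [spec.seed * 1000 + k for k in range(spec.n_seeds)]


def _trained_model(config: ModelConfig, seed: int, ci: float = 1.0) -> Model:
    model = build_model(config, seed=seed)
    train_task(model, encode("green", "upright", ci),
               encode("blue", "inverted", ci), epochs=1)
    return model


def _reversed_cue_choice(model, ci: float, force_pathway=None, schedule=None):
    """The shape-colour dilemma test: reversed pairings, current input
    upright-blue T."""
    current = encode("blue", "upright", ci)
    other = encode("green", "inverted", ci)
    return choose(model, current, other, force_pathway=force_pathway,
                  schedule=schedule)


# --- individual experiments -------------------------------------------------

def exp_single_cue(spec: ExperimentSpec) -> pd.DataFrame:
    """Colour conditioning: green safe, blue punished; choice on each."""
    rows = []
    for seed in _seeds(spec):
        model = build_model(spec.config, seed=seed)
        green = encode("green", "upright", 1.0)
        blue = encode("blue", "upright", 1.0)
        train_task(model, green, blue, epochs=1)
        for name, cur, oth in (("safe", green, blue), ("punished", blue, green)):
            out = choose(model, cur, oth)
            rows.append({"seed": seed, "test": name, "pattern": cur.name,
                         "pathway": out.pathway, "pi": out.pi})
    return pd.DataFrame(rows)


def exp_two_cue(spec: ExperimentSpec) -> pd.DataFrame:
    """Two-cue conditioning followed by single-cue colour and shape tests."""
    rows = []
    for seed in _seeds(spec):
        model = _trained_model(spec.config, seed)
        tests = {
            "color_safe": (encode("green", "upright"), encode("blue", "upright")),
            "color_punished": (encode("blue", "upright"), encode("green", "upright")),
            "shape_safe": (encode("white", "upright"), encode("white", "inverted")),
            "shape_punished": (encode("white", "inverted"), encode("white", "upright")),
        }
        for test, (cur, oth) in tests.items():
            out = choose(model, cur, oth)
            rows.append({"seed": seed, "test": test, "pathway": out.pathway,
                         "pi": out.pi})
    return pd.DataFrame(rows)


def exp_ci_shape_sweep(spec: ExperimentSpec) -> pd.DataFrame:
    """Shape test after two-cue training at each CI in [0, 1]."""
    rows = []
    for seed in _seeds(spec):
        for ci in CI_GRID:
            model = _trained_model(spec.config, seed, ci)
            out = choose(model, encode("white", "upright"),
                         encode("white", "inverted"))
            rows.append({"seed": seed, "ci": ci, "pathway": out.pathway,
                         "pi": out.pi})
    return pd.DataFrame(rows)


def exp_ci_color_sweep(spec: ExperimentSpec) -> pd.DataFrame:
    """Colour test after two-cue training at each CI in [0, 1]."""
    rows = []
    for seed in _seeds(spec):
        for ci in CI_GRID:
            model = _trained_model(spec.config, seed, ci)
            out = choose(model, encode("green", "upright", ci),
                         encode("blue", "upright", ci))
            rows.append({"seed": seed, "ci": ci, "pathway": out.pathway,
                         "pi": out.pi})
    return pd.DataFrame(rows)


def exp_conflict_sweep(spec: ExperimentSpec,
                       ci_grid=None) -> pd.DataFrame:
    """Reversed-cue dilemma over CI in [0.1, 2]: untrained network, trained
    linear pathway and trained nonlinear pathway."""
    if ci_grid is None:
        ci_grid = CONFLICT_CI_GRID
    rows = []
    for seed in _seeds(spec):
        trained = _trained_model(spec.config, seed, ci=0.8)
        untrained = build_model(spec.config, seed=seed)
        for ci in ci_grid:
            for condition, model, pathway in (
                ("untrained", untrained, None),
                ("linear", trained, "linear"),
                ("nonlinear", trained, "nonlinear"),
            ):
                out = _reversed_cue_choice(model.copy(), ci,
                                           force_pathway=pathway)
                rows.append({"seed": seed, "ci": ci, "condition": condition,
                             "pi": out.pi})
    return pd.DataFrame(rows)


def exp_ablation_da_apl(spec: ExperimentSpec, ci_grid=None) -> pd.DataFrame:
    """Conflict sweep under DA/APL ablations of the nonlinear pathway."""
    if ci_grid is None:
        ci_grid = CONFLICT_CI_GRID
    variants = {
        "full": (True, True),
        "only_apl": (False, True),
        "no_da_no_apl": (False, False),
    }
    rows = []
    for seed in _seeds(spec):
        trained = _trained_model(spec.config, seed, ci=0.8)
        for ci in ci_grid:
            for label, (da_on, apl_on) in variants.items():
                variant = set_nonlinear_gating(trained, da_on, apl_on)
                out = _reversed_cue_choice(variant, ci,
                                           force_pathway="nonlinear")
                rows.append({"seed": seed, "ci": ci, "variant": label,
                             "pi": out.pi})
    return pd.DataFrame(rows)


def exp_da_duration_sweep(spec: ExperimentSpec, ci_grid=(0.8, 0.9, 1.2),
                          durations=DA_DURATIONS) -> pd.DataFrame:
    """Decision quality of the nonlinear pathway for different durations of
    the external dopamine activation."""
    rows = []
    for seed in _seeds(spec):
        trained = _trained_model(spec.config, seed, ci=0.8)
        for dur in durations:
            schedule = GatingSchedule(
                da_duration=dur, da_drive=spec.config.protocol.da_drive
            )
            for ci in ci_grid:
                out = _reversed_cue_choice(trained.copy(), ci,
                                           force_pathway="nonlinear",
                                           schedule=schedule)
                rows.append({"seed": seed, "da_duration": dur, "ci": ci,
                             "pi": out.pi})
    return pd.DataFrame(rows)


def exp_spike_train_compare(spec: ExperimentSpec,
                            cues=(9.0, 10.0)) -> pd.DataFrame:
    """Per-cue spike counts for two nearby cues under the three circuit
    variants (counting layer: CC input for linear, KC otherwise)."""
    rows = []
    norm = normalize_cues(cues)
    for seed in _seeds(spec):
        model = build_model(spec.config, seed=seed)
        for variant in ("linear", "only-apl", "nonlinear"):
            counts = gain_gate(model, norm,
                               rng=np.random.default_rng(seed), variant=variant)
            for i, c in enumerate(counts):
                rows.append({"seed": seed, "variant": variant, "cue": i,
                             "raw": cues[i], "count": int(c)})
    return pd.DataFrame(rows)


def exp_reversal(spec: ExperimentSpec) -> pd.DataFrame:
    """Online reversal learning over a two-reversal protocol."""
    protocol = ReversalProtocol(blocks=(1, 0, 1))
    rows = []
    for seed in _seeds(spec):
        model = build_model(spec.config, seed=seed)
        patterns = (encode("green", "upright"), encode("blue", "inverted"))
        records = run_reversal(model, patterns, protocol)
        for rec in records:
            for idx, pat in enumerate(patterns):
                rows.append({
                    "seed": seed, "block": rec["block"], "pattern": pat.name,
                    "incorrect": rec["incorrect"][idx],
                    "converged": rec["converged"],
                })
    return pd.DataFrame(rows)


def exp_window_task(spec: ExperimentSpec, trials: int = 16) -> pd.DataFrame:
    """Mean steps to the window centre from each corner per policy."""
    rows = []
    for seed in _seeds(spec):
        model = build_model(spec.config, seed=seed)
        for policy in ("nonlinear", "linear", "uniform"):
            for corner in CORNERS:
                mean_steps = simulate_window(
                    policy, corner, trials=trials,
                    rng=np.random.default_rng(seed), model=model,
                )
                rows.append({"seed": seed, "policy": policy, "start": corner,
                             "mean_steps": mean_steps})
    return pd.DataFrame(rows)


def exp_obstacle_task(spec: ExperimentSpec,
                      scene: ObstacleScene | None = None) -> pd.DataFrame:
    """Escape-direction probabilities for a four-cue obstacle scene."""
    if scene is None:
        scene = ObstacleScene(14.0, 15.0, 20.0, 16.0)  # right cue most salient
    rows = []
    for seed in _seeds(spec):
        model = build_model(spec.config, seed=seed)
        for variant in ("linear", "only-apl", "nonlinear"):
            p = simulate_obstacle(scene, variant,
                                  rng=np.random.default_rng(seed), model=model)
            row = {"seed": seed, "variant": variant}
            row.update({f"p{i + 1}": float(v) for i, v in enumerate(p)})
            rows.append(row)
    return pd.DataFrame(rows)


EXPERIMENTS = {
    "single_cue": exp_single_cue,
    "two_cue": exp_two_cue,
    "ci_shape_sweep": exp_ci_shape_sweep,
    "ci_color_sweep": exp_ci_color_sweep,
    "conflict_sweep": exp_conflict_sweep,
    "ablation_da_apl": exp_ablation_da_apl,
    "da_duration_sweep": exp_da_duration_sweep,
    "spike_train_compare": exp_spike_train_compare,
    "reversal": exp_reversal,
    "window_task": exp_window_task,
    "obstacle_task": exp_obstacle_task,
}


def _summarize(name: str, df: pd.DataFrame) -> dict:
    summary: dict = {"schema_version": 1, "experiment": name,
                     "n_rows": int(len(df))}
    value_col = next((c for c in ("pi", "mean_steps", "count", "incorrect")
                      if c in df.columns), None)
    if value_col is not None:
        group_cols = [c for c in df.columns
                      if c not in (value_col, "seed") and df[c].dtype != float]
        if group_cols:
            means = df.groupby(group_cols, sort=True)[value_col].mean()
            summary["mean_" + value_col] = {
                "/".join(map(str, k)) if isinstance(k, tuple) else str(k):
                    round(float(v), 4)
                for k, v in means.items()
            }
        else:
            summary["mean_" + value_col] = round(float(df[value_col].mean()), 4)
    return summary


def run_experiment(spec: ExperimentSpec) -> dict:
    """Execute a named experiment; write CSV, JSON summary and a log."""
    out_dir = Path(spec.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log.info("running experiment %s (seed=%d, n_seeds=%d)",
             spec.name, spec.seed, spec.n_seeds)
    df = EXPERIMENTS[spec.name](spec)
    df.insert(0, "experiment", spec.name)
    df.insert(1, "base_seed", spec.seed)
    csv_path = out_dir / f"{spec.name}.csv"
    df.to_csv(csv_path, index=False)
    summary = _summarize(spec.name, df)
    summary["seed"] = spec.seed
    summary["n_seeds"] = spec.n_seeds
    json_path = out_dir / f"{spec.name}.json"
    json_path.write_text(json.dumps(summary, indent=2, sort_keys=True))
    log.info("wrote %s and %s", csv_path, json_path)
    return {"csv": csv_path, "json": json_path, "data": df, "summary": summary}


def generate_fixtures(seed: int = 0, out_dir: str | Path = "fixtures") -> list[Path]:
    """Write the stimulus library and sample task scenes as CSV fixtures."""
    rng = np.random.default_rng(seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    lib_path = out / "patterns.csv"
    write_pattern_csv(lib_path, pattern_library(1.0))
    written.append(lib_path)

    ci_rows = []
    for ci in CI_GRID:
        for name, pat in sorted(pattern_library(ci).items()):
            ci_rows.append({"ci": ci, "name": name,
                            **{f"c{i}": v for i, v in enumerate(pat.vector)}})
    ci_path = out / "ci_grid.csv"
    pd.DataFrame(ci_rows).to_csv(ci_path, index=False)
    written.append(ci_path)

    scenes = [ObstacleScene(*(rng.uniform(5, 25, size=4).round(2)))
              for _ in range(5)]
    sc_path = out / "obstacle_scenes.csv"
    pd.DataFrame([{"d1": s.d1, "d2": s.d2, "d3": s.d3, "d4": s.d4}
                  for s in scenes]).to_csv(sc_path, index=False)
    written.append(sc_path)

    win_rows = [{"corner": c, "width": 9, "height": 9} for c in CORNERS]
    win_path = out / "window_starts.csv"
    pd.DataFrame(win_rows).to_csv(win_path, index=False)
    written.append(win_path)
    return written
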