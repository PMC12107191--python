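"""Replicate-aware statistics and pipeline orchestration.

Following the SuperPlots convention, per-cell values are summarized to
per-experiment means and all hypothesis tests run on those means (3-4
independent experiments per condition), never on pooled cells.  Two-tailed
paired t tests compare conditions across experiments; Pearson correlations
relate per-cluster quantities.  Raw p values are reported without
multiple-testing correction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats as sps

__all__ = [
    "TestResult",
    "superplot_aggregate",
    "paired_t_test",
    "pearson_r",
    "run_pipeline",
]


@dataclass
class TestResult:
    """A test statistic (t or r), its dof, two-tailed p and unit count."""

    statistic: float
    dof: int
    p_value: float
    n_units: int
    method: str
    flags: list[str] = field(default_factory=list)


def superplot_aggregate(
    table: pd.DataFrame,
    value_col: str = "value",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-experiment means per condition, plus cohort mean +/- SEM.

    ``table`` has one row per cell with columns ``experiment_id``,
    ``condition`` and the value column.  Returns ``(experiment_means,
    cohort_summary)`` where the summary aggregates experiment means per
    condition (mean, SEM over experiments, n_experiments, n_cells).
    """
    required = {"experiment_id", "condition", value_col}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"table missing columns: {sorted(missing)}")
    if table["experiment_id"].isna().any():
        raise ValueError("every row needs an experiment_id")
    exp_means = (
        table.groupby(["condition", "experiment_id"])[value_col]
        .agg(["mean", "size"])
        .reset_index()
        .rename(columns={"mean": "experiment_mean", "size": "n_cells"})
    )
    rows = []
    for cond, grp in exp_means.groupby("condition"):
        m = grp["experiment_mean"].to_numpy(float)
        sem = float(m.std(ddof=1) / np.sqrt(len(m))) if len(m) > 1 else np.nan
        rows.append(
            {
                "condition": cond,
                "mean": float(m.mean()),
                "sem": sem,
                "n_experiments": len(m),
                "n_cells": int(grp["n_cells"].sum()),
            }
        )
    return exp_means, pd.DataFrame(rows)


def paired_t_test(means_a: np.ndarray, means_b: np.ndarray) -> TestResult:
    """Two-tailed paired t test on per-experiment means.

    The arrays must be paired by experiment.  With zero variance of the
    differences the statistic is undefined and flagged rather than raised.
    """
    a = np.asarray(means_a, float)
    b = np.asarray(means_b, float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired samples must be 1D arrays of equal length")
    n = len(a)
    if n < 2:
        raise ValueError("need at least 2 pairs")
    d = a - b
    sd = d.std(ddof=1)
    if sd == 0:
        return TestResult(
            statistic=np.nan,
            dof=n - 1,
            p_value=np.nan,
            n_units=n,
            method="paired t (experiment means)",
            flags=["zero_variance"],
        )
    t = float(d.mean() / (sd / np.sqrt(n)))
    p = float(2.0 * sps.t.sf(abs(t), df=n - 1))
    return TestResult(
        statistic=t, dof=n - 1, p_value=p, n_units=n, method="paired t (experiment means)"
    )


def pearson_r(x: np.ndarray, y: np.ndarray) -> TestResult:
    """Pearson correlation with a two-tailed p from the t transform."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("need equal-length 1D arrays with at least 3 points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return TestResult(
            statistic=np.nan,
            dof=len(x) - 2,
            p_value=np.nan,
            n_units=len(x),
            method="pearson",
            flags=["constant_input"],
        )
    res = sps.pearsonr(x, y)
    return TestResult(
        statistic=float(res.statistic),
        dof=len(x) - 2,
        p_value=float(res.pvalue),
        n_units=len(x),
        method="pearson",
    )


# ---------------------------------------------------------------------------
# pipeline orchestration


def _stage_physics(params: dict) -> dict:
    from . import membrane

    specs = {
        "DOPC": membrane.DOPC,
        "DPPC": membrane.DPPC,
    }
    out = {}
    for name, spec in specs.items():
        out[f"D_predicted_{name}_um2_s"] = membrane.predict_diffusion_coefficient(spec)
    out["viscosity_fold_change"] = membrane.viscosity_fold_change(
        specs["DOPC"], specs["DPPC"]
    )
    return out


def _stage_tracking(params: dict, seed: int) -> dict:
    from . import simulate, spt

    D = float(params.get("D_um2_s", 1.9))
    n_tracks = int(params.get("n_tracks", 200))
    n_steps = int(params.get("n_steps", 100))
    dt = float(params.get("dt_s", simulate.SPT_FRAME_INTERVAL_S))
    tracks, _ = simulate.simulate_brownian_tracks(
        D=D, n_tracks=n_tracks, n_steps=n_steps, dt=dt, seed=seed
    )
    fits = spt.fit_tracks(tracks)
    return {
        "D_true_um2_s": D,
        "D_estimated_um2_s": float(fits["D_um2_s"].mean()),
        "alpha_estimated": float(fits["alpha"].mean()),
        "n_tracks": int(len(fits)),
    }


def _stage_frap(params: dict, seed: int) -> dict:
    from . import frap as frap_mod
    from . import simulate

    mobile = float(params.get("mobile_fraction", 0.95))
    t_half = float(params.get("t_half_s", 28.0))
    noise_sd = float(params.get("noise_sd", 0.02))
    times = np.arange(0.0, float(params.get("duration_s", 240.0)), 2.0)
    curve, _ = simulate.simulate_frap_curve(mobile, t_half, times, noise_sd=noise_sd, seed=seed)
    fit = frap_mod.fit_recovery(curve)
    return {
        "mobile_fraction_true": mobile,
        "mobile_fraction_fit": fit.mobile_fraction,
        "t_half_true_s": t_half,
        "t_half_fit_s": fit.t_half,
        "recovery_percent": fit.recovery_percent,
    }


def _stage_extraction(params: dict, seed: int) -> dict:
    from . import simulate, synapse

    config = simulate.SimulationConfig(
        seed=seed,
        duration=int(params.get("duration_frames", 40)),
        fov_px=int(params.get("fov_px", 96)),
    )
    n_cells = int(params.get("n_cells", 4))
    movies, truth = simulate.simulate_extraction_experiment(
        n_cells=n_cells,
        config=config,
        waiting_time_mean=float(params.get("waiting_time_mean_s", 74.0)),
    )
    all_events = []
    for cid, pair in enumerate(movies):
        events = synapse.detect_unquenching_events(
            pair["internalized"], cell_id=cid, psf_sigma_px=config.psf_sigma / config.pixel_size
        )
        frames = {}
        for f in range(pair["bound"].n_frames):
            seg = synapse.segment_cell(pair["bound"].pixels[f], config.pixel_size, frame=f)
            if seg is not None:
                frames[f] = seg
        synapse.assign_event_zones(events, frames)
        all_events.extend(events)
    table = synapse.events_to_frame(all_events)
    kinetics, frac5 = synapse.extraction_kinetics(
        table.rename(columns={"onset_time_s": "onset_time_s"}), list(range(n_cells))
    )
    zones = table["zone"].value_counts(normalize=True).to_dict() if len(table) else {}
    return {
        "n_true_events": int(len(truth.events)),
        "n_detected_events": int(len(table)),
        "fraction_within_5min": frac5,
        "mean_time_to_first_s": float(np.nanmean(kinetics["time_to_first_s"]))
        if kinetics["time_to_first_s"].notna().any()
        else np.nan,
        "zone_fractions": zones,
    }


def _stage_calcium(params: dict, seed: int) -> dict:
    from . import signaling, simulate

    n_per = int(params.get("n_per_class", 25))
    correct = 0
    total = 0
    for i, pattern in enumerate(signaling.PATTERNS):
        for j in range(n_per):
            trace, label = simulate.simulate_calcium_trace(pattern, seed=seed + 1000 * i + j)
            predicted = signaling.classify_calcium_pattern(trace)
            correct += int(predicted == label)
            total += 1
    return {"classifier_accuracy": correct / total, "n_traces": total}


def _stage_translocation(params: dict, seed: int) -> dict:
    from . import signaling, simulate

    rng = np.random.default_rng(seed)
    n_cells = int(params.get("n_cells", 100))
    p_active = float(params.get("p_active", 0.66))
    measures = []
    for i in range(n_cells):
        ratio = rng.uniform(1.05, 2.5) if rng.random() < p_active else rng.uniform(0.4, 0.95)
        img, nuc, cyt, _ = simulate.render_translocation_image(
            ratio, noise_model="poisson", seed=int(rng.integers(2**31))
        )
        measures.append(signaling.measure_translocation(img, nuc, cyt))
    return {
        "activated_percent": signaling.activated_fraction(measures),
        "true_active_percent": 100.0 * p_active,
        "n_cells": n_cells,
    }


_STAGES = {
    "physics": _stage_physics,
    "tracking": _stage_tracking,
    "frap": _stage_frap,
    "extraction": _stage_extraction,
    "calcium": _stage_calcium,
    "translocation": _stage_translocation,
}


def run_pipeline(config: dict | str | Path, out_dir: str | Path | None = None) -> dict:
    """Run simulate-then-analyze stages and emit a summary bundle.

    ``config`` is a mapping (or path to a YAML file) with a top-level
    ``seed`` and a ``stages`` mapping of stage name to parameter dict.
    Unknown stages raise before any computation.  Writes
    ``summary.json`` and ``report.md`` into ``out_dir`` when given, and
    returns the summary dict.
    """
    if isinstance(config, (str, Path)):
        config = yaml.safe_load(Path(config).read_text())
    if not config or "stages" not in config or not config["stages"]:
        raise ValueError("config must define at least one stage under 'stages'")
    unknown = set(config["stages"]) - set(_STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}; known: {sorted(_STAGES)}")
    seed = int(config.get("seed", 0))
    summary: dict = {"seed": seed, "stages": {}}
    for offset, (name, params) in enumerate(sorted(config["stages"].items())):
        fn = _STAGES[name]
        if name == "physics":
            summary["stages"][name] = fn(params or {})
        else:
            summary["stages"][name] = fn(params or {}, seed + 101 * offset)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "summary.json").write_text(json.dumps(summary, indent=2, default=float))
        lines = ["# Synapse-capture pipeline report", ""]
        for name, result in summary["stages"].items():
            lines.append(f"## {name}")
            for key, value in result.items():
                lines.append(f"- {key}: {value}")
            lines.append("")
        (out_dir / "report.md").write_text("\n".join(lines))
    return summary
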