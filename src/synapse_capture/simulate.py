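"""Synthetic-data generators for every input the analysis pipeline consumes.

Each generator is a pure function of its parameters and a seed, and returns
both the rendered signal and a :class:`GroundTruth` record so that every
analysis step can be validated against known truth: Brownian and
fractional-Brownian trajectories at membrane-realistic diffusion
coefficients, FRAP recovery curves, TIRF-style movies with Gaussian-PSF
emitters, two-channel antigen-extraction experiments in which unquenching
spots appear inside a spreading cell footprint, four-pattern calcium
traces, and two-compartment translocation images.

``STUDY_PRESETS`` collects the measured study conditions for the two
bilayer compositions (diffusion coefficients, FRAP parameters, extraction
kinetics, responder rates).  They parameterize realistic simulations and
documentation; they are measurements of real cells, not quantities a
simulation is expected to reproduce exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.linalg import cholesky

from .frap import RecoveryCurve
from .io import MovieStack
from .signaling import CalciumTrace
from .spt import TrajectorySet

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "STUDY_PRESETS",
    "simulate_brownian_tracks",
    "simulate_fbm_tracks",
    "simulate_frap_curve",
    "render_movie",
    "simulate_extraction_experiment",
    "simulate_calcium_trace",
    "render_translocation_image",
    "spreading_radius",
]


#: Measured study conditions per bilayer composition.  Documentation and
#: simulation presets only — these are properties of real B cells.
STUDY_PRESETS: dict[str, dict] = {
    "DOPC": {
        "D_um2_s": 1.9,
        "alpha": 0.75,
        "frap_mobile_fraction": 0.95,
        "frap_t_half_s": 28.0,
        "time_to_first_extraction_s": 421.0,
        "fraction_within_5min": 0.26,
        "central_zone_fraction": 0.15,
        "responder_fraction": 0.80,
        "cluster_size_vs_time_r": 0.47,
        "n_extracted_clusters": 245,
    },
    "DPPC": {
        "D_um2_s": 0.057,
        "alpha": 0.37,
        "frap_mobile_fraction": 0.02,
        "frap_t_half_s": np.nan,
        "time_to_first_extraction_s": 74.0,
        "fraction_within_5min": 0.64,
        "central_zone_fraction": 0.07,
        "responder_fraction": 0.93,
        "cluster_size_vs_time_r": 0.11,
        "n_extracted_clusters": 324,
    },
}

#: Default frame intervals: 8 s for extraction movies, 10 ms for SPT movies.
EXTRACTION_FRAME_INTERVAL_S = 8.0
SPT_FRAME_INTERVAL_S = 0.01


@dataclass
class SimulationConfig:
    """Acquisition parameters shared by the image-rendering generators."""

    seed: int = 0
    frame_interval: float = EXTRACTION_FRAME_INTERVAL_S
    pixel_size: float = 0.16
    psf_sigma: float = 0.2
    background: float = 100.0
    noise_model: str = "poisson"
    gaussian_sd: float = 10.0
    duration: int = 60
    fov_px: int = 128

    def __post_init__(self) -> None:
        if self.frame_interval <= 0 or self.pixel_size <= 0 or self.psf_sigma <= 0:
            raise ValueError("frame_interval, pixel_size and psf_sigma must be positive")
        if self.noise_model not in ("poisson", "gaussian", "none"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class GroundTruth:
    """Everything a generator knows about what it rendered."""

    params: dict = field(default_factory=dict)
    tracks: pd.DataFrame | None = None
    events: pd.DataFrame | None = None
    footprints: pd.DataFrame | None = None
    labels: list | None = None
    nc_ratio: float | None = None

    def write(self, directory) -> None:
        """Serialize to a directory of CSV tables plus a JSON manifest."""
        from pathlib import Path

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        manifest = {"params": self.params, "labels": self.labels, "nc_ratio": self.nc_ratio}
        (directory / "manifest.json").write_text(json.dumps(manifest, indent=2, default=float))
        for name in ("tracks", "events", "footprints"):
            table = getattr(self, name)
            if table is not None:
                table.to_csv(directory / f"{name}.csv", index=False)

    @classmethod
    def read(cls, directory) -> "GroundTruth":
        from pathlib import Path

        directory = Path(directory)
        manifest = json.loads((directory / "manifest.json").read_text())
        tables = {}
        for name in ("tracks", "events", "footprints"):
            path = directory / f"{name}.csv"
            tables[name] = pd.read_csv(path) if path.exists() else None
        return cls(
            params=manifest.get("params", {}),
            labels=manifest.get("labels"),
            nc_ratio=manifest.get("nc_ratio"),
            **tables,
        )


def _tracks_frame(positions: np.ndarray, dt: float) -> pd.DataFrame:
    """Long-format table from positions of shape (n_tracks, n_steps+1, 2)."""
    n_tracks, n_pts, _ = positions.shape
    track_id = np.repeat(np.arange(n_tracks), n_pts)
    frame = np.tile(np.arange(n_pts), n_tracks)
    flat = positions.reshape(-1, 2)
    return pd.DataFrame(
        {"track_id": track_id, "frame": frame, "x_um": flat[:, 0], "y_um": flat[:, 1]}
    )


def simulate_brownian_tracks(
    D: float,
    n_tracks: int,
    n_steps: int,
    dt: float,
    loc_noise: float = 0.0,
    seed: int = 0,
) -> tuple[TrajectorySet, GroundTruth]:
    """Simulate 2D Brownian trajectories at diffusion coefficient ``D``.

    Per-axis increments are i.i.d. Gaussian with variance ``2 D dt`` so the
    2D ensemble MSD is ``4 D tau``.  Reported positions add independent
    Gaussian localization noise of sd ``loc_noise`` (um) on top of the true
    positions, which are kept in the ground truth.
    """
    if D < 0 or loc_noise < 0:
        raise ValueError("D and loc_noise must be non-negative")
    if n_steps < 2:
        raise ValueError("need at least 2 steps")
    rng = np.random.default_rng(seed)
    steps = rng.normal(0.0, np.sqrt(2.0 * D * dt), size=(n_tracks, n_steps, 2))
    true_pos = np.concatenate(
        [np.zeros((n_tracks, 1, 2)), np.cumsum(steps, axis=1)], axis=1
    )
    observed = true_pos + rng.normal(0.0, loc_noise, size=true_pos.shape)
    truth = GroundTruth(
        params={"D": D, "dt": dt, "loc_noise": loc_noise, "seed": seed, "model": "brownian"},
        tracks=_tracks_frame(true_pos, dt),
    )
    return TrajectorySet(data=_tracks_frame(observed, dt), dt=dt), truth


def fgn_covariance(alpha: float, max_lag: int) -> np.ndarray:
    """Autocovariance of unit-variance fractional Gaussian noise.

    gamma(k) = 0.5 * (|k+1|^alpha - 2 |k|^alpha + |k-1|^alpha) with
    alpha = 2H; gamma(0) = 1.
    """
    k = np.arange(max_lag + 1, dtype=float)
    return 0.5 * (np.abs(k + 1) ** alpha - 2 * np.abs(k) ** alpha + np.abs(k - 1) ** alpha)


def simulate_fbm_tracks(
    alpha: float,
    scale: float,
    n_tracks: int,
    n_steps: int,
    dt: float,
    loc_noise: float = 0.0,
    seed: int = 0,
) -> tuple[TrajectorySet, GroundTruth]:
    """Simulate 2D fractional Brownian motion with MSD(tau) = 4 scale tau^alpha.

    Per-axis increments are fractional Gaussian noise with Hurst index
    ``H = alpha/2`` and per-step variance ``2 scale dt^alpha``, sampled
    exactly through the Cholesky factor of the fGN covariance.  ``alpha=1``
    reduces to Brownian motion; ``alpha=2`` is the ballistic limit where
    every increment of a track repeats its first.
    """
    if not (0 < alpha <= 2):
        raise ValueError("alpha must be in (0, 2]")
    if scale < 0 or loc_noise < 0:
        raise ValueError("scale and loc_noise must be non-negative")
    rng = np.random.default_rng(seed)
    step_sd = np.sqrt(2.0 * scale * dt**alpha)
    if alpha == 2.0:
        # degenerate, perfectly persistent case
        first = rng.normal(0.0, step_sd, size=(n_tracks, 1, 2))
        steps = np.repeat(first, n_steps, axis=1)
    elif alpha == 1.0:
        steps = rng.normal(0.0, step_sd, size=(n_tracks, n_steps, 2))
    else:
        gamma = fgn_covariance(alpha, n_steps - 1)
        idx = np.abs(np.subtract.outer(np.arange(n_steps), np.arange(n_steps)))
        cov = gamma[idx]
        L = cholesky(cov + 1e-12 * np.eye(n_steps), lower=True)
        z = rng.normal(size=(n_tracks, 2, n_steps))
        steps = step_sd * np.einsum("ij,ncj->nci", L, z).transpose(0, 2, 1)
    true_pos = np.concatenate(
        [np.zeros((n_tracks, 1, 2)), np.cumsum(steps, axis=1)], axis=1
    )
    observed = true_pos + rng.normal(0.0, loc_noise, size=true_pos.shape)
    truth = GroundTruth(
        params={
            "alpha": alpha,
            "scale": scale,
            "dt": dt,
            "loc_noise": loc_noise,
            "seed": seed,
            "model": "fbm",
        },
        tracks=_tracks_frame(true_pos, dt),
    )
    return TrajectorySet(data=_tracks_frame(observed, dt), dt=dt), truth


def simulate_frap_curve(
    mobile_fraction: float,
    t_half: float,
    times: np.ndarray,
    noise_sd: float = 0.0,
    seed: int = 0,
    F0: float = 0.0,
    n_prebleach: int = 5,
    prebleach_dt: float | None = None,
) -> tuple[RecoveryCurve, GroundTruth]:
    """Generate a normalized FRAP curve with a mobile fraction and half-time.

    The noiseless post-bleach curve is
    ``F(t) = F0 + (Fp - F0) (1 - 2**(-t/t_half))`` with pre-bleach level 1
    and plateau ``Fp = F0 + mobile_fraction (1 - F0)``.  ``times`` are
    post-bleach sample times (s, starting at 0); ``n_prebleach`` unit-level
    frames are prepended.
    """
    if not (0.0 <= mobile_fraction <= 1.0):
        raise ValueError("mobile_fraction must be in [0, 1]")
    if mobile_fraction > 0 and not (t_half > 0):
        raise ValueError("t_half must be positive when there is recovery")
    times = np.asarray(times, float)
    rng = np.random.default_rng(seed)
    Fp = F0 + mobile_fraction * (1.0 - F0)
    if mobile_fraction > 0:
        post = F0 + (Fp - F0) * (1.0 - np.power(2.0, -times / t_half))
    else:
        post = np.full_like(times, F0)
    if prebleach_dt is None:
        prebleach_dt = float(times[1] - times[0]) if len(times) > 1 else 1.0
    pre_times = -prebleach_dt * np.arange(n_prebleach, 0, -1)
    values = np.concatenate([np.ones(n_prebleach), post])
    values = values + rng.normal(0.0, noise_sd, size=values.shape)
    curve = RecoveryCurve(
        times=np.concatenate([pre_times, times]),
        values=values,
        bleach_index=n_prebleach,
        n_prebleach=n_prebleach,
    )
    truth = GroundTruth(
        params={
            "mobile_fraction": mobile_fraction,
            "t_half": t_half,
            "F0": F0,
            "F_plateau": Fp,
            "noise_sd": noise_sd,
            "seed": seed,
        }
    )
    return curve, truth


# ---------------------------------------------------------------------------
# image rendering


def _render_gaussians(
    frame: np.ndarray, xs_px: np.ndarray, ys_px: np.ndarray, intensities: np.ndarray, sigma_px: float
) -> None:
    """Add 2D Gaussian emitters (integrated intensity per emitter) in place."""
    h, w = frame.shape
    half = int(np.ceil(5 * sigma_px))
    for x, y, inten in zip(xs_px, ys_px, intensities):
        x0, x1 = int(np.floor(x)) - half, int(np.floor(x)) + half + 1
        y0, y1 = int(np.floor(y)) - half, int(np.floor(y)) + half + 1
        x0c, x1c = max(0, x0), min(w, x1)
        y0c, y1c = max(0, y0), min(h, y1)
        if x0c >= x1c or y0c >= y1c:
            continue
        yy, xx = np.mgrid[y0c:y1c, x0c:x1c]
        amp = inten / (2.0 * np.pi * sigma_px**2)
        frame[y0c:y1c, x0c:x1c] += amp * np.exp(
            -((xx - x) ** 2 + (yy - y) ** 2) / (2.0 * sigma_px**2)
        )


def _apply_noise(stack: np.ndarray, config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    if config.noise_model == "poisson":
        return rng.poisson(np.clip(stack, 0.0, None)).astype(float)
    if config.noise_model == "gaussian":
        return stack + rng.normal(0.0, config.gaussian_sd, size=stack.shape)
    return stack


def render_movie(
    emitters: pd.DataFrame,
    config: SimulationConfig,
    footprints: pd.DataFrame | None = None,
    footprint_level: float = 0.0,
    channel: str = "",
) -> tuple[MovieStack, GroundTruth]:
    """Render point emitters (and an optional disk footprint) into a stack.

    ``emitters`` columns: ``x_um, y_um, intensity`` plus optional
    ``start_frame`` / ``end_frame`` (an unquenching emitter is dark before
    ``start_frame`` and fluorescent from it onward).  ``footprints``
    columns: ``frame, cx_um, cy_um, radius_um``; pixels inside the disk get
    ``footprint_level`` added (a diffuse bound-antigen signal).  Emitters
    outside the field of view are skipped with a warning record in the
    ground truth.
    """
    rng = np.random.default_rng(config.seed)
    n = config.fov_px
    stack = np.full((config.duration, n, n), float(config.background))
    fov_um = n * config.pixel_size
    emitters = emitters.copy()
    if "start_frame" not in emitters:
        emitters["start_frame"] = 0
    if "end_frame" not in emitters:
        emitters["end_frame"] = config.duration
    inside = (
        (emitters["x_um"] >= 0)
        & (emitters["x_um"] < fov_um)
        & (emitters["y_um"] >= 0)
        & (emitters["y_um"] < fov_um)
    )
    rejected = int((~inside).sum())
    emitters = emitters[inside]
    sigma_px = config.psf_sigma / config.pixel_size
    yy, xx = np.mgrid[0:n, 0:n]
    for f in range(config.duration):
        if footprints is not None and footprint_level:
            rows = footprints[footprints["frame"] == f]
            for _, r in rows.iterrows():
                cx, cy = r["cx_um"] / config.pixel_size, r["cy_um"] / config.pixel_size
                rad = r["radius_um"] / config.pixel_size
                disk = (xx - cx) ** 2 + (yy - cy) ** 2 <= rad**2
                stack[f][disk] += footprint_level
        live = emitters[(emitters["start_frame"] <= f) & (f < emitters["end_frame"])]
        if len(live):
            _render_gaussians(
                stack[f],
                live["x_um"].to_numpy() / config.pixel_size,
                live["y_um"].to_numpy() / config.pixel_size,
                live["intensity"].to_numpy(),
                sigma_px,
            )
    stack = _apply_noise(stack, config, rng)
    movie = MovieStack(
        pixels=stack,
        pixel_size=config.pixel_size,
        frame_interval=config.frame_interval,
        channel=channel,
    )
    truth = GroundTruth(
        params={"config": config.to_dict(), "rejected_emitters": rejected, "channel": channel},
        events=emitters.reset_index(drop=True),
        footprints=footprints,
    )
    return movie, truth


def spreading_radius(
    n_frames: int,
    frame_interval: float,
    r0: float = 3.0,
    r_max: float = 7.0,
    tau_spread: float = 120.0,
) -> np.ndarray:
    """Cell footprint radius over time: saturating spread from r0 to r_max (um)."""
    t = np.arange(n_frames) * frame_interval
    return r0 + (r_max - r0) * (1.0 - np.exp(-t / tau_spread))


def _sample_radial_fraction(rng: np.random.Generator, zone: str | None) -> float:
    """Radial fraction r/R, uniform in area, optionally restricted to a zone."""
    bounds = {
        None: (0.0, 1.0),
        "central": (0.0, 1.0 / 3.0),
        "peripheral": (1.0 / 3.0, 2.0 / 3.0),
        "distal": (2.0 / 3.0, 1.0),
    }
    a, b = bounds[zone]
    return float(np.sqrt(rng.uniform(a**2, b**2)))


def zone_of(normalized_distance: float) -> str:
    """Zone label from a normalized radial distance (half-open thirds)."""
    if normalized_distance < 1.0 / 3.0:
        return "central"
    if normalized_distance < 2.0 / 3.0:
        return "peripheral"
    return "distal"


def simulate_extraction_experiment(
    n_cells: int,
    config: SimulationConfig,
    waiting_time_mean: float = 74.0,
    zone_event_rates: dict[str, float] | None = None,
    cluster_intensity_mean: float = 4000.0,
    cluster_intensity_cv: float = 0.3,
    cell_radius_trajectory: np.ndarray | None = None,
    bound_level: float = 200.0,
    min_separation_um: float = 1.0,
) -> tuple[list[dict[str, MovieStack]], GroundTruth]:
    """Simulate live-cell antigen-extraction movies with ground truth.

    One cell per two-channel movie pair.  The footprint is a disk whose
    radius follows ``cell_radius_trajectory`` (default: a saturating
    spreading curve).  Unquenching events occur as a memoryless renewal
    process with exponential inter-event times of mean ``waiting_time_mean``
    seconds; each event's position is drawn uniformly in area, either over
    the whole current footprint (default) or within a zone chosen with
    probability proportional to ``zone_event_rates``.  Channel ``"bound"``
    carries a diffuse membrane-bound antigen signal inside the footprint;
    channel ``"internalized"`` carries spots that are dark before their
    rupture frame and fluorescent from it onward.  Cluster intensities are
    gamma-distributed around ``cluster_intensity_mean``.
    """
    if waiting_time_mean is None and not zone_event_rates:
        raise ValueError("need a waiting_time_mean or zone_event_rates")
    if zone_event_rates is not None:
        total_rate = sum(zone_event_rates.values())
        if total_rate < 0 or any(v < 0 for v in zone_event_rates.values()):
            raise ValueError("zone rates must be non-negative")
        if total_rate == 0 and waiting_time_mean is None:
            raise ValueError("all rates zero and no waiting_time_mean")
        if waiting_time_mean is None:
            waiting_time_mean = 1.0 / total_rate
    rng = np.random.default_rng(config.seed)
    radii = (
        np.asarray(cell_radius_trajectory, float)
        if cell_radius_trajectory is not None
        else spreading_radius(config.duration, config.frame_interval)
    )
    if np.any(radii <= 0):
        raise ValueError("cell radius trajectory must be positive")
    if len(radii) != config.duration:
        raise ValueError("radius trajectory length must equal duration")
    fov_um = config.fov_px * config.pixel_size
    center = fov_um / 2.0
    t_end = config.duration * config.frame_interval

    movies: list[dict[str, MovieStack]] = []
    event_rows: list[dict] = []
    fp_rows: list[dict] = []
    shape_k = 1.0 / cluster_intensity_cv**2 if cluster_intensity_cv > 0 else None
    for cell in range(n_cells):
        footprints = pd.DataFrame(
            {
                "cell_id": cell,
                "frame": np.arange(config.duration),
                "cx_um": center,
                "cy_um": center,
                "radius_um": radii,
            }
        )
        fp_rows.append(footprints)
        # exponential renewal process for rupture times
        times = []
        t = rng.exponential(waiting_time_mean) if waiting_time_mean > 0 else np.inf
        while t < t_end:
            times.append(t)
            t += rng.exponential(waiting_time_mean)
        placed: list[tuple[float, float]] = []
        cell_events = []
        zone_names = list(zone_event_rates) if zone_event_rates else [None]
        zone_probs = (
            np.array([zone_event_rates[z] for z in zone_names], float)
            if zone_event_rates
            else np.array([1.0])
        )
        if zone_probs.sum() > 0:
            zone_probs = zone_probs / zone_probs.sum()
        for t in times:
            frame = max(1, int(np.ceil(t / config.frame_interval)))
            if frame >= config.duration:
                continue
            radius = radii[frame]
            for _ in range(50):  # rejection sampling to keep spots separable
                zone_req = zone_names[rng.choice(len(zone_names), p=zone_probs)]
                r_frac = _sample_radial_fraction(rng, zone_req)
                theta = rng.uniform(0.0, 2.0 * np.pi)
                x = center + r_frac * radius * np.cos(theta)
                y = center + r_frac * radius * np.sin(theta)
                if all((x - px) ** 2 + (y - py) ** 2 >= min_separation_um**2 for px, py in placed):
                    break
            else:
                continue
            placed.append((x, y))
            if shape_k is not None:
                intensity = float(rng.gamma(shape_k, cluster_intensity_mean / shape_k))
            else:
                intensity = cluster_intensity_mean
            cell_events.append(
                {
                    "cell_id": cell,
                    "frame": frame,
                    "t_s": t,
                    "x_um": x,
                    "y_um": y,
                    "r_frac": r_frac,
                    "zone": zone_of(r_frac),
                    "intensity": intensity,
                    "start_frame": frame,
                }
            )
        events = pd.DataFrame(
            cell_events,
            columns=[
                "cell_id",
                "frame",
                "t_s",
                "x_um",
                "y_um",
                "r_frac",
                "zone",
                "intensity",
                "start_frame",
            ],
        )
        event_rows.append(events)
        cfg_bound = SimulationConfig(**{**config.to_dict(), "seed": config.seed + 7919 * cell + 1})
        cfg_int = SimulationConfig(**{**config.to_dict(), "seed": config.seed + 7919 * cell + 2})
        bound, _ = render_movie(
            pd.DataFrame(columns=["x_um", "y_um", "intensity"]),
            cfg_bound,
            footprints=footprints,
            footprint_level=bound_level,
            channel="bound",
        )
        internal, _ = render_movie(
            events[["x_um", "y_um", "intensity", "start_frame"]]
            if len(events)
            else pd.DataFrame(columns=["x_um", "y_um", "intensity"]),
            cfg_int,
            channel="internalized",
        )
        movies.append({"bound": bound, "internalized": internal})
    truth = GroundTruth(
        params={
            "n_cells": n_cells,
            "waiting_time_mean": waiting_time_mean,
            "zone_event_rates": zone_event_rates,
            "cluster_intensity_mean": cluster_intensity_mean,
            "cluster_intensity_cv": cluster_intensity_cv,
            "bound_level": bound_level,
            "config": config.to_dict(),
        },
        events=(
            pd.concat([e for e in event_rows if len(e)], ignore_index=True)
            if any(len(e) for e in event_rows)
            else event_rows[0]
        ),
        footprints=pd.concat(fp_rows, ignore_index=True),
    )
    return movies, truth


# ---------------------------------------------------------------------------
# calcium and translocation


def _pulse(t: np.ndarray, onset: float, tau: float) -> np.ndarray:
    """Unit-peak transient: linear-exponential rise-decay (gamma-like)."""
    s = np.clip((t - onset) / tau, 0.0, None)
    return s * np.exp(1.0 - s)


def simulate_calcium_trace(
    pattern: str,
    duration: float = 300.0,
    dt: float = 1.0,
    noise_sd: float = 2.0,
    seed: int = 0,
    baseline: float = 100.0,
    amplitude_dff: float = 2.0,
    onset: float = 30.0,
    tau_rise: float = 8.0,
    period: float = 60.0,
    n_oscillations: int = 5,
    contact_time: float = 20.0,
) -> tuple[CalciumTrace, str]:
    """Generate a calcium trace of one of the four response patterns.

    nonresponsive: baseline plus noise.  unique: a single transient rising
    at ``onset`` and decaying back to baseline.  maintained: a rise to a
    plateau held for the rest of the trace.  oscillatory: ``n_oscillations``
    transients spaced ``period`` seconds apart.  Gaussian noise of sd
    ``noise_sd`` (raw-fluorescence units) is added per timepoint.
    """
    if pattern not in ("oscillatory", "maintained", "unique", "nonresponsive"):
        raise ValueError(f"unknown pattern {pattern!r}")
    if duration <= onset:
        raise ValueError("duration must exceed the onset time")
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, duration, dt)
    dff = np.zeros_like(t)
    if pattern == "unique":
        dff = amplitude_dff * _pulse(t, onset, tau_rise)
    elif pattern == "maintained":
        dff = amplitude_dff * (1.0 - np.exp(-np.clip(t - onset, 0.0, None) / tau_rise))
        dff[t < onset] = 0.0
    elif pattern == "oscillatory":
        for i in range(n_oscillations):
            dff = dff + amplitude_dff * _pulse(t, onset + i * period, tau_rise)
    values = baseline * (1.0 + dff) + rng.normal(0.0, noise_sd, size=t.shape)
    trace = CalciumTrace(times=t, values=values, contact_time=contact_time)
    return trace, pattern


def render_translocation_image(
    nc_ratio: float,
    shape: tuple[int, int] = (64, 64),
    nucleus_radius: int = 10,
    cyto_radius: int = 22,
    cyto_level: float = 200.0,
    background: float = 0.0,
    noise_model: str = "none",
    gaussian_sd: float = 5.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, GroundTruth]:
    """Render a two-compartment cell with a controlled N/C intensity ratio.

    The nucleus is a central disk, the cytoplasm the surrounding annulus;
    before noise the nuclear-to-cytoplasmic mean intensity ratio equals
    ``nc_ratio`` exactly.  Returns (image, nuclear_mask, cyto_mask, truth).
    """
    if nc_ratio <= 0:
        raise ValueError("nc_ratio must be positive")
    if nucleus_radius >= cyto_radius:
        raise ValueError("nucleus must fit inside the cytoplasm annulus")
    rng = np.random.default_rng(seed)
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    r2 = (yy - cy) ** 2 + (xx - cx) ** 2
    nuclear_mask = r2 <= nucleus_radius**2
    cyto_mask = (r2 > nucleus_radius**2) & (r2 <= cyto_radius**2)
    image = np.full(shape, float(background))
    image[cyto_mask] += cyto_level
    image[nuclear_mask] += cyto_level * nc_ratio
    if noise_model == "poisson":
        image = rng.poisson(np.clip(image, 0.0, None)).astype(float)
    elif noise_model == "gaussian":
        image = image + rng.normal(0.0, gaussian_sd, size=shape)
    elif noise_model != "none":
        raise ValueError(f"unknown noise model {noise_model!r}")
    truth = GroundTruth(
        params={"cyto_level": cyto_level, "background": background, "seed": seed},
        nc_ratio=nc_ratio,
    )
    return image, nuclear_mask, cyto_mask, truth
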