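"""Single-particle tracking: spot detection, linking, MSD and diffusion fits.

The workflow mirrors standard membrane SPT analysis: detect diffraction-
limited puncta frame by frame, link detections into trajectories, compute
time-averaged mean-squared displacement (MSD) per trajectory, and estimate
the diffusion coefficient D from the short-lag linear fit MSD = 4 D tau + c
and the anomalous exponent alpha from the log-log slope of MSD versus lag.

Summary statistics are aggregated per-track then averaged, mirroring how
per-bilayer means are formed from trajectory ensembles.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.optimize import linear_sum_assignment

__all__ = [
    "Spot",
    "TrajectorySet",
    "MSDCurve",
    "DiffusionFit",
    "detect_spots",
    "link_tracks",
    "compute_msd",
    "fit_diffusion_coefficient",
    "fit_anomalous_exponent",
    "fit_tracks",
]


@dataclass(frozen=True)
class Spot:
    """A detected punctum: frame index, subpixel position (px), intensity."""

    frame: int
    x: float
    y: float
    intensity: float
    sigma: float = np.nan


@dataclass
class TrajectorySet:
    """A set of linked trajectories in physical units.

    ``data`` holds one row per localization with columns
    ``track_id, frame, x_um, y_um`` (optionally ``intensity``);
    ``dt`` is the frame interval in seconds and ``pixel_size`` the
    calibration in um/px used to produce the coordinates.
    """

    data: pd.DataFrame
    dt: float
    pixel_size: float = 1.0

    def __post_init__(self) -> None:
        required = {"track_id", "frame", "x_um", "y_um"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"trajectory table missing columns: {sorted(missing)}")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if not np.isfinite(self.data[["x_um", "y_um"]].to_numpy()).all():
            raise ValueError("positions must be finite")

    @property
    def n_tracks(self) -> int:
        return self.data["track_id"].nunique()

    def iter_tracks(self) -> Iterator[tuple[int, np.ndarray, np.ndarray]]:
        """Yield (track_id, frames, positions[n, 2]) sorted by frame."""
        for tid, grp in self.data.groupby("track_id", sort=True):
            grp = grp.sort_values("frame")
            frames = grp["frame"].to_numpy()
            if np.any(np.diff(frames) <= 0):
                raise ValueError(f"track {tid} has non-increasing frames")
            yield tid, frames, grp[["x_um", "y_um"]].to_numpy(float)

    def track_lengths(self) -> pd.Series:
        return self.data.groupby("track_id").size()

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, dt: float, pixel_size: float = 1.0) -> "TrajectorySet":
        return cls(pd.read_csv(path), dt=dt, pixel_size=pixel_size)


@dataclass
class MSDCurve:
    """Mean-squared displacement versus lag time.

    ``lags`` are lag times in seconds (strictly increasing), ``values`` the
    MSD in um^2 and ``n_pairs`` the number of displacement pairs that went
    into each lag.  MSD(0) = 0 is implicit and not stored.
    """

    lags: np.ndarray
    values: np.ndarray
    n_pairs: np.ndarray

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, float)
        self.values = np.asarray(self.values, float)
        self.n_pairs = np.asarray(self.n_pairs, int)
        if np.any(np.diff(self.lags) <= 0):
            raise ValueError("lags must be strictly increasing")
        if np.any(self.values < 0):
            raise ValueError("MSD values must be non-negative")


@dataclass
class DiffusionFit:
    """Result of fitting MSD(tau) = 4 D tau + c (and log-log slope alpha)."""

    D: float
    noise_offset: float
    alpha: float = np.nan
    fit_range: tuple[int, int] = (0, 0)
    r_squared: float = np.nan


# ---------------------------------------------------------------------------
# Detection


def detect_spots(
    frame: np.ndarray,
    psf_sigma: float,
    snr_threshold: float = 5.0,
    frame_index: int = 0,
) -> list[Spot]:
    """Detect diffraction-limited spots in a single image.

    Band-pass the image with a difference of Gaussians at ``psf_sigma``,
    find local maxima, keep those whose raw peak exceeds
    ``median + snr_threshold * robust_sd`` (robust sd from the median
    absolute deviation), then refine each to a subpixel centroid in a
    window of half-width ``2 * psf_sigma``.  Maxima closer than
    ``2 * psf_sigma`` are merged keeping the brighter one.
    """
    img = np.asarray(frame, float)
    if img.ndim != 2 or min(img.shape) < 7:
        raise ValueError("image must be 2D and at least 7x7 px")
    if not np.isfinite(img).all():
        raise ValueError("image contains non-finite pixels")

    bandpass = ndimage.gaussian_filter(img, psf_sigma) - ndimage.gaussian_filter(
        img, 2.0 * psf_sigma
    )
    background = float(np.median(img))
    mad = float(np.median(np.abs(img - background)))
    robust_sd = 1.4826 * mad
    if robust_sd == 0.0:
        # noiseless image: any strictly positive band-pass response counts
        robust_sd = max(1e-12, 1e-9 * max(abs(img).max(), 1.0))
    threshold = background + snr_threshold * robust_sd

    footprint = np.ones((3, 3), bool)
    local_max = (bandpass == ndimage.maximum_filter(bandpass, footprint=footprint)) & (
        bandpass > 0
    )
    ys, xs = np.nonzero(local_max)
    keep = img[ys, xs] > threshold
    ys, xs = ys[keep], xs[keep]
    if ys.size == 0:
        return []

    # enforce minimum separation, brighter spot wins
    order = np.argsort(img[ys, xs])[::-1]
    ys, xs = ys[order], xs[order]
    min_sep2 = (2.0 * psf_sigma) ** 2
    chosen: list[tuple[int, int]] = []
    for y, x in zip(ys, xs):
        if all((y - cy) ** 2 + (x - cx) ** 2 >= min_sep2 for cy, cx in chosen):
            chosen.append((y, x))

    half = max(1, int(round(2.0 * psf_sigma)))
    spots: list[Spot] = []
    for y, x in chosen:
        y0, y1 = max(0, y - half), min(img.shape[0], y + half + 1)
        x0, x1 = max(0, x - half), min(img.shape[1], x + half + 1)
        window = img[y0:y1, x0:x1] - background
        window = np.clip(window, 0.0, None)
        total = window.sum()
        if total <= 0:
            continue
        yy, xx = np.mgrid[y0:y1, x0:x1]
        cy = float((yy * window).sum() / total)
        cx = float((xx * window).sum() / total)
        var = ((yy - cy) ** 2 + (xx - cx) ** 2) * window
        sigma = float(np.sqrt(var.sum() / total / 2.0))
        spots.append(Spot(frame=frame_index, x=cx, y=cy, intensity=float(total), sigma=sigma))
    spots.sort(key=lambda s: (s.y, s.x))
    return spots


# ---------------------------------------------------------------------------
# Linking


def _assign(prev: np.ndarray, curr: np.ndarray, max_disp: float, method: str):
    """Match rows of prev to rows of curr within max_disp.

    Returns list of (i_prev, j_curr) pairs.
    """
    if len(prev) == 0 or len(curr) == 0:
        return []
    d2 = ((prev[:, None, :] - curr[None, :, :]) ** 2).sum(axis=2)
    max2 = max_disp**2
    if method == "greedy":
        pairs = []
        used_i: set[int] = set()
        used_j: set[int] = set()
        order = np.argsort(d2, axis=None)
        for flat in order:
            i, j = np.unravel_index(flat, d2.shape)
            if d2[i, j] > max2:
                break
            if i in used_i or j in used_j:
                continue
            pairs.append((int(i), int(j)))
            used_i.add(int(i))
            used_j.add(int(j))
        return pairs
    # optimal: Hungarian with a forbidden-cost sentinel
    big = max2 * 1e6 + 1.0
    cost = np.where(d2 <= max2, d2, big)
    rows, cols = linear_sum_assignment(cost)
    return [(int(i), int(j)) for i, j in zip(rows, cols) if d2[i, j] <= max2]


def link_tracks(
    spots_by_frame: Sequence[Sequence[Spot]],
    max_disp: float,
    max_gap: int = 1,
    dt: float = 1.0,
    pixel_size: float = 1.0,
    method: str = "optimal",
) -> TrajectorySet:
    """Link per-frame detections into trajectories.

    Frame-to-frame assignment minimizes total squared displacement subject
    to a hard gate of ``max_disp`` px per frame step (scaled by the gap
    length when bridging up to ``max_gap`` missing frames).  Unmatched
    detections seed new tracks.  ``method`` selects optimal (Hungarian)
    assignment or a greedy nearest-neighbour variant.
    """
    if max_disp <= 0:
        raise ValueError("max_disp must be positive")
    if method not in ("optimal", "greedy"):
        raise ValueError(f"unknown linking method {method!r}")

    rows: list[dict] = []
    # active track state: id -> (last_frame, last_pos)
    active: dict[int, tuple[int, np.ndarray]] = {}
    next_id = 0
    for f, spots in enumerate(spots_by_frame):
        positions = np.array([[s.x, s.y] for s in spots], float).reshape(len(spots), 2)
        # drop stale tracks
        active = {tid: st for tid, st in active.items() if f - st[0] <= max_gap + 1}
        tids = list(active.keys())
        matched_j: set[int] = set()
        if tids and len(spots):
            prev = np.array([active[tid][1] for tid in tids])
            gaps = np.array([f - active[tid][0] for tid in tids], float)
            # gate each candidate pair by gap-scaled displacement
            d2 = ((prev[:, None, :] - positions[None, :, :]) ** 2).sum(axis=2)
            allowed = d2 <= (max_disp * gaps[:, None]) ** 2
            big = d2.max() * 1e6 + 1.0
            cost = np.where(allowed, d2, big)
            if method == "optimal":
                ri, cj = linear_sum_assignment(cost)
                pairs = [(int(i), int(j)) for i, j in zip(ri, cj) if allowed[i, j]]
            else:
                pairs = []
                used_i: set[int] = set()
                used_j: set[int] = set()
                for flat in np.argsort(cost, axis=None):
                    i, j = np.unravel_index(flat, cost.shape)
                    if not allowed[i, j]:
                        break
                    if i in used_i or j in used_j:
                        continue
                    pairs.append((int(i), int(j)))
                    used_i.add(int(i))
                    used_j.add(int(j))
            for i, j in pairs:
                tid = tids[i]
                active[tid] = (f, positions[j])
                matched_j.add(j)
                rows.append(
                    {
                        "track_id": tid,
                        "frame": f,
                        "x_um": positions[j, 0] * pixel_size,
                        "y_um": positions[j, 1] * pixel_size,
                        "intensity": spots[j].intensity,
                    }
                )
        for j, s in enumerate(spots):
            if j in matched_j:
                continue
            active[next_id] = (f, positions[j])
            rows.append(
                {
                    "track_id": next_id,
                    "frame": f,
                    "x_um": positions[j, 0] * pixel_size,
                    "y_um": positions[j, 1] * pixel_size,
                    "intensity": s.intensity,
                }
            )
            next_id += 1
    columns = ["track_id", "frame", "x_um", "y_um", "intensity"]
    data = pd.DataFrame(rows, columns=columns)
    return TrajectorySet(data=data, dt=dt, pixel_size=pixel_size)


# ---------------------------------------------------------------------------
# MSD and fits


def _track_msd(positions: np.ndarray, max_lag: int) -> tuple[np.ndarray, np.ndarray]:
    """Time-averaged MSD over all ordered pairs, lags 1..max_lag (frames)."""
    n = len(positions)
    values = np.empty(max_lag)
    counts = np.empty(max_lag, int)
    for k in range(1, max_lag + 1):
        disp = positions[k:] - positions[:-k]
        values[k - 1] = (disp**2).sum(axis=1).mean()
        counts[k - 1] = n - k
    return values, counts


def compute_msd(
    tracks: TrajectorySet,
    max_lag_fraction: float = 0.5,
    min_track_length: int = 2,
) -> tuple[dict[int, MSDCurve], MSDCurve]:
    """Time-averaged MSD per track plus the pair-weighted ensemble curve.

    Lags run from one frame up to ``max_lag_fraction`` of each track's
    length.  Tracks must have contiguous frames (gaps disqualify the track
    from MSD analysis).  Returns ``(per_track, ensemble)``.
    """
    if not (0 < max_lag_fraction <= 1):
        raise ValueError("max_lag_fraction must be in (0, 1]")
    per_track: dict[int, MSDCurve] = {}
    acc_vals: dict[int, float] = {}
    acc_counts: dict[int, int] = {}
    n_used = 0
    for tid, frames, positions in tracks.iter_tracks():
        if len(frames) < max(2, min_track_length):
            continue
        if np.any(np.diff(frames) != 1):
            continue  # gapped tracks excluded from MSD
        max_lag = max(1, int(np.floor(max_lag_fraction * len(frames))))
        values, counts = _track_msd(positions, max_lag)
        lags = np.arange(1, max_lag + 1) * tracks.dt
        per_track[tid] = MSDCurve(lags=lags, values=values, n_pairs=counts)
        n_used += 1
        for k in range(max_lag):
            acc_vals[k] = acc_vals.get(k, 0.0) + values[k] * counts[k]
            acc_counts[k] = acc_counts.get(k, 0) + counts[k]
    if n_used == 0:
        raise ValueError("no usable tracks (need >= 2 contiguous points)")
    ks = sorted(acc_counts)
    ens = MSDCurve(
        lags=np.array([(k + 1) * tracks.dt for k in ks]),
        values=np.array([acc_vals[k] / acc_counts[k] for k in ks]),
        n_pairs=np.array([acc_counts[k] for k in ks]),
    )
    return per_track, ens


def fit_diffusion_coefficient(msd: MSDCurve, n_fit_points: int = 4) -> DiffusionFit:
    """Fit MSD(tau) = 4 D tau + c over the first ``n_fit_points`` lags.

    Weighted least squares with weights proportional to the number of
    displacement pairs per lag.  D is the slope / 4 clamped at zero; the
    intercept absorbs the 4 sigma_loc^2 localization-noise term and is
    reported clamped at zero as ``noise_offset``.
    """
    if n_fit_points < 2:
        raise ValueError("need at least 2 fit points")
    if len(msd.lags) < n_fit_points:
        raise ValueError(
            f"MSD curve has {len(msd.lags)} lags, fewer than n_fit_points={n_fit_points}"
        )
    tau = msd.lags[:n_fit_points]
    y = msd.values[:n_fit_points]
    w = msd.n_pairs[:n_fit_points].astype(float)
    X = np.column_stack([tau, np.ones_like(tau)])
    sw = np.sqrt(w)
    beta, *_ = np.linalg.lstsq(X * sw[:, None], y * sw, rcond=None)
    slope, intercept = beta
    yhat = X @ beta
    ss_res = float((w * (y - yhat) ** 2).sum())
    ss_tot = float((w * (y - np.average(y, weights=w)) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return DiffusionFit(
        D=max(slope / 4.0, 0.0),
        noise_offset=max(float(intercept), 0.0),
        fit_range=(0, n_fit_points),
        r_squared=r2,
    )


def fit_anomalous_exponent(msd: MSDCurve, lag_range: tuple[int, int] = (0, 10)) -> float:
    """Anomalous exponent: OLS slope of log MSD versus log lag.

    ``lag_range`` selects lag indices [start, stop) into the curve.
    """
    start, stop = lag_range
    stop = min(stop, len(msd.lags))
    if stop - start < 2:
        raise ValueError("lag_range must select at least 2 lags")
    tau = msd.lags[start:stop]
    y = msd.values[start:stop]
    if np.any(y <= 0):
        raise ValueError("MSD values in lag_range must be positive for log fit")
    slope, _ = np.polyfit(np.log(tau), np.log(y), 1)
    return float(slope)


def fit_tracks(
    tracks: TrajectorySet,
    n_fit_points: int = 4,
    alpha_lag_range: tuple[int, int] = (0, 10),
    min_track_length: int = 10,
) -> pd.DataFrame:
    """Per-track D and alpha estimates, one row per usable track.

    Tracks shorter than ``min_track_length`` frames are excluded (short
    tracks give high-variance fits).  The per-condition summary statistic
    is the mean of the per-track values, not a single pooled fit.
    """
    per_track, _ = compute_msd(tracks, min_track_length=min_track_length)
    rows = []
    for tid, curve in per_track.items():
        if len(curve.lags) < n_fit_points:
            continue
        fit = fit_diffusion_coefficient(curve, n_fit_points=n_fit_points)
        stop = min(alpha_lag_range[1], len(curve.lags))
        alpha = np.nan
        if stop - alpha_lag_range[0] >= 2 and np.all(
            curve.values[alpha_lag_range[0] : stop] > 0
        ):
            alpha = fit_anomalous_exponent(curve, (alpha_lag_range[0], stop))
        rows.append(
            {
                "track_id": tid,
                "D_um2_s": fit.D,
                "noise_offset_um2": fit.noise_offset,
                "alpha": alpha,
                "r2": fit.r_squared,
            }
        )
    return pd.DataFrame(rows, columns=["track_id", "D_um2_s", "noise_offset_um2", "alpha", "r2"])
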