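"""Per-cell immune-synapse quantification and antigen-extraction analysis.

A B cell settling on an antigen-coated bilayer forms a synapse whose
footprint is segmented from a membrane-label channel.  Within it we
measure spread area, antigen intensities and clusters; detect unquenching
events (new fluorescent spots marking force-mediated antigen extraction);
time them relative to first contact; and localize them within three
concentric zones of equal radial width (central / peripheral / distal)
that are recomputed for every frame because the footprint changes as the
cell spreads.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.morphology import disk

from .io import MovieStack
from .spt import Spot, detect_spots, link_tracks

__all__ = [
    "SynapseFrame",
    "ExtractionEvent",
    "SynapseMeasurements",
    "ColocalizationResult",
    "segment_cell",
    "find_contact_time",
    "partition_zones",
    "detect_unquenching_events",
    "assign_event_zones",
    "quantify_synapse",
    "extraction_efficiency",
    "extraction_kinetics",
    "colocalize_clusters",
    "discrimination_ratio",
    "events_to_frame",
]


@dataclass
class SynapseFrame:
    """Segmented cell footprint for one frame.

    ``centroid_um`` is the intensity-weighted centroid (x, y);
    ``zone_boundaries`` are the radial fractions separating the central,
    peripheral and distal zones.
    """

    frame: int
    mask: np.ndarray
    centroid_um: tuple[float, float]
    pixel_size: float
    zone_boundaries: tuple[float, float] = (1.0 / 3.0, 2.0 / 3.0)

    @property
    def area_um2(self) -> float:
        return float(self.mask.sum()) * self.pixel_size**2

    @property
    def r_eq_um(self) -> float:
        """Equivalent-circle radius sqrt(area / pi)."""
        return float(np.sqrt(self.area_um2 / np.pi))


@dataclass
class ExtractionEvent:
    """A rupture (unquenching) event: a new spot persisting in the movie."""

    cell_id: int
    frame: int
    onset_time: float
    x_um: float
    y_um: float
    intensity: float
    distance_to_center_um: float = np.nan
    normalized_distance: float = np.nan
    zone: str | None = None


@dataclass
class SynapseMeasurements:
    """Per-cell synapse summary across channels."""

    cell_id: int
    spread_area_um2: float
    mean_intensity: dict[str, float]
    total_intensity: dict[str, float]
    cluster_table: pd.DataFrame
    extraction_efficiency: float = np.nan
    time_to_first_extraction_s: float = np.nan
    extracted_within_5min: bool = False
    flags: list[str] = field(default_factory=list)


@dataclass
class ColocalizationResult:
    """Per-cluster marker intensities and the percentage above threshold."""

    cluster_marker: pd.DataFrame
    percent_positive: float
    threshold: float
    flags: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# segmentation and zone geometry


def segment_cell(
    frame_image: np.ndarray,
    pixel_size: float,
    frame: int = 0,
    min_area_um2: float = 10.0,
    closing_radius: int = 2,
) -> SynapseFrame | None:
    """Segment the cell footprint from a membrane-label image.

    Background (median) subtraction, Otsu threshold, largest connected
    component, hole filling and morphological closing.  Returns ``None``
    when no component reaches ``min_area_um2`` (no cell in the frame).
    """
    img = np.asarray(frame_image, float)
    background = float(np.median(img))
    sub = img - background
    if sub.max() <= 0:
        return None
    try:
        thr = threshold_otsu(sub)
    except ValueError:
        return None
    mask = sub > thr
    if not mask.any():
        return None
    labels = cc_label(mask)
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    mask = labels == int(np.argmax(sizes))
    mask = ndimage.binary_fill_holes(mask)
    if closing_radius > 0:
        mask = ndimage.binary_closing(mask, structure=disk(closing_radius))
        mask = ndimage.binary_fill_holes(mask)
    area = mask.sum() * pixel_size**2
    if area < min_area_um2:
        return None
    weights = np.clip(sub, 0.0, None) * mask
    total = weights.sum()
    yy, xx = np.mgrid[0 : img.shape[0], 0 : img.shape[1]]
    if total > 0:
        cx = float((xx * weights).sum() / total) * pixel_size
        cy = float((yy * weights).sum() / total) * pixel_size
    else:  # pragma: no cover - degenerate flat mask
        cy, cx = [c * pixel_size for c in ndimage.center_of_mass(mask)]
    return SynapseFrame(frame=frame, mask=mask, centroid_um=(cx, cy), pixel_size=pixel_size)


def _boundary_distance_um(synapse: SynapseFrame, direction: np.ndarray) -> float:
    """Distance from the centroid to the mask boundary along a unit ray (um)."""
    cx, cy = synapse.centroid_um
    px = synapse.pixel_size
    h, w = synapse.mask.shape
    max_dist = float(np.hypot(h, w)) * px

    def inside(t: float) -> bool:
        x = (cx + t * direction[0]) / px
        y = (cy + t * direction[1]) / px
        i, j = int(round(y)), int(round(x))
        return 0 <= i < h and 0 <= j < w and bool(synapse.mask[i, j])

    # coarse march to the first exit, then refine at quarter-pixel resolution
    coarse = px
    t = coarse
    last_inside = 0.0
    while t <= max_dist and inside(t):
        last_inside = t
        t += coarse
    fine = 0.25 * px
    base = last_inside
    t = base + fine
    while t < base + coarse and inside(t):
        last_inside = t
        t += fine
    return last_inside


def partition_zones(
    synapse: SynapseFrame, point_um: tuple[float, float]
) -> tuple[float, str]:
    """Normalized radial distance and zone label of a point in the synapse.

    The distance from the centroid to the point is normalized by the
    distance from the centroid to the mask boundary along the same ray, so
    that the three equal-width zones adapt to non-circular footprints.
    Zone bounds are half-open: exactly 1/3 is peripheral, exactly 2/3 is
    distal.
    """
    cx, cy = synapse.centroid_um
    x, y = point_um
    px = synapse.pixel_size
    i, j = int(round(y / px)), int(round(x / px))
    h, w = synapse.mask.shape
    if i < 0 or j < 0 or i >= h or j >= w or not synapse.mask[i, j]:
        raise ValueError(f"point {point_um} lies outside the cell mask")
    r = float(np.hypot(x - cx, y - cy))
    if r == 0.0:
        return 0.0, "central"
    direction = np.array([(x - cx) / r, (y - cy) / r])
    boundary = _boundary_distance_um(synapse, direction)
    if boundary <= 0:
        return 0.0, "central"
    norm = min(r / boundary, 1.0)
    b1, b2 = synapse.zone_boundaries
    if norm < b1:
        zone = "central"
    elif norm < b2:
        zone = "peripheral"
    else:
        zone = "distal"
    return norm, zone


# ---------------------------------------------------------------------------
# unquenching-event detection


def find_contact_time(
    membrane_movie: MovieStack, min_area_um2: float = 10.0
) -> float | None:
    """First bilayer-contact time: first frame whose segmented area exceeds
    ``min_area_um2``.  Returns ``None`` when the cell never lands."""
    for f in range(membrane_movie.n_frames):
        seg = segment_cell(
            membrane_movie.pixels[f],
            membrane_movie.pixel_size,
            frame=f,
            min_area_um2=min_area_um2,
        )
        if seg is not None:
            return membrane_movie.frame_time(f)
    return None


def detect_unquenching_events(
    movie: MovieStack,
    contact_time: float = 0.0,
    min_persist_frames: int = 3,
    psf_sigma_px: float | None = None,
    snr_threshold: float = 5.0,
    cell_id: int = 0,
) -> list[ExtractionEvent]:
    """Detect antigen-extraction (unquenching) events in a spot channel.

    Spots are detected per frame and linked; a track qualifies as an event
    when its first detection occurs after frame 0, no spot was present at
    the same location (within two PSF widths) during the preceding
    ``min_persist_frames`` frames, and the track persists for at least
    ``min_persist_frames`` frames.  Onset time is the first-detection frame
    time minus ``contact_time``; the intensity is taken from the first
    detection frame.
    """
    if contact_time >= movie.n_frames * movie.frame_interval:
        raise ValueError("contact_time is outside the movie duration")
    sigma = psf_sigma_px if psf_sigma_px is not None else 1.3
    spots_by_frame: list[list[Spot]] = [
        detect_spots(movie.pixels[f], psf_sigma=sigma, snr_threshold=snr_threshold, frame_index=f)
        for f in range(movie.n_frames)
    ]
    tracks = link_tracks(
        spots_by_frame,
        max_disp=2.0 * sigma,
        max_gap=1,
        dt=movie.frame_interval,
        pixel_size=movie.pixel_size,
    )
    events: list[ExtractionEvent] = []
    min_sep2 = (2.0 * sigma) ** 2
    for tid, frames, positions_um in tracks.iter_tracks():
        f0 = int(frames[0])
        if f0 == 0:
            continue  # fluorophore already present at movie start
        if len(frames) < min_persist_frames:
            continue  # blink
        x_px = positions_um[0, 0] / movie.pixel_size
        y_px = positions_um[0, 1] / movie.pixel_size
        preceding = range(max(0, f0 - min_persist_frames), f0)
        fresh = True
        for f in preceding:
            for s in spots_by_frame[f]:
                if (s.x - x_px) ** 2 + (s.y - y_px) ** 2 < min_sep2:
                    fresh = False
                    break
            if not fresh:
                break
        if not fresh:
            continue
        first_row = tracks.data[(tracks.data["track_id"] == tid)].sort_values("frame").iloc[0]
        events.append(
            ExtractionEvent(
                cell_id=cell_id,
                frame=f0,
                onset_time=movie.frame_time(f0) - contact_time,
                x_um=float(positions_um[0, 0]),
                y_um=float(positions_um[0, 1]),
                intensity=float(first_row.get("intensity", np.nan)),
            )
        )
    events.sort(key=lambda e: (e.frame, e.x_um))
    return events


def assign_event_zones(
    events: list[ExtractionEvent], synapse_frames: dict[int, SynapseFrame]
) -> list[ExtractionEvent]:
    """Fill distance/zone fields of events using the frame-matched footprint.

    Zones are recomputed per frame from the footprint current at each
    event's detection frame.  Events falling outside the mask of their
    frame (or in frames with no segmented cell) are left unassigned.
    """
    for event in events:
        synapse = synapse_frames.get(event.frame)
        if synapse is None:
            continue
        cx, cy = synapse.centroid_um
        event.distance_to_center_um = float(np.hypot(event.x_um - cx, event.y_um - cy))
        try:
            norm, zone = partition_zones(synapse, (event.x_um, event.y_um))
        except ValueError:
            continue
        event.normalized_distance = norm
        event.zone = zone
    return events


def events_to_frame(events: list[ExtractionEvent]) -> pd.DataFrame:
    """Tabulate events for CSV output."""
    return pd.DataFrame(
        [
            {
                "cell_id": e.cell_id,
                "frame": e.frame,
                "onset_time_s": e.onset_time,
                "x_um": e.x_um,
                "y_um": e.y_um,
                "intensity": e.intensity,
                "distance_to_center_um": e.distance_to_center_um,
                "normalized_distance": e.normalized_distance,
                "zone": e.zone,
            }
            for e in events
        ],
        columns=[
            "cell_id",
            "frame",
            "onset_time_s",
            "x_um",
            "y_um",
            "intensity",
            "distance_to_center_um",
            "normalized_distance",
            "zone",
        ],
    )


# ---------------------------------------------------------------------------
# intensity quantification


def _background_stats(image: np.ndarray, mask: np.ndarray) -> tuple[float, float]:
    """Median and robust sd of pixels outside the cell mask."""
    outside = image[~mask]
    if outside.size == 0:
        return 0.0, 0.0
    med = float(np.median(outside))
    sd = 1.4826 * float(np.median(np.abs(outside - med)))
    return med, sd


def quantify_synapse(
    channels: dict[str, np.ndarray],
    synapse: SynapseFrame,
    cell_id: int = 0,
    cluster_channel: str | None = None,
    cluster_k: float = 3.0,
    min_cluster_area_px: int = 4,
) -> SynapseMeasurements:
    """Mean/total intensity per channel inside the footprint, plus clusters.

    Intensities are background-subtracted using the median of pixels
    outside the mask.  Clusters in ``cluster_channel`` are connected
    components above background + ``cluster_k`` robust sd with at least
    ``min_cluster_area_px`` pixels; each contributes its area and
    integrated (background-subtracted) intensity.
    """
    mask = synapse.mask
    n_px = int(mask.sum())
    means: dict[str, float] = {}
    totals: dict[str, float] = {}
    for name, image in channels.items():
        image = np.asarray(image, float)
        if image.shape != mask.shape:
            raise ValueError(f"channel {name!r} shape {image.shape} != mask {mask.shape}")
        bg, _ = _background_stats(image, mask)
        inside = image[mask] - bg
        mean = float(np.clip(inside.mean(), 0.0, None)) if n_px else 0.0
        means[name] = mean
        totals[name] = mean * n_px
    clusters = pd.DataFrame(columns=["cluster_id", "area_px", "area_um2", "total_intensity"])
    if cluster_channel is not None:
        image = np.asarray(channels[cluster_channel], float)
        bg, sd = _background_stats(image, mask)
        above = (image > bg + cluster_k * sd) & mask
        labels = cc_label(above)
        rows = []
        for cid in range(1, labels.max() + 1):
            sel = labels == cid
            area = int(sel.sum())
            if area < min_cluster_area_px:
                continue
            rows.append(
                {
                    "cluster_id": cid,
                    "area_px": area,
                    "area_um2": area * synapse.pixel_size**2,
                    "total_intensity": float((image[sel] - bg).sum()),
                }
            )
        if rows:
            clusters = pd.DataFrame(rows)
    return SynapseMeasurements(
        cell_id=cell_id,
        spread_area_um2=synapse.area_um2,
        mean_intensity=means,
        total_intensity=totals,
        cluster_table=clusters,
    )


def extraction_efficiency(internalized_total: float, bound_total: float) -> float:
    """Ratio of internalized to membrane-bound antigen intensity per cell.

    Returns NaN when the bound total is non-positive (undefined ratio).
    """
    if bound_total <= 0:
        return np.nan
    return internalized_total / bound_total


def extraction_kinetics(
    events: pd.DataFrame,
    cell_ids: list[int],
    within_s: float = 300.0,
) -> tuple[pd.DataFrame, float]:
    """Per-cell time to first extraction and the cohort fraction within 5 min.

    ``events`` needs columns ``cell_id`` and ``onset_time_s`` (seconds since
    first bilayer contact).  Cells with no events have a missing
    time-to-first but still count in the denominator of the fraction.
    """
    per_cell = []
    n_within = 0
    for cid in cell_ids:
        sel = events[events["cell_id"] == cid] if len(events) else events
        if len(sel):
            t_first = float(sel["onset_time_s"].min())
            within = t_first <= within_s
        else:
            t_first, within = np.nan, False
        n_within += int(within)
        per_cell.append(
            {"cell_id": cid, "time_to_first_s": t_first, "within_window": within}
        )
    if not cell_ids:
        raise ValueError("need at least one cell")
    return pd.DataFrame(per_cell), n_within / len(cell_ids)


def colocalize_clusters(
    cluster_labels: np.ndarray,
    marker_image: np.ndarray,
    threshold: float | None = None,
    threshold_k: float = 2.0,
) -> ColocalizationResult:
    """Mean marker intensity per cluster and the percentage above threshold.

    ``cluster_labels`` is a label image of internalized-antigen clusters
    (0 = background).  The default threshold is the marker background mean
    plus ``threshold_k`` sd, estimated from pixels outside all clusters.
    """
    labels = np.asarray(cluster_labels)
    marker = np.asarray(marker_image, float)
    if labels.shape != marker.shape:
        raise ValueError("label image and marker image must share shape")
    ids = np.unique(labels)
    ids = ids[ids > 0]
    outside = marker[labels == 0]
    bg_mean = float(outside.mean()) if outside.size else 0.0
    bg_sd = float(outside.std()) if outside.size else 0.0
    if threshold is None:
        threshold = bg_mean + threshold_k * bg_sd
    rows = []
    for cid in ids:
        mean_marker = float(marker[labels == cid].mean())
        rows.append(
            {"cluster_id": int(cid), "marker_mean": mean_marker, "positive": mean_marker > threshold}
        )
    table = pd.DataFrame(rows, columns=["cluster_id", "marker_mean", "positive"])
    if len(table):
        percent = 100.0 * float(table["positive"].mean())
        flags = []
    else:
        percent = np.nan
        flags = ["no_clusters"]
    return ColocalizationResult(
        cluster_marker=table, percent_positive=percent, threshold=float(threshold), flags=flags
    )


def discrimination_ratio(
    high_affinity: pd.DataFrame,
    low_affinity: pd.DataFrame,
) -> tuple[float, float, pd.DataFrame]:
    """Affinity-discrimination ratio of extracted antigen, experiment-paired.

    Inputs are per-cell tables with columns ``experiment_id`` and
    ``value`` (extracted antigen per cell).  Cells are first averaged per
    experiment, the high/low ratio is formed per experiment, and the
    cross-experiment mean and SEM of those ratios are returned together
    with the per-experiment table.
    """
    if not len(high_affinity) or not len(low_affinity):
        raise ValueError("both cohorts must be non-empty")
    hi = high_affinity.groupby("experiment_id")["value"].mean()
    lo = low_affinity.groupby("experiment_id")["value"].mean()
    shared = hi.index.intersection(lo.index)
    if len(shared) == 0:
        raise ValueError("no shared experiments between cohorts")
    ratios = []
    for exp in shared:
        if lo[exp] == 0:
            ratios.append(np.inf)
        else:
            ratios.append(hi[exp] / lo[exp])
    table = pd.DataFrame(
        {"experiment_id": list(shared), "mean_high": hi[shared].values,
         "mean_low": lo[shared].values, "ratio": ratios}
    )
    finite = np.asarray([r for r in ratios if np.isfinite(r)], float)
    mean = float(finite.mean()) if finite.size else np.inf
    sem = float(finite.std(ddof=1) / np.sqrt(len(finite))) if finite.size > 1 else np.nan
    return mean, sem, table
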