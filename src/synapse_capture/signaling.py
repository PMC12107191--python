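"""Calcium-trace summaries and transcription-factor translocation scoring.

Antigen binding triggers calcium release whose amplitude and temporal
pattern encode signaling strength.  Traces are normalized to dF/F against
the pre-contact baseline, summarized by the area under the curve and the
delay to peak, and classified into four patterns: oscillatory (repeated
transients), maintained (sustained plateau), unique (a single transient)
and nonresponsive.  Downstream activation of NF-kB / NFAT is scored per
cell as the nuclear-to-cytoplasmic mean intensity ratio; a ratio strictly
greater than 1 defines an activated cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

__all__ = [
    "CalciumTrace",
    "CalciumSummary",
    "TranslocationMeasure",
    "PATTERNS",
    "summarize_calcium",
    "classify_calcium_pattern",
    "measure_translocation",
    "activated_fraction",
]

PATTERNS = ("oscillatory", "maintained", "unique", "nonresponsive")


@dataclass
class CalciumTrace:
    """A raw single-cell calcium trace with its contact time."""

    times: np.ndarray
    values: np.ndarray
    contact_time: float = 0.0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, float)
        self.values = np.asarray(self.values, float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must share shape")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    def baseline(self) -> float:
        """Pre-contact mean fluorescence F0."""
        pre = self.values[self.times < self.contact_time]
        if pre.size == 0:
            pre = self.values[:1]
        return float(pre.mean())

    def dff(self) -> np.ndarray:
        f0 = self.baseline()
        if f0 <= 0:
            raise ValueError("baseline must be positive to compute dF/F")
        return (self.values - f0) / f0


@dataclass
class CalciumSummary:
    auc: float
    delay_to_peak: float
    responder: bool
    n_peaks: int = 0
    pattern: str = ""


@dataclass
class TranslocationMeasure:
    """Nuclear and cytoplasmic mean intensities and their ratio."""

    i_nuc: float
    i_cyt: float
    flags: list[str] = field(default_factory=list)

    @property
    def ratio(self) -> float:
        return self.i_nuc / self.i_cyt if self.i_cyt > 0 else np.nan

    @property
    def activated(self) -> bool:
        return bool(self.ratio > 1.0)


def summarize_calcium(
    trace: CalciumTrace,
    response_threshold: float = 0.5,
    sustained_frames: int = 2,
) -> CalciumSummary:
    """AUC, delay to peak and responder call for one trace.

    dF/F is computed against the pre-contact baseline; the AUC integrates
    the positive part of dF/F after contact (trapezoid rule); the delay is
    the time from contact to the global dF/F maximum.  A cell is a
    responder when dF/F reaches ``response_threshold`` for at least
    ``sustained_frames`` consecutive frames.
    """
    if len(trace.times) < 10:
        raise ValueError("need at least 10 timepoints")
    dff = trace.dff()
    post = trace.times >= trace.contact_time
    t_post = trace.times[post]
    dff_post = dff[post]
    if t_post.size < 2:
        raise ValueError("no post-contact samples")
    auc = float(np.trapezoid(np.clip(dff_post, 0.0, None), t_post))
    i_peak = int(np.argmax(dff_post))
    delay = float(t_post[i_peak] - trace.contact_time)
    above = dff_post >= response_threshold
    responder = False
    run = 0
    for flag in above:
        run = run + 1 if flag else 0
        if run >= sustained_frames:
            responder = True
            break
    return CalciumSummary(auc=auc, delay_to_peak=delay, responder=responder)


def classify_calcium_pattern(
    trace: CalciumTrace,
    summary: CalciumSummary | None = None,
    response_threshold: float = 0.5,
    min_peak_separation: float = 10.0,
    oscillatory_min_peaks: int = 3,
    plateau_level: float = 0.5,
    plateau_fraction: float = 0.5,
) -> str:
    """Assign one of the four response patterns to a trace.

    Nonresponders are called first from the summary.  For responders,
    peaks with prominence at least half the dF/F maximum and separated by
    ``min_peak_separation`` seconds are counted: >= 3 peaks is
    oscillatory; fewer peaks with dF/F held above ``plateau_level`` of the
    maximum for at least ``plateau_fraction`` of the post-onset trace is
    maintained; anything else is unique.
    """
    if summary is None:
        summary = summarize_calcium(trace, response_threshold=response_threshold)
    if not summary.responder:
        summary.pattern = "nonresponsive"
        summary.n_peaks = 0
        return "nonresponsive"
    dff = trace.dff()
    post = trace.times >= trace.contact_time
    t_post = trace.times[post]
    dff_post = dff[post]
    dt = float(np.median(np.diff(t_post)))
    distance = max(1, int(round(min_peak_separation / dt)))
    peak_height = max(dff_post.max() * 0.5, response_threshold)
    peaks, _ = find_peaks(
        dff_post,
        prominence=0.5 * dff_post.max(),
        distance=distance,
        height=peak_height,
    )
    summary.n_peaks = len(peaks)
    if len(peaks) >= oscillatory_min_peaks:
        summary.pattern = "oscillatory"
        return "oscillatory"
    # onset = first crossing of the response threshold
    onset_idx = int(np.argmax(dff_post >= response_threshold))
    tail = dff_post[onset_idx:]
    frac_high = float(np.mean(tail >= plateau_level * dff_post.max())) if tail.size else 0.0
    if frac_high >= plateau_fraction:
        summary.pattern = "maintained"
        return "maintained"
    summary.pattern = "unique"
    return "unique"


def measure_translocation(
    image: np.ndarray,
    nuclear_mask: np.ndarray,
    cyto_mask: np.ndarray,
    background: float = 0.0,
) -> TranslocationMeasure:
    """Background-subtracted compartment means and their N/C ratio."""
    image = np.asarray(image, float)
    nuclear_mask = np.asarray(nuclear_mask, bool)
    cyto_mask = np.asarray(cyto_mask, bool)
    if nuclear_mask.shape != image.shape or cyto_mask.shape != image.shape:
        raise ValueError("masks must match the image shape")
    if np.any(nuclear_mask & cyto_mask):
        raise ValueError("nuclear and cytoplasmic masks must be disjoint")
    if not nuclear_mask.any() or not cyto_mask.any():
        raise ValueError("both masks must be non-empty")
    i_nuc = float(image[nuclear_mask].mean() - background)
    i_cyt = float(image[cyto_mask].mean() - background)
    flags = [] if i_cyt > 0 else ["nonpositive_cytoplasm"]
    return TranslocationMeasure(i_nuc=i_nuc, i_cyt=i_cyt, flags=flags)


def activated_fraction(measures: list[TranslocationMeasure]) -> float:
    """Percent of cells with N/C ratio strictly above 1."""
    if not measures:
        raise ValueError("need at least one measurement")
    return 100.0 * float(np.mean([m.activated for m in measures]))
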