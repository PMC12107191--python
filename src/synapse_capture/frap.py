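"""FRAP normalization and recovery fitting.

Fluorescence recovery after photobleaching reports membrane fluidity: a
bleached region refills by lateral diffusion of unbleached fluorophores.
The recovery is summarized by the mobile fraction (how much of the signal
is recoverable) and the half-time t_half.  A fluid DOPC bilayer recovers
almost completely within tens of seconds; a gel-phase DPPC bilayer barely
recovers at all.

The default model is a single-exponential recovery written in half-time
form, F(t) = F0 + (Fp - F0) * (1 - 2**(-t / t_half)), with mobile fraction
(Fp - F0) / (1 - F0) under pre-bleach-normalized units.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "RecoveryCurve",
    "RecoveryFit",
    "recovery_model",
    "normalize_recovery",
    "fit_recovery",
]


@dataclass
class RecoveryCurve:
    """A normalized recovery trace: times in s (0 at bleach), pre-bleach = 1."""

    times: np.ndarray
    values: np.ndarray
    bleach_index: int = 0
    n_prebleach: int = 1

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, float)
        self.values = np.asarray(self.values, float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have the same shape")
        if np.any(np.diff(self.times) < 0):
            raise ValueError("times must be non-decreasing")
        if self.n_prebleach < 1:
            raise ValueError("need at least one pre-bleach frame")

    def post_bleach(self) -> tuple[np.ndarray, np.ndarray]:
        """Times and values from the bleach frame on, times shifted to 0."""
        i = self.bleach_index
        return self.times[i:] - self.times[i], self.values[i:]


@dataclass
class RecoveryFit:
    """Fitted recovery parameters; ``recovery_percent`` = 100 x mobile fraction."""

    mobile_fraction: float
    t_half: float
    F0: float
    F_plateau: float
    rmse: float
    flags: list[str] = field(default_factory=list)

    @property
    def recovery_percent(self) -> float:
        return 100.0 * self.mobile_fraction


def recovery_model(t: np.ndarray, F0: float, Fp: float, t_half: float) -> np.ndarray:
    """Single-exponential recovery in half-time form."""
    return F0 + (Fp - F0) * (1.0 - np.power(2.0, -np.asarray(t, float) / t_half))


def normalize_recovery(
    bleach_roi_trace: np.ndarray,
    reference_roi_trace: np.ndarray,
    prebleach_frames: int,
    times: np.ndarray | None = None,
) -> RecoveryCurve:
    """Double-normalize a bleach-ROI trace.

    The bleach trace is divided by a reference ROI trace (correcting for
    acquisition photobleaching of the whole field), then by its own
    pre-bleach mean so that the pre-bleach level is exactly 1.  The bleach
    frame is taken to be ``prebleach_frames`` (0-based), i.e. the first
    frame after the pre-bleach window.
    """
    bleach = np.asarray(bleach_roi_trace, float)
    ref = np.asarray(reference_roi_trace, float)
    if bleach.shape != ref.shape:
        raise ValueError("bleach and reference traces must share shape")
    if prebleach_frames < 1 or prebleach_frames >= len(bleach):
        raise ValueError("prebleach_frames must leave at least one post-bleach frame")
    if np.any(ref <= 0):
        raise ValueError("reference trace must be strictly positive")
    corrected = bleach / ref
    pre_mean = corrected[:prebleach_frames].mean()
    if pre_mean <= 0:
        raise ValueError("pre-bleach mean must be positive")
    values = corrected / pre_mean
    if times is None:
        times = np.arange(len(bleach), dtype=float)
    times = np.asarray(times, float) - np.asarray(times, float)[prebleach_frames]
    return RecoveryCurve(
        times=times,
        values=values,
        bleach_index=prebleach_frames,
        n_prebleach=prebleach_frames,
    )


def read_roi_traces(path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Read (t_s, bleach_roi, reference_roi) columns from a CSV file."""
    df = pd.read_csv(path)
    return df["t_s"].to_numpy(), df["bleach_roi"].to_numpy(), df["reference_roi"].to_numpy()


def fit_recovery(curve: RecoveryCurve) -> RecoveryFit:
    """Nonlinear least-squares fit of the single-exponential recovery.

    Initial guesses: F0 from the first post-bleach value, plateau from the
    last value, t_half from the first crossing of the midpoint.  A plateau
    at or below the floor is reported as mobile_fraction 0 with a flag
    rather than an error (the immobile, gel-phase regime).
    """
    t, y = curve.post_bleach()
    if len(t) < 4:
        raise ValueError("need at least 4 post-bleach points")
    f0_guess = float(y[0])
    fp_guess = float(y[-1])
    flags: list[str] = []
    if fp_guess <= f0_guess:
        resid = y - y.mean()
        return RecoveryFit(
            mobile_fraction=0.0,
            t_half=np.nan,
            F0=f0_guess,
            F_plateau=fp_guess,
            rmse=float(np.sqrt((resid**2).mean())),
            flags=["no_recovery"],
        )
    midpoint = 0.5 * (f0_guess + fp_guess)
    above = np.nonzero(y >= midpoint)[0]
    th_guess = float(t[above[0]]) if above.size and t[above[0]] > 0 else float(t[-1]) / 4 or 1.0
    try:
        popt, _ = curve_fit(
            recovery_model,
            t,
            y,
            p0=[f0_guess, fp_guess, th_guess],
            bounds=([-np.inf, -np.inf, 1e-9], [np.inf, np.inf, np.inf]),
            maxfev=20000,
        )
    except RuntimeError as err:  # pragma: no cover - solver pathologies
        raise RuntimeError(f"recovery fit failed to converge: {err}") from err
    F0, Fp, t_half = map(float, popt)
    mobile = (Fp - F0) / (1.0 - F0) if F0 < 1.0 else np.nan
    if not np.isfinite(mobile):
        flags.append("invalid_prebleach_floor")
        mobile = 0.0
    mobile = float(np.clip(mobile, 0.0, None))
    resid = y - recovery_model(t, *popt)
    return RecoveryFit(
        mobile_fraction=mobile,
        t_half=t_half,
        F0=F0,
        F_plateau=Fp,
        rmse=float(np.sqrt((resid**2).mean())),
        flags=flags,
    )
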