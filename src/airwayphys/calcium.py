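"""Fura-2 ratiometric calcium analysis.

Converts dual-excitation (340/380 nm) fluorescence to intracellular Ca2+
concentration with the Grynkiewicz calibration,

    [Ca2+] = Kd * beta * (R - Rmin) / (Rmax - R),

and summarises traces: basal concentration over a pre-stimulus window and
the rate of the Ca2+ undershoot that follows caffeine withdrawal, a readout
of SERCA-mediated sarcoplasmic-reticulum refilling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CalibrationConstants",
    "FluorometryTrace",
    "UndershootResult",
    "ratio_trace",
    "grynkiewicz",
    "inverse_grynkiewicz",
    "basal_level",
    "undershoot_rate",
]


@dataclass(frozen=True)
class CalibrationConstants:
    """Fura-2 calibration constants.

    Parameters
    ----------
    kd : float
        Fura-2 dissociation constant, nM.
    rmin, rmax : float
        340/380 ratio at zero and saturating Ca2+ (dimensionless).
        ``rmax`` here is the calibration ceiling of the ratio, not the
        obstruction outcome of the same name.
    beta : float
        Ratio of 380-nm fluorescence in Ca2+-free over Ca2+-saturated
        conditions (dimensionless).
    """

    kd: float = 386.0
    rmin: float = 0.5
    rmax: float = 11.7
    beta: float = 7.5

    def __post_init__(self) -> None:
        if not (self.kd > 0 and self.beta > 0):
            raise ValueError("Kd and beta must be positive")
        if not (0 < self.rmin < self.rmax):
            raise ValueError("require 0 < Rmin < Rmax")


@dataclass
class FluorometryTrace:
    """Paired 340/380 fluorescence channels with per-channel background."""

    time: np.ndarray  # s
    f340: np.ndarray  # a.u.
    f380: np.ndarray  # a.u.
    b340: float = 0.0
    b380: float = 0.0
    meta: dict = field(default_factory=dict)

    def ratio(self) -> np.ndarray:
        return ratio_trace(self.f340, self.f380, self.b340, self.b380)

    def calcium(self, constants: CalibrationConstants) -> np.ndarray:
        return grynkiewicz(self.ratio(), constants)


def ratio_trace(f340, f380, b340: float = 0.0, b380: float = 0.0) -> np.ndarray:
    """Background-subtracted 340/380 ratio.

    Samples whose corrected 380 channel is <= 0 are undefined and returned
    as NaN; an all-undefined trace triggers a warning, not an exception.
    """
    f340 = np.asarray(f340, dtype=float)
    f380 = np.asarray(f380, dtype=float)
    if f340.shape != f380.shape:
        raise ValueError("channels must be time-aligned (equal length)")
    if b340 < 0 or b380 < 0:
        raise ValueError("backgrounds must be non-negative")
    denom = f380 - b380
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(denom > 0, (f340 - b340) / denom, np.nan)
    if r.size and np.all(np.isnan(r)):
        warnings.warn("degenerate 380 channel: entire ratio trace undefined")
    return r


def grynkiewicz(r, constants: CalibrationConstants = CalibrationConstants()) -> np.ndarray:
    """Convert a 340/380 ratio to [Ca2+] in nM.

    Strictly monotone increasing on [Rmin, Rmax). Ratios at or above Rmax
    (dye saturation, where the formula diverges) are flagged as NaN; ratios
    below Rmin are clamped to 0 nM with a warning.
    """
    r = np.asarray(r, dtype=float)
    c = constants
    out = np.full(r.shape, np.nan)
    low = r < c.rmin
    ok = (r >= c.rmin) & (r < c.rmax)
    out[ok] = c.kd * c.beta * (r[ok] - c.rmin) / (c.rmax - r[ok])
    if np.any(low):
        warnings.warn(f"{int(low.sum())} sample(s) below Rmin clamped to 0 nM")
        out[low] = 0.0
    return out


def inverse_grynkiewicz(ca, constants: CalibrationConstants = CalibrationConstants()) -> np.ndarray:
    """Ratio that the Grynkiewicz formula maps to the given [Ca2+] (nM)."""
    ca = np.asarray(ca, dtype=float)
    if np.any(ca < 0):
        raise ValueError("Ca2+ concentrations must be non-negative")
    c = constants
    return (ca * c.rmax + c.kd * c.beta * c.rmin) / (ca + c.kd * c.beta)


def basal_level(ca, time, window: tuple[float, float]) -> float:
    """Mean [Ca2+] over a pre-stimulus window, flagged samples excluded.

    Raises if the window contains no defined samples.
    """
    ca = np.asarray(ca, dtype=float)
    time = np.asarray(time, dtype=float)
    lo, hi = window
    sel = (time >= lo) & (time < hi)
    vals = ca[sel]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("empty basal window: no defined samples")
    return float(vals.mean())


@dataclass
class UndershootResult:
    """Outcome of the post-caffeine undershoot slope fit."""

    rate: float  # nM/s, magnitude of the decline slope; NaN if no undershoot
    t_start: float
    t_min: float
    undershoot: bool


def undershoot_rate(
    ca,
    time,
    withdrawal_time: float,
    baseline: float,
    search_window: float = 60.0,
    method: str = "fit",
    initial_span: float = 5.0,
) -> UndershootResult:
    """Rate of the Ca2+ decline into the post-caffeine undershoot, nM/s.

    Within ``search_window`` seconds after caffeine withdrawal, the decline
    segment runs from the post-withdrawal maximum to the undershoot minimum.
    The returned rate is the magnitude of the least-squares linear slope
    over that segment (``method='fit'``) or over its first ``initial_span``
    seconds (``method='initial'``). If the minimum never drops below the
    pre-caffeine baseline the trace is flagged as having no undershoot.
    """
    ca = np.asarray(ca, dtype=float)
    time = np.asarray(time, dtype=float)
    if time[-1] < withdrawal_time + 30.0:
        raise ValueError("trace must extend at least 30 s past caffeine withdrawal")
    sel = (time >= withdrawal_time) & (time <= withdrawal_time + search_window)
    t, y = time[sel], ca[sel]
    finite = np.isfinite(y)
    t, y = t[finite], y[finite]
    if t.size < 4:
        raise ValueError("too few defined samples after withdrawal")
    imin = int(np.argmin(y))
    if y[imin] >= baseline:
        return UndershootResult(np.nan, np.nan, np.nan, undershoot=False)
    imax = int(np.argmax(y[: imin + 1])) if imin > 0 else 0
    ts, ys = t[imax : imin + 1], y[imax : imin + 1]
    if method == "initial":
        keep = ts <= ts[0] + initial_span
        ts, ys = ts[keep], ys[keep]
    elif method != "fit":
        raise ValueError(f"unknown method {method!r}")
    if ts.size < 2:
        return UndershootResult(np.nan, float(t[imax]), float(t[imin]), undershoot=False)
    slope = np.polyfit(ts, ys, 1)[0]
    return UndershootResult(abs(float(slope)), float(t[imax]), float(t[imin]), undershoot=True)
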