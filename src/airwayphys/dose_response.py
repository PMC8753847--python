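"""Histamine dose-response curves and PD200 airway responsiveness.

PD200 is the interpolated provocative dose at which the bronchoobstructive
index (Bi) reaches three times its baseline value. Curves are built from
non-cumulative doses (0.001-0.1 mg/ml); interpolation is linear in log10
dose by default, because the schedule spans two decades. The PD200 ratio
(post-challenge / pre-challenge) classifies responsiveness: a ratio below 1
is hyperresponsive, above 1 hyporesponsive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["PD200Result", "RatioResult", "pd200", "pd200_ratio", "post_dose_response"]

#: Bi threshold as a multiple of baseline ("three-fold increase")
THRESHOLD_FOLD = 3.0


@dataclass(frozen=True)
class PD200Result:
    dose: float  # mg/ml
    threshold: float  # Bi at which the curve is read off
    censored: str | None  # None | "low" (first dose already over) | "high" (never reached)


@dataclass(frozen=True)
class RatioResult:
    ratio: float
    responsiveness: str  # hyperresponsive | hyporesponsive | unchanged
    censored: bool


def pd200(baseline: float, steps, log_dose: bool = True) -> PD200Result:
    """Interpolated dose producing a three-fold Bi increase over baseline.

    ``steps`` is an ordered sequence of (dose mg/ml, post-dose Bi) pairs with
    strictly increasing doses. The first step at or above threshold is
    bracketed with its predecessor and the dose interpolated at
    Bi = 3 * baseline (on log10 dose unless ``log_dose`` is False).
    Censoring: threshold never reached -> censored "high" at the top dose;
    reached already at the first dose -> censored "low" at the bottom dose.
    """
    if baseline <= 0:
        raise ValueError("baseline Bi must be positive")
    steps = list(steps)
    if not steps:
        raise ValueError("need at least one dose step")
    doses = np.array([d for d, _ in steps], dtype=float)
    bis = np.array([b for _, b in steps], dtype=float)
    if np.any(doses <= 0):
        raise ValueError("doses must be positive")
    if np.any(np.diff(doses) <= 0):
        raise ValueError("doses must be strictly increasing")
    threshold = THRESHOLD_FOLD * baseline
    hit = np.flatnonzero(bis >= threshold)
    if hit.size == 0:
        return PD200Result(float(doses[-1]), threshold, censored="high")
    k = int(hit[0])
    if bis[k] == threshold:
        return PD200Result(float(doses[k]), threshold, censored=None)
    if k == 0:
        return PD200Result(float(doses[0]), threshold, censored="low")
    x = np.log10(doses) if log_dose else doses
    frac = (threshold - bis[k - 1]) / (bis[k] - bis[k - 1])
    xi = x[k - 1] + frac * (x[k] - x[k - 1])
    dose = 10.0 ** xi if log_dose else xi
    return PD200Result(float(dose), threshold, censored=None)


def pd200_ratio(post: PD200Result | float, pre: PD200Result | float) -> RatioResult:
    """PD200 ratio = post-challenge / pre-challenge dose, with class label.

    Censoring on either input propagates to the ratio flag; a post dose
    censored high makes the ratio a lower bound only, etc.
    """
    post_dose, post_cens = _unpack(post)
    pre_dose, pre_cens = _unpack(pre)
    if post_dose <= 0 or pre_dose <= 0:
        raise ValueError("PD200 doses must be positive")
    ratio = post_dose / pre_dose
    if ratio < 1:
        cls = "hyperresponsive"
    elif ratio > 1:
        cls = "hyporesponsive"
    else:
        cls = "unchanged"
    return RatioResult(float(ratio), cls, censored=post_cens or pre_cens)


def _unpack(x) -> tuple[float, bool]:
    if isinstance(x, PD200Result):
        return x.dose, x.censored is not None
    return float(x), False


def post_dose_response(window_start, window_bi, dose_time: float, span: float = 600.0, stat: str = "max") -> float:
    """Bi response to one dose: summary of the 15-s window means in the
    ``span`` seconds after dose delivery (maximum by convention; mean via
    ``stat='mean'``)."""
    window_start = np.asarray(window_start, dtype=float)
    window_bi = np.asarray(window_bi, dtype=float)
    sel = (window_start >= dose_time) & (window_start < dose_time + span)
    if not sel.any():
        raise ValueError("no Bi windows in the post-dose span")
    vals = window_bi[sel]
    if stat == "max":
        return float(vals.max())
    if stat == "mean":
        return float(vals.mean())
    raise ValueError(f"unknown stat {stat!r}")
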