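"""Breath-by-breath analysis of whole-body plethysmograph recordings.

Segments a flow-like box signal into breaths, extracts per-breath timing,
pressure and volume features, applies the study's inclusion filters, and
computes the bronchoobstructive index

    Bi = ((Te - Rt) / Rt) * (PEP / PIP)

per breath, the enhanced-pause (Penh) form of the obstruction index. Bi is
then aggregated as 15-s window means averaged over the last 5 min of each
recording period, and session summaries (Rmax, change in baseline Bi)
are assembled from period values.

Sign convention: inspiration is the positive lobe of the signal, expiration
the negative lobe. PIP and PEP are the unsigned lobe extrema, so Bi is
invariant under uniform rescaling of the signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BreathRecord",
    "BiSeries",
    "ChallengeSession",
    "FilterRules",
    "segment_breaths",
    "breath_features",
    "compute_bi",
    "apply_breath_filters",
    "aggregate_bi",
    "session_summary",
]

#: fraction of the expired tidal volume used to define the relaxation time
#: (the enhanced-pause convention: Rt = time to expire 64% of TVe)
RT_VOLUME_FRACTION = 0.64


@dataclass
class BreathRecord:
    """Features of one segmented breath."""

    start: float
    end: float
    ti: float = np.nan  # inspiratory time, s
    te: float = np.nan  # expiratory time, s
    rt: float = np.nan  # relaxation time, s
    pip: float = np.nan  # peak inspiratory deflection (signal units)
    pep: float = np.nan  # peak expiratory deflection (signal units)
    tvi: float = np.nan  # inspired volume (integral of the positive lobe)
    tve: float = np.nan  # expired volume (integral of the negative lobe)
    bi: float = np.nan
    qc_pass: bool = True
    qc_reason: str | None = None


@dataclass
class BiSeries:
    """Non-overlapping 15-s window means of per-breath Bi."""

    window_start: np.ndarray
    bi_mean: np.ndarray
    period: str = ""


@dataclass
class ChallengeSession:
    """Period-level summary of one provocation session."""

    baseline_bi: float
    post_times: list[float]
    post_bi: list[float]
    rmax_obstruction: float
    delta_baseline_bi: float


def segment_breaths(time, signal) -> list[slice]:
    """Split a uniformly sampled flow-like signal into breath segments.

    A breath starts at each signed zero-crossing into the positive
    (inspiratory) lobe and runs to the next such onset. A flat signal yields
    an empty list; non-uniform sampling is rejected.
    """
    time = np.asarray(time, dtype=float)
    signal = np.asarray(signal, dtype=float)
    if time.size != signal.size:
        raise ValueError("time and signal must have equal length")
    if time.size < 2 or time[-1] - time[0] < 1.0:
        raise ValueError("need at least 1 s of uniformly sampled data")
    dt = np.diff(time)
    if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
        raise ValueError("non-uniform sampling")
    pos = signal > 0
    onsets = np.flatnonzero(~pos[:-1] & pos[1:]) + 1
    if pos[0]:
        onsets = np.concatenate([[0], onsets])
    if onsets.size == 0:
        return []
    bounds = np.concatenate([onsets, [signal.size]])
    return [slice(int(a), int(b)) for a, b in zip(bounds[:-1], bounds[1:])]


def breath_features(time, signal, segment: slice) -> BreathRecord:
    """Extract timing, pressure and volume features for one breath segment.

    A segment lacking an expiratory (negative) lobe produces a qc-failed
    record rather than raising.
    """
    t = np.asarray(time, dtype=float)[segment]
    x = np.asarray(signal, dtype=float)[segment]
    rec = BreathRecord(start=float(t[0]), end=float(t[-1]))
    neg = np.flatnonzero(x < 0)
    if neg.size == 0 or np.all(x[neg] > -1e-12):
        rec.qc_pass = False
        rec.qc_reason = "no expiration"
        return rec
    iexp = int(neg[0])  # first expiratory sample
    insp_t, insp_x = t[:iexp], x[:iexp]
    exp_t, exp_x = t[iexp:], -x[iexp:]
    rec.ti = float(exp_t[0] - t[0])
    rec.te = float(t[-1] - exp_t[0])
    rec.pip = float(insp_x.max()) if insp_x.size else np.nan
    rec.pep = float(exp_x.max())
    rec.tvi = float(np.trapezoid(np.clip(insp_x, 0, None), insp_t)) if insp_x.size > 1 else 0.0
    rec.tve = float(np.trapezoid(np.clip(exp_x, 0, None), exp_t))
    if rec.tve <= 0:
        rec.qc_pass = False
        rec.qc_reason = "no expiration"
        return rec
    # relaxation time: time into expiration at which RT_VOLUME_FRACTION of
    # the expired volume has left, linearly interpolated between samples
    cum = np.concatenate([[0.0], np.cumsum(np.diff(exp_t) * 0.5 * (exp_x[1:] + exp_x[:-1]))])
    target = RT_VOLUME_FRACTION * cum[-1]
    k = int(np.searchsorted(cum, target))
    if k == 0:
        rec.rt = 0.0
    else:
        frac = (target - cum[k - 1]) / (cum[k] - cum[k - 1])
        rec.rt = float(exp_t[k - 1] + frac * (exp_t[k] - exp_t[k - 1]) - exp_t[0])
    if rec.rt > 0 and rec.pip > 0:
        rec.bi = compute_bi(rec.te, rec.rt, rec.pep, rec.pip)
    return rec


def compute_bi(te: float, rt: float, pep: float, pip: float) -> float:
    """Bronchoobstructive index Bi = ((Te - Rt)/Rt) * (PEP/PIP)."""
    if rt <= 0:
        raise ValueError("relaxation time must be positive")
    if pip <= 0:
        raise ValueError("peak inspiratory pressure must be positive")
    return (te - rt) / rt * (pep / pip)


@dataclass(frozen=True)
class FilterRules:
    """Breath inclusion rules (boundary-inclusive)."""

    min_tidal_volume: float = 1.0  # ml, applied to inspired volume
    min_ti: float = 0.15  # s
    max_ti: float = 3.0  # s
    max_volume_diff: float = 0.10  # |TVi - TVe| / TVi


def apply_breath_filters(
    records: list[BreathRecord], rules: FilterRules = FilterRules()
) -> tuple[list[BreathRecord], list[BreathRecord]]:
    """Tag each record accepted/rejected with the first violated rule.

    Records already qc-failed at feature extraction stay rejected. The
    filter is idempotent: re-applying it never changes the partition.
    Returns (accepted, rejected).
    """
    accepted, rejected = [], []
    for rec in records:
        if not rec.qc_pass and rec.qc_reason not in (None,):
            # keep an existing failure reason unless it was set by this filter
            if rec.qc_reason not in _RULE_NAMES:
                rejected.append(rec)
                continue
        reason = _first_violation(rec, rules)
        rec.qc_pass = reason is None
        rec.qc_reason = reason
        (accepted if reason is None else rejected).append(rec)
    return accepted, rejected


_RULE_NAMES = ("tidal_volume", "min_Ti", "max_Ti", "volume_diff")


def _first_violation(rec: BreathRecord, rules: FilterRules) -> str | None:
    if not np.isfinite(rec.tvi) or rec.tvi < rules.min_tidal_volume:
        return "tidal_volume"
    if not np.isfinite(rec.ti) or rec.ti < rules.min_ti:
        return "min_Ti"
    if rec.ti > rules.max_ti:
        return "max_Ti"
    if abs(rec.tvi - rec.tve) / rec.tvi > rules.max_volume_diff:
        return "volume_diff"
    return None


def aggregate_bi(
    records: list[BreathRecord],
    t_end: float,
    window: float = 15.0,
    period: float = 300.0,
    t_start: float = 0.0,
    min_partial: float = 5.0,
) -> tuple[float, BiSeries]:
    """Period Bi: mean of 15-s window means over the last ``period`` seconds.

    Windows are aligned to the recording start; a breath belongs to the
    window containing its onset. Windows with no accepted breath are
    skipped; a partial trailing window counts if it covers at least
    ``min_partial`` seconds of data. Returns (period value, window series);
    the value is NaN when no window in the period has an accepted breath.
    """
    starts, means = [], []
    w0 = t_start
    while w0 < t_end:
        if t_end - w0 < min_partial:
            break
        in_win = [r.bi for r in records if r.qc_pass and w0 <= r.start < w0 + window]
        if in_win:
            starts.append(w0)
            means.append(float(np.mean(in_win)))
        w0 += window
    series = BiSeries(np.array(starts), np.array(means))
    sel = series.window_start >= t_end - period
    value = float(series.bi_mean[sel].mean()) if sel.any() else float("nan")
    return value, series


def session_summary(
    baseline_bi: float,
    post_values: list[tuple[float, float]],
    reinforcement_baseline: float,
) -> ChallengeSession:
    """Summarise one provocation session.

    ``post_values`` are (minutes after provocation, period Bi) pairs on the
    5, 10, then every-15-min schedule. Rmax is the maximal post-provocation
    Bi; the change in baseline Bi is the current session's baseline minus
    the baseline recorded at sensitization reinforcement, so rising
    intrinsic tone is positive.
    """
    if baseline_bi is None or not np.isfinite(baseline_bi):
        raise ValueError("missing baseline Bi")
    if not post_values:
        raise ValueError("need at least one post-provocation value")
    times = [t for t, _ in post_values]
    if any(b <= a for a, b in zip(times, times[1:])):
        raise ValueError("schedule times must be strictly increasing")
    post_bi = [v for _, v in post_values]
    return ChallengeSession(
        baseline_bi=float(baseline_bi),
        post_times=list(times),
        post_bi=[float(v) for v in post_bi],
        rmax_obstruction=float(max(post_bi)),
        delta_baseline_bi=float(baseline_bi - reinforcement_baseline),
    )
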