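"""Tuning-curve metrics: CF, Q10, and QERB from frequency-threshold curves.

A tuning curve is the threshold sound level for excitation of a fiber as a
function of tone frequency. Curves are smoothed with a five-point
triangular window, CF is the frequency of the lowest threshold, Q10 is CF
over the bandwidth 10 dB above the minimum threshold, and QERB is CF over
the equivalent rectangular bandwidth — the width of the rectangular filter
with the same area as the inverted tuning curve on a linear power scale.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "TuningCurve",
    "TuningMetrics",
    "smooth_triangular5",
    "find_cf",
    "q10",
    "q_erb",
    "compute_metrics",
    "summarize_ratio",
]

_KERNEL = np.array([1.0, 2.0, 3.0, 2.0, 1.0]) / 9.0

FLAG_TRUNCATED_TIP = "truncated_tip"
FLAG_Q10_UNDEFINED = "q10_undefined"
FLAG_SPAN_TRUNCATED = "span_truncated"


@dataclass
class TuningCurve:
    """Frequency-threshold function of one fiber (stored ascending)."""

    freq: np.ndarray
    threshold: np.ndarray
    fiber_id: str = ""

    def __post_init__(self):
        freq = np.asarray(self.freq, dtype=float)
        thr = np.asarray(self.threshold, dtype=float)
        if freq.size != thr.size:
            raise ValueError("freq and threshold must have equal length")
        if freq.size < 7:
            raise ValueError("tuning curve needs at least 7 points")
        if not np.all(np.isfinite(thr)):
            raise ValueError("thresholds must be finite")
        order = np.argsort(freq)
        freq, thr = freq[order], thr[order]
        if np.any(np.diff(freq) <= 0):
            raise ValueError("frequencies must be strictly ascending (no duplicates)")
        self.freq, self.threshold = freq, thr


@dataclass
class TuningMetrics:
    """Sharpness metrics of one tuning curve; NaN where undefined."""

    fiber_id: str
    cf: float
    threshold_at_cf: float
    q10: float
    bw10: float
    q_erb: float
    erb: float
    flags: Tuple[str, ...] = ()


def smooth_triangular5(curve: TuningCurve) -> TuningCurve:
    """Five-point triangular smoothing, kernel (1,2,3,2,1)/9.

    At the edges the kernel is renormalized over in-range taps rather than
    padding, so no thresholds are fabricated beyond the measured span. The
    frequency grid is unchanged.
    """
    thr = curve.threshold
    if thr.size < 5:
        raise ValueError("smoothing needs at least 5 points")
    num = np.convolve(thr, _KERNEL, mode="same")
    den = np.convolve(np.ones_like(thr), _KERNEL, mode="same")
    return TuningCurve(curve.freq.copy(), num / den, curve.fiber_id)


def find_cf(curve: TuningCurve) -> Tuple[float, float, Tuple[str, ...]]:
    """CF = frequency of the (smoothed) global threshold minimum.

    Ties are broken by the geometric mean of the tied frequencies
    (symmetric on the log axis). A minimum at either grid end flags the
    metrics as unreliable (truncated tip). Returns (cf, threshold_at_cf,
    flags).
    """
    thr = curve.threshold
    thr_min = thr.min()
    tied = np.flatnonzero(thr == thr_min)
    cf = float(np.exp(np.mean(np.log(curve.freq[tied]))))
    flags: Tuple[str, ...] = ()
    if tied.min() == 0 or tied.max() == thr.size - 1:
        flags = (FLAG_TRUNCATED_TIP,)
    return cf, float(thr_min), flags


def _crossing_outward(
    logf: np.ndarray, thr: np.ndarray, start: int, target: float, step: int
) -> float:
    """First crossing of `target` moving outward from index `start`.

    Linear interpolation in (log2 f, dB). Returns log2 frequency of the
    crossing, or NaN when the flank never reaches the target.
    """
    i = start
    while 0 <= i + step < thr.size:
        j = i + step
        if (thr[i] < target <= thr[j]) or (thr[i] <= target < thr[j]):
            frac = (target - thr[i]) / (thr[j] - thr[i])
            return logf[i] + frac * (logf[j] - logf[i])
        i = j
    return np.nan


def q10(
    curve: TuningCurve, cf: float, thr_cf: float
) -> Tuple[float, float]:
    """Q10 = CF / bandwidth at 10 dB above the minimum threshold.

    The two flank crossings of thr_cf + 10 dB are found by moving outward
    from CF and interpolating linearly in (log2 f, dB) — never
    extrapolating: a flank that stays below +10 dB leaves the metric
    undefined (NaN). Returns (q10, bw10) in (dimensionless, Hz).
    """
    logf = np.log2(curve.freq)
    thr = curve.threshold
    i_cf = int(np.argmin(np.abs(logf - np.log2(cf))))
    target = thr_cf + 10.0
    lo = _crossing_outward(logf, thr, i_cf, target, -1)
    hi = _crossing_outward(logf, thr, i_cf, target, +1)
    if np.isnan(lo) or np.isnan(hi):
        return np.nan, np.nan
    f_lo, f_hi = 2.0**lo, 2.0**hi
    bw = f_hi - f_lo
    return cf / bw, bw


def q_erb(
    curve: TuningCurve, cf: float, thr_cf: float
) -> Tuple[float, float, Tuple[str, ...]]:
    """QERB = CF / ERB with ERB the area under the inverted tuning curve.

    The curve is inverted to a linear power weight relative to the tip,
    W(f) = 10^((thr_cf - T(f))/10), and integrated over the measured span
    by the trapezoid rule on the linear frequency axis (Hz). A span
    narrower than one octave around CF is flagged as truncated. Returns
    (q_erb, erb_hz, flags).
    """
    w = 10.0 ** ((thr_cf - curve.threshold) / 10.0)
    erb = float(np.trapezoid(w, curve.freq))
    flags: Tuple[str, ...] = ()
    if curve.freq[0] > cf / np.sqrt(2.0) or curve.freq[-1] < cf * np.sqrt(2.0):
        flags = (FLAG_SPAN_TRUNCATED,)
    return cf / erb, erb, flags


def compute_metrics(curve: TuningCurve, smooth: bool = True) -> TuningMetrics:
    """Full metric chain for one curve (smoothing first, as acquired data
    are processed)."""
    smoothed = smooth_triangular5(curve) if smooth else curve
    cf, thr_cf, flags = find_cf(smoothed)
    q10_val, bw10 = q10(smoothed, cf, thr_cf)
    if np.isnan(q10_val):
        flags = flags + (FLAG_Q10_UNDEFINED,)
    qe, erb, erb_flags = q_erb(smoothed, cf, thr_cf)
    return TuningMetrics(
        fiber_id=curve.fiber_id,
        cf=cf,
        threshold_at_cf=thr_cf,
        q10=q10_val,
        bw10=bw10,
        q_erb=qe,
        erb=erb,
        flags=flags + erb_flags,
    )


def summarize_ratio(
    metrics: Iterable[TuningMetrics],
) -> Tuple[float, Tuple[float, float], int]:
    """Median and interquartile range of the per-fiber QERB/Q10 ratio.

    Fibers lacking either metric are skipped. Returns
    (median, (q25, q75), n_used).
    """
    ratios = np.array(
        [m.q_erb / m.q10 for m in metrics if np.isfinite(m.q10) and np.isfinite(m.q_erb)]
    )
    if ratios.size == 0:
        raise ValueError("no fiber has both Q10 and QERB defined")
    q25, med, q75 = np.percentile(ratios, [25.0, 50.0, 75.0])
    return float(med), (float(q25), float(q75)), int(ratios.size)
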