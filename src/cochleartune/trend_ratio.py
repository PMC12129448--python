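"""Gaussian-weighted trends with bootstrap CIs, the tuning ratio r, and
SFOAE-based prediction of cochlear tuning.

The local-mean trend of scattered (frequency, value) data is a weighted
mean with Gaussian weights on the log2-frequency axis. Delay data are fit
in the group-delay domain (value x frequency, approximately normally
distributed) and converted back; Q metrics are averaged directly.
Confidence intervals come from a percentile bootstrap over the sampling
units (ears for emission data, fibers for neural data). The tuning ratio
r(f) = QERB(f) / N_SFOAE(f) converts emission delays into tuning-sharpness
predictions: QERB_predicted = N_SFOAE x r.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
import statsmodels.api as sm

__all__ = [
    "TrendCurve",
    "TuningRatioCurve",
    "PredictionCurve",
    "log_grid",
    "gaussian_trend",
    "bootstrap_ci",
    "tuning_ratio",
    "extrapolate_q10",
    "predict_qerb",
    "db_per_octave",
    "loess_trend",
    "scale_behavioral",
    "build_species_ratio",
]


@dataclass
class TrendCurve:
    """Weighted-mean trend on a log-spaced grid, with optional bootstrap CI."""

    freq: np.ndarray
    mean: np.ndarray
    ci_lo: Optional[np.ndarray] = None
    ci_hi: Optional[np.ndarray] = None
    sigma_octaves: float = 0.25
    n_boot: int = 0
    resample_unit: str = ""
    unreliable: Optional[np.ndarray] = None

    def defined(self) -> np.ndarray:
        return np.isfinite(self.mean)


@dataclass
class TuningRatioCurve:
    """Tuning ratio r = QERB / N_SFOAE per grid frequency."""

    freq: np.ndarray
    r: np.ndarray
    source_species: str = ""
    extended_mask: Optional[np.ndarray] = None
    r_lo: Optional[np.ndarray] = None
    r_hi: Optional[np.ndarray] = None


@dataclass
class PredictionCurve:
    """SFOAE-based QERB prediction, with bounds where r carries an SE band."""

    freq: np.ndarray
    q_erb_predicted: np.ndarray
    se_lo: Optional[np.ndarray] = None
    se_hi: Optional[np.ndarray] = None


def log_grid(f_lo: float, f_hi: float, per_octave: int = 48) -> np.ndarray:
    """Log-spaced evaluation grid at `per_octave` points per octave."""
    n = int(np.floor(np.log2(f_hi / f_lo) * per_octave)) + 1
    return f_lo * 2.0 ** (np.arange(n) / per_octave)


# ---------------------------------------------------------------------------
# Gaussian-weighted trend and bootstrap
# ---------------------------------------------------------------------------

def _partial_sums(freq, value, unit, grid, sigma_octaves, mode):
    """Per-unit weighted sums on the grid.

    Returns (units, num, den, cnt): num/den are (U, G) accumulator arrays
    whose per-unit rows sum to the pooled weighted mean (exactly — a
    bootstrap replicate is the sum of its units' partial sums), and cnt
    counts each unit's points within 3 sigma of each grid frequency.
    """
    freq = np.asarray(freq, dtype=float)
    value = np.asarray(value, dtype=float)
    unit = np.asarray(unit)
    d = np.log2(freq)[None, :] - np.log2(np.asarray(grid, float))[:, None]  # (G, P)
    w = np.exp(-(d * d) / (2.0 * sigma_octaves**2))
    inrange = np.abs(d) <= 3.0 * sigma_octaves
    v = value * freq if mode == "group_delay" else value
    units = np.unique(unit)
    num = np.empty((units.size, len(grid)))
    den = np.empty_like(num)
    cnt = np.empty_like(num)
    for k, u in enumerate(units):
        sel = unit == u
        num[k] = w[:, sel] @ v[sel]
        den[k] = w[:, sel].sum(axis=1)
        cnt[k] = inrange[:, sel].sum(axis=1)
    return units, num, den, cnt


def _combine(num, den, cnt, grid, mode):
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = num.sum(axis=0) / den.sum(axis=0)
    if mode == "group_delay":
        mean = mean / grid
    mean = np.where(cnt.sum(axis=0) > 0, mean, np.nan)
    return mean


def gaussian_trend(
    freq,
    value,
    grid,
    sigma_octaves: float = 0.25,
    mode: str = "direct",
    unit=None,
) -> TrendCurve:
    """Gaussian-weighted local mean of (freq, value) data on `grid`.

    Weights are ``exp(-log2(f_i/f0)^2 / (2 sigma^2))`` on the octave axis.
    ``mode="group_delay"`` averages value x frequency and divides the
    result by the grid frequency (used for delay-in-cycles data);
    ``mode="direct"`` averages raw values (used for Q trends). Grid points
    with no datum within 3 sigma are undefined (NaN), not zero.
    """
    if mode not in ("direct", "group_delay"):
        raise ValueError(f"unknown mode {mode!r}")
    grid = np.asarray(grid, dtype=float)
    if unit is None:
        unit = np.zeros(len(np.asarray(freq)), dtype=int)
    _, num, den, cnt = _partial_sums(freq, value, unit, grid, sigma_octaves, mode)
    mean = _combine(num, den, cnt, grid, mode)
    return TrendCurve(freq=grid, mean=mean, sigma_octaves=sigma_octaves)


def bootstrap_ci(
    freq,
    value,
    unit,
    grid,
    sigma_octaves: float = 0.25,
    mode: str = "direct",
    n_boot: int = 1000,
    seed: int = 0,
    resample_unit: str = "unit",
    ci_level: float = 95.0,
    max_undefined_frac: float = 0.10,
) -> TrendCurve:
    """Percentile-bootstrap CI for the Gaussian-weighted trend.

    Sampling units (ears or fibers) are resampled with replacement
    `n_boot` times and the trend recomputed each time; the CI is the
    2.5/97.5 percentile envelope per grid point. Grid points undefined in
    more than `max_undefined_frac` of replicates are marked unreliable.
    Reproducible from `seed`.
    """
    grid = np.asarray(grid, dtype=float)
    units, num, den, cnt = _partial_sums(freq, value, unit, grid, sigma_octaves, mode)
    if units.size < 2:
        raise ValueError("bootstrap needs at least 2 distinct resample units")
    mean = _combine(num, den, cnt, grid, mode)

    rng = np.random.default_rng(seed)
    idx = rng.integers(0, units.size, size=(n_boot, units.size))
    num_b = num[idx].sum(axis=1)  # (n_boot, G)
    den_b = den[idx].sum(axis=1)
    cnt_b = cnt[idx].sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        trend_b = num_b / den_b
    if mode == "group_delay":
        trend_b = trend_b / grid
    trend_b = np.where(cnt_b > 0, trend_b, np.nan)

    undef_frac = np.mean(np.isnan(trend_b), axis=0)
    alpha = (100.0 - ci_level) / 2.0
    with np.errstate(invalid="ignore"):
        ci_lo, ci_hi = np.nanpercentile(trend_b, [alpha, 100.0 - alpha], axis=0)
    return TrendCurve(
        freq=grid,
        mean=mean,
        ci_lo=ci_lo,
        ci_hi=ci_hi,
        sigma_octaves=sigma_octaves,
        n_boot=n_boot,
        resample_unit=resample_unit,
        unreliable=undef_frac > max_undefined_frac,
    )


# ---------------------------------------------------------------------------
# Tuning ratio and prediction
# ---------------------------------------------------------------------------

def _interp_log2(x_new, x_src, y_src):
    """Linear interpolation in (log2 f, value); NaN outside the source span."""
    x_new = np.asarray(x_new, dtype=float)
    good = np.isfinite(np.asarray(y_src, float))
    out = np.interp(
        np.log2(x_new), np.log2(np.asarray(x_src, float)[good]),
        np.asarray(y_src, float)[good],
        left=np.nan, right=np.nan,
    )
    return out


def tuning_ratio(
    q_trend: TrendCurve,
    n_trend: TrendCurve,
    source_species: str = "",
) -> TuningRatioCurve:
    """r(f) = Q trend / N_SFOAE trend on the delay trend's grid.

    The Q trend is interpolated onto `n_trend.freq` (linear in log2 f);
    points where the delay trend is non-positive or either trend undefined
    are dropped with a warning-free mask (they simply do not appear).
    """
    q_on_n = _interp_log2(n_trend.freq, q_trend.freq, q_trend.mean)
    keep = np.isfinite(q_on_n) & np.isfinite(n_trend.mean) & (n_trend.mean > 0)
    freq = n_trend.freq[keep]
    with np.errstate(invalid="ignore", divide="ignore"):
        r = q_on_n[keep] / n_trend.mean[keep]
    return TuningRatioCurve(
        freq=freq,
        r=r,
        source_species=source_species,
        extended_mask=np.zeros(freq.size, dtype=bool),
    )


def extrapolate_q10(
    cf,
    q10,
    cf_min: float = 1700.0,
    grid: Optional[np.ndarray] = None,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Extend a Q10-vs-CF trend by OLS on log2(CF) above `cf_min`.

    Fits ordinary least squares of Q10 on log2(CF) using fibers with
    CF > `cf_min` and evaluates the predicted mean and its +/- 1 SE band on
    `grid` (default 3.35 -> 4.6 kHz). Returns (grid, mean, se_mean).
    """
    cf = np.asarray(cf, dtype=float)
    q10 = np.asarray(q10, dtype=float)
    sel = cf > cf_min
    if sel.sum() < 3:
        raise ValueError("need at least 3 fibers above cf_min for extrapolation")
    x = np.log2(cf[sel])
    if np.ptp(x) == 0:
        raise ValueError("singular design: all CFs equal above cf_min")
    if grid is None:
        grid = log_grid(3350.0, 4600.0)
    res = sm.OLS(q10[sel], sm.add_constant(x)).fit()
    pred = res.get_prediction(sm.add_constant(np.log2(np.asarray(grid, float))))
    return np.asarray(grid, float), pred.predicted_mean, pred.se_mean


def predict_qerb(n_trend: TrendCurve, r: TuningRatioCurve) -> PredictionCurve:
    """QERB_predicted(f) = N_SFOAE(f) x r(f) on the ratio's grid.

    Where the ratio carries a band (extended region built from extrapolated
    Q10), the bounds propagate multiplicatively.
    """
    n_on_r = _interp_log2(r.freq, n_trend.freq, n_trend.mean)
    keep = np.isfinite(n_on_r)
    pred = n_on_r * r.r
    se_lo = se_hi = None
    if r.r_lo is not None and r.r_hi is not None:
        se_lo = n_on_r * r.r_lo
        se_hi = n_on_r * r.r_hi
        se_lo, se_hi = se_lo[keep], se_hi[keep]
    return PredictionCurve(
        freq=r.freq[keep],
        q_erb_predicted=pred[keep],
        se_lo=se_lo,
        se_hi=se_hi,
    )


def build_species_ratio(
    cf,
    q10,
    n_trend: TrendCurve,
    qerb_factor: float = 1.76,
    sigma_octaves: float = 0.5,
    source_species: str = "",
    extrapolate_above: Optional[float] = None,
    extrapolation_cf_min: float = 1700.0,
    extension_grid: Optional[np.ndarray] = None,
) -> TuningRatioCurve:
    """Empirical tuning ratio from Q10 points and a delay trend.

    Fits the Q10 trend (Gaussian weighting, direct mode), scales it by
    `qerb_factor` to approximate QERB, and divides by the delay trend.
    When `extrapolate_above` is given, Q10 is linearly extrapolated (on
    log2 CF, from fibers above `extrapolation_cf_min`) over
    `extension_grid` and the extended portion of r carries a +/- 1 SE band;
    extended points are contiguous at the high-frequency end.
    """
    cf = np.asarray(cf, dtype=float)
    q10 = np.asarray(q10, dtype=float)
    span_grid = n_trend.freq
    q_trend = gaussian_trend(cf, q10, span_grid, sigma_octaves=sigma_octaves)
    qerb_trend = TrendCurve(
        freq=q_trend.freq, mean=q_trend.mean * qerb_factor,
        sigma_octaves=sigma_octaves,
    )
    base = tuning_ratio(qerb_trend, n_trend, source_species=source_species)
    if extrapolate_above is None:
        return base

    keep_emp = base.freq <= extrapolate_above
    if extension_grid is None:
        ext_hi = float(n_trend.freq[np.isfinite(n_trend.mean)].max())
        extension_grid = log_grid(extrapolate_above, ext_hi)
    ext_f, ext_q10, ext_se = extrapolate_q10(
        cf, q10, cf_min=extrapolation_cf_min, grid=extension_grid
    )
    n_on_ext = _interp_log2(ext_f, n_trend.freq, n_trend.mean)
    ok = np.isfinite(n_on_ext) & (n_on_ext > 0)
    ext_f, ext_q10, ext_se, n_on_ext = (
        ext_f[ok], ext_q10[ok], ext_se[ok], n_on_ext[ok],
    )
    r_ext = qerb_factor * ext_q10 / n_on_ext
    r_ext_lo = qerb_factor * (ext_q10 - ext_se) / n_on_ext
    r_ext_hi = qerb_factor * (ext_q10 + ext_se) / n_on_ext

    freq = np.concatenate([base.freq[keep_emp], ext_f])
    r = np.concatenate([base.r[keep_emp], r_ext])
    nan_emp = np.full(keep_emp.sum(), np.nan)
    return TuningRatioCurve(
        freq=freq,
        r=r,
        source_species=source_species,
        extended_mask=np.concatenate(
            [np.zeros(keep_emp.sum(), bool), np.ones(ext_f.size, bool)]
        ),
        r_lo=np.concatenate([nan_emp, r_ext_lo]),
        r_hi=np.concatenate([nan_emp, r_ext_hi]),
    )


# ---------------------------------------------------------------------------
# Comparison metrics
# ---------------------------------------------------------------------------

def db_per_octave(freq, value, f_range: Optional[Tuple[float, float]] = None) -> float:
    """Slope of 10*log10(value) against log2(frequency), in dB/octave.

    3.01 dB/octave means the value doubles per octave.
    """
    freq = np.asarray(freq, dtype=float)
    value = np.asarray(value, dtype=float)
    if f_range is not None:
        sel = (freq >= f_range[0]) & (freq <= f_range[1])
        freq, value = freq[sel], value[sel]
    good = np.isfinite(value) & np.isfinite(freq)
    freq, value = freq[good], value[good]
    if freq.size < 2:
        raise ValueError("need at least 2 frequencies in range")
    if np.any(value <= 0):
        raise ValueError("values must be positive for a dB slope")
    slope, _ = np.polyfit(np.log2(freq), 10.0 * np.log10(value), 1)
    return float(slope)


def loess_trend(freq, value, grid, span: float = 0.65) -> np.ndarray:
    """LOESS: locally weighted linear regression on the log2-frequency axis.

    Tricube weights over the `span` fraction of nearest points, local
    first-degree fit evaluated at each grid frequency. Exact for data
    linear in log2(f).
    """
    x = np.log2(np.asarray(freq, dtype=float))
    y = np.asarray(value, dtype=float)
    if x.size < 5:
        raise ValueError("LOESS needs at least 5 points")
    k = int(np.ceil(span * x.size))
    if k < 3:
        raise ValueError("span yields fewer than 3 points per local fit")
    out = np.empty(len(grid))
    for i, f0 in enumerate(np.asarray(grid, dtype=float)):
        x0 = np.log2(f0)
        d = np.abs(x - x0)
        dmax = np.sort(d)[k - 1]
        if dmax == 0:
            out[i] = y[d == 0].mean()
            continue
        w = np.clip(1.0 - (d / dmax) ** 3, 0.0, None) ** 3
        sw = w.sum()
        xm = (w @ x) / sw
        ym = (w @ y) / sw
        sxx = w @ ((x - xm) ** 2)
        beta = 0.0 if sxx == 0 else (w @ ((x - xm) * (y - ym))) / sxx
        out[i] = ym + beta * (x0 - xm)
    return out


def scale_behavioral(q10_points, factor: float = 1.76) -> np.ndarray:
    """Scale behavioral Q10 values by the QERB/Q10 factor to approximate QERB."""
    q10_points = np.asarray(q10_points, dtype=float)
    if np.any(q10_points <= 0):
        raise ValueError("Q10 values must be positive")
    return q10_points * factor
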