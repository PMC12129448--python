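"""Swept-tone SFOAE extraction: artifact rejection, averaging, vector
subtraction, least-squares spectral analysis, phase-gradient delay, and the
two exclusion rules (low SNR, magnitude troughs).

The emission is isolated by the suppressor paradigm: the ear-canal pressure
is recorded for probe alone, suppressor alone, and both together, and the
residual P_probe + P_suppressor - P_both cancels everything that combines
linearly, leaving the emission (which the suppressor removes from the
combined condition). Magnitude and phase follow the sweep via a windowed
least-squares fit of a quadrature pair locked to the probe's instantaneous
phase; the delay in stimulus cycles is N(f) = -f * dphi/df with phi in
cycles.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .session import P_REF, RecordingSession, SweepSpec, amplitude_to_db_spl

__all__ = [
    "RecordingSession",
    "SfoaeSpectrum",
    "DelayCurve",
    "reject_artifacts",
    "clean_session_reps",
    "average_reps",
    "vector_subtract",
    "lsf_spectrum",
    "estimate_noise_floor",
    "phase_gradient_delay",
    "apply_exclusions",
    "extract_session",
    "mad_threshold",
]

#: Per-point exclusion labels.
REASON_NONE = "none"
REASON_LOW_SNR = "low_snr"
REASON_TROUGH = "trough"


@dataclass
class SfoaeSpectrum:
    """Complex emission pressure on an ascending frequency grid.

    `pressure` holds the complex peak amplitude of the fitted quadrature
    pair (Pa); `level` is the corresponding RMS level in dB SPL; `phase` is
    unwrapped and expressed in cycles. `noise_floor_level` is filled in by
    :func:`estimate_noise_floor` / :func:`extract_session`.
    """

    freq: np.ndarray
    pressure: np.ndarray
    level: np.ndarray
    phase: np.ndarray
    noise_floor_level: Optional[np.ndarray] = None

    def __post_init__(self):
        n = len(self.freq)
        for name in ("pressure", "level", "phase"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length does not match freq")
        if np.any(np.diff(self.freq) <= 0):
            raise ValueError("frequency grid must ascend")


@dataclass
class DelayCurve:
    """Phase-gradient delay in stimulus cycles with per-point validity."""

    freq: np.ndarray
    n_sfoae: np.ndarray
    valid: np.ndarray
    exclusion_reason: np.ndarray

    def __post_init__(self):
        n = len(self.freq)
        if not (len(self.n_sfoae) == len(self.valid) == len(self.exclusion_reason) == n):
            raise ValueError("DelayCurve arrays must share one length")


# ---------------------------------------------------------------------------
# Artifact rejection and averaging
# ---------------------------------------------------------------------------

def mad_threshold(deviations: np.ndarray, k: float = 6.0) -> float:
    """Default artifact threshold: k times the median absolute deviation.

    Applied to the ensemble of deviations from the across-repetition mean,
    where the deterministic stimulus has been removed and artifacts stand
    out against the noise.
    """
    mad = np.median(np.abs(deviations - np.median(deviations)))
    return float(k * mad)


def reject_artifacts(
    rep: np.ndarray,
    threshold: float,
    fs: float = 50_000.0,
    window_s: float = 0.020,
) -> Tuple[np.ndarray, List[Tuple[int, int]], bool]:
    """Flag 20-ms windows around every sample exceeding |threshold|.

    Returns ``(excised_mask, intervals, dropped)``: a boolean mask of
    flagged samples (True = excised, to be ignored by averaging rather than
    zeroed), the list of merged excision intervals in samples
    (half-open ``[start, end)``), and a flag set when more than half of the
    repetition would be excised, in which case the repetition should be
    dropped.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    rep = np.asarray(rep)
    n = rep.size
    half = int(round(window_s * fs / 2.0))
    hits = np.flatnonzero(np.abs(rep) > threshold)
    mask = np.zeros(n, dtype=bool)
    intervals: List[Tuple[int, int]] = []
    for i in hits:
        start, end = max(0, i - half), min(n, i + half)
        if intervals and start <= intervals[-1][1]:
            intervals[-1] = (intervals[-1][0], max(end, intervals[-1][1]))
        else:
            intervals.append((start, end))
    for start, end in intervals:
        mask[start:end] = True
    dropped = mask.mean() > 0.5
    if dropped:
        warnings.warn(
            f"more than 50% of repetition excised "
            f"({mask.mean():.0%}); repetition dropped",
            stacklevel=2,
        )
    return mask, intervals, dropped


def clean_session_reps(
    reps: np.ndarray,
    fs: float,
    threshold: Optional[float] = None,
) -> Tuple[np.ndarray, np.ndarray]:
    """Artifact-clean a repetition matrix against its ensemble mean.

    Detection runs on deviations from the across-repetition mean so the
    swept stimulus itself does not trigger the threshold. Returns
    ``(masks, kept)`` where `masks` is (n_reps, n_samples) True = excised,
    and `kept` marks repetitions that survive the 50% rule.
    """
    reps = np.asarray(reps, dtype=float)
    dev = reps - reps.mean(axis=0, keepdims=True)
    if threshold is None:
        threshold = mad_threshold(dev)
    masks = np.zeros(reps.shape, dtype=bool)
    kept = np.ones(reps.shape[0], dtype=bool)
    if threshold <= 0:  # noiseless ensemble: nothing to excise
        return masks, kept
    for i in range(reps.shape[0]):
        mask, _, dropped = reject_artifacts(dev[i], threshold, fs=fs)
        masks[i] = mask
        kept[i] = not dropped
    return masks, kept


def average_reps(
    reps: np.ndarray,
    masks: Optional[np.ndarray] = None,
) -> Tuple[np.ndarray, np.ndarray]:
    """Per-sample mean over repetitions, ignoring excised samples.

    Samples with zero contributing repetitions are linearly interpolated
    from neighbors and reported with a contribution count of zero.
    Returns ``(mean, n_contributing)``.
    """
    reps = np.asarray(reps, dtype=float)
    if reps.ndim != 2 or reps.shape[0] < 2:
        raise ValueError("need at least 2 surviving repetitions to average")
    if masks is None:
        return reps.mean(axis=0), np.full(reps.shape[1], reps.shape[0])
    masks = np.asarray(masks, dtype=bool)
    good = ~masks
    counts = good.sum(axis=0)
    total = np.where(good, reps, 0.0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = total / counts
    missing = counts == 0
    if missing.any():
        idx = np.arange(reps.shape[1])
        mean[missing] = np.interp(idx[missing], idx[~missing], mean[~missing])
    return mean, counts


def vector_subtract(
    p_probe: np.ndarray, p_supp: np.ndarray, p_both: np.ndarray
) -> np.ndarray:
    """Residual P_probe + P_suppressor - P_both (samplewise, Pa)."""
    p_probe, p_supp, p_both = (np.asarray(p) for p in (p_probe, p_supp, p_both))
    if not (p_probe.shape == p_supp.shape == p_both.shape):
        raise ValueError("condition waveforms must have equal lengths")
    return p_probe + p_supp - p_both


# ---------------------------------------------------------------------------
# Least-squares spectral analysis
# ---------------------------------------------------------------------------

def lsf_spectrum(
    waveform: np.ndarray,
    sweep: SweepSpec,
    window_s: float = 0.020,
    hop_s: float = 0.005,
    mask: Optional[np.ndarray] = None,
    skip_ramps: bool = True,
) -> SfoaeSpectrum:
    """Windowed least-squares fit of a quadrature pair locked to the sweep.

    At each analysis center t_c a Hann-weighted least-squares fit of
    ``a*cos(phi(t)) + b*sin(phi(t))`` (phi = the probe sweep's instantaneous
    phase) over a `window_s` window yields the complex amplitude ``a - i*b``
    assigned to the sweep frequency f(t_c). Samples flagged in `mask` get
    zero weight. Windows extending past the signal (or into the stimulus
    ramps when `skip_ramps`) are dropped, so the grid ascends with the
    sweep over the interior of the recording.
    """
    x = np.asarray(waveform, dtype=float)
    fs = sweep.fs
    nw = int(round(window_s * fs))
    hop = int(round(hop_s * fs))
    if hop <= 0:
        raise ValueError("hop must be positive")
    if nw > x.size:
        raise ValueError("window longer than the signal")
    f_first = sweep.instantaneous_frequency(nw / 2.0 / fs)
    if f_first * window_s < 3.0:
        raise ValueError(
            "window covers fewer than 3 cycles of the local sweep frequency"
        )

    t = np.arange(x.size) / fs
    phi = sweep.phase(t)
    c_full = np.cos(phi)
    s_full = np.sin(phi)
    w_full = np.ones(x.size)
    if mask is not None:
        w_full[np.asarray(mask, dtype=bool)] = 0.0

    start_min = 0
    start_max = x.size - nw
    if skip_ramps and sweep.ramp > 0:
        start_min = int(np.ceil(sweep.ramp * fs))
        start_max = min(start_max, int(np.floor((sweep.duration - sweep.ramp) * fs)) - nw)
    starts = np.arange(start_min, start_max + 1, hop)
    if starts.size == 0:
        raise ValueError("no complete analysis window fits inside the signal")

    win = np.hanning(nw)
    # Strided views over all windows at once; each row is one analysis frame.
    sw = sliding_window_view
    xw = sw(x, nw)[starts]
    cw = sw(c_full, nw)[starts]
    s_w = sw(s_full, nw)[starts]
    ww = sw(w_full, nw)[starts] * win

    scc = np.einsum("ij,ij,ij->i", ww, cw, cw)
    sss = np.einsum("ij,ij,ij->i", ww, s_w, s_w)
    scs = np.einsum("ij,ij,ij->i", ww, cw, s_w)
    sxc = np.einsum("ij,ij,ij->i", ww, xw, cw)
    sxs = np.einsum("ij,ij,ij->i", ww, xw, s_w)
    det = scc * sss - scs * scs
    a = (sxc * sss - sxs * scs) / det
    b = (sxs * scc - sxc * scs) / det
    pressure = a - 1j * b

    centers = (starts + nw / 2.0) / fs
    freq = sweep.instantaneous_frequency(centers)
    level = amplitude_to_db_spl(np.abs(pressure))
    phase = np.unwrap(np.angle(pressure)) / (2.0 * np.pi)
    return SfoaeSpectrum(freq=freq, pressure=pressure, level=level, phase=phase)


def estimate_noise_floor(
    reps_probe: np.ndarray,
    reps_supp: np.ndarray,
    reps_both: np.ndarray,
    sweep: SweepSpec,
    masks: Optional[dict] = None,
    **lsf_kwargs,
) -> np.ndarray:
    """Noise-floor level (dB SPL) from the odd/even repetition split.

    The three-condition residual is formed separately from odd- and
    even-indexed repetitions; half their difference carries the same noise
    power as the full-average residual (for equal split sizes) and none of
    the emission, and is analyzed with the same spectral estimator as the
    signal. Unequal odd/even counts are truncated to the smaller count.
    """
    reps = {"probe": reps_probe, "suppressor": reps_supp, "both": reps_both}
    halves = {}
    for cond, mat in reps.items():
        mat = np.asarray(mat, dtype=float)
        if mat.shape[0] < 4:
            raise ValueError("need >= 4 repetitions per condition (>=2 odd, >=2 even)")
        m = masks[cond] if masks is not None else None
        odd_idx = np.arange(1, mat.shape[0], 2)
        even_idx = np.arange(0, mat.shape[0], 2)
        k = min(odd_idx.size, even_idx.size)
        odd_idx, even_idx = odd_idx[:k], even_idx[:k]
        halves[cond] = (
            average_reps(mat[odd_idx], None if m is None else m[odd_idx])[0],
            average_reps(mat[even_idx], None if m is None else m[even_idx])[0],
        )
    resid_odd = vector_subtract(*(halves[c][0] for c in ("probe", "suppressor", "both")))
    resid_even = vector_subtract(*(halves[c][1] for c in ("probe", "suppressor", "both")))
    diff = 0.5 * (resid_odd - resid_even)
    return lsf_spectrum(diff, sweep, **lsf_kwargs).level


# ---------------------------------------------------------------------------
# Delay and exclusions
# ---------------------------------------------------------------------------

def phase_gradient_delay(spectrum: SfoaeSpectrum) -> DelayCurve:
    """N_SFOAE(f) = -f * dphi/df, phi in cycles, by centered differences.

    One-sided differences are used at the grid edges. The phase must be
    unwrapped before differentiation (lsf_spectrum does this).
    """
    if len(spectrum.freq) < 3:
        raise ValueError("need at least 3 grid points to form a phase gradient")
    dphi = np.gradient(spectrum.phase, spectrum.freq)
    n_sfoae = -spectrum.freq * dphi
    n = len(spectrum.freq)
    return DelayCurve(
        freq=spectrum.freq.copy(),
        n_sfoae=n_sfoae,
        valid=np.ones(n, dtype=bool),
        exclusion_reason=np.array([REASON_NONE] * n, dtype=object),
    )


def _trough_mask(
    freq: np.ndarray,
    level: np.ndarray,
    depth_db: float = 10.0,
    half_width_octaves: float = 1.0 / 24.0,
    base_db: float = 3.0,
) -> np.ndarray:
    """Points at the base of magnitude troughs.

    A trough is a local minimum of the level curve lying >= `depth_db`
    below both flanking local maxima (the grid edge counts as a flank).
    Excluded points are those within +/- `half_width_octaves` of the
    minimum, or inside the notch (between the flanking maxima) and within
    `base_db` of the minimum level.
    """
    n = len(level)
    mask = np.zeros(n, dtype=bool)
    if n < 3:
        return mask
    interior = np.arange(1, n - 1)
    is_min = (level[interior] < level[interior - 1]) & (
        level[interior] <= level[interior + 1]
    )
    is_max = (level[interior] > level[interior - 1]) & (
        level[interior] >= level[interior + 1]
    )
    minima = interior[is_min]
    maxima = list(interior[is_max])
    # Edges act as flanking maxima for notches that run off the grid.
    maxima = np.array([0] + maxima + [n - 1])
    logf = np.log2(freq)
    for m in minima:
        left_candidates = maxima[maxima < m]
        right_candidates = maxima[maxima > m]
        left = left_candidates.max() if left_candidates.size else 0
        right = right_candidates.min() if right_candidates.size else n - 1
        if (level[left] - level[m] >= depth_db) and (
            level[right] - level[m] >= depth_db
        ):
            near = np.abs(logf - logf[m]) <= half_width_octaves
            inside = np.zeros(n, dtype=bool)
            inside[left : right + 1] = True
            low = level <= level[m] + base_db
            mask |= near | (inside & low)
    return mask


def apply_exclusions(
    delay: DelayCurve,
    spectrum: SfoaeSpectrum,
    snr_db: float = 10.0,
) -> DelayCurve:
    """Mask delay points failing the SNR rule or sitting in magnitude troughs.

    A point is excluded as ``low_snr`` when its level is less than `snr_db`
    above the *median* of the estimated noise floor, and as ``trough`` when
    it sits at the base of a magnitude notch (where phase is unreliable).
    """
    if spectrum.noise_floor_level is None:
        raise ValueError("spectrum has no noise-floor estimate")
    if not np.array_equal(delay.freq, spectrum.freq):
        raise ValueError("delay and spectrum must share the frequency grid")
    floor_median = np.median(spectrum.noise_floor_level)
    low_snr = spectrum.level < floor_median + snr_db
    trough = _trough_mask(spectrum.freq, spectrum.level)

    reason = np.array([REASON_NONE] * len(delay.freq), dtype=object)
    reason[trough] = REASON_TROUGH
    reason[low_snr] = REASON_LOW_SNR  # SNR rule takes precedence in the label
    valid = ~(low_snr | trough)
    if not valid.any():
        warnings.warn("all delay points excluded", stacklevel=2)
    return DelayCurve(
        freq=delay.freq.copy(),
        n_sfoae=delay.n_sfoae.copy(),
        valid=valid,
        exclusion_reason=reason,
    )


def extract_session(
    session: RecordingSession,
    window_s: float = 0.020,
    hop_s: float = 0.005,
    snr_db: float = 10.0,
    artifact_threshold: Optional[float] = None,
) -> Tuple[SfoaeSpectrum, DelayCurve]:
    """Full extraction chain for one session.

    Cleans each condition's repetitions, averages, forms the
    three-condition residual, runs the least-squares spectral fit against
    the probe sweep, estimates the noise floor from the odd/even split, and
    returns the spectrum plus the exclusion-masked delay curve.
    """
    means = {}
    masks = {}
    kept_reps = {}
    for cond, reps in session.waveforms.items():
        m, kept = clean_session_reps(reps, session.fs, threshold=artifact_threshold)
        masks[cond] = m[kept]
        kept_reps[cond] = reps[kept]
        means[cond], _ = average_reps(kept_reps[cond], masks[cond])
    residual = vector_subtract(means["probe"], means["suppressor"], means["both"])
    spectrum = lsf_spectrum(residual, session.probe, window_s=window_s, hop_s=hop_s)
    spectrum.noise_floor_level = estimate_noise_floor(
        kept_reps["probe"],
        kept_reps["suppressor"],
        kept_reps["both"],
        session.probe,
        masks=masks,
        window_s=window_s,
        hop_s=hop_s,
    )
    delay = phase_gradient_delay(spectrum)
    delay = apply_exclusions(delay, spectrum, snr_db=snr_db)
    return spectrum, delay
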