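"""Synthetic ear: SFOAE recording sessions and nerve tuning curves with known truth.

This module fabricates the two kinds of raw data the pipeline consumes:

* swept-tone ear-canal recording sessions in the three-condition suppressor
  paradigm, with an embedded emission whose level, group delay, spectral
  notches, and suppressibility are fully specified — so the extraction stages
  have an exact recoverable target; and
* V-shaped auditory-nerve frequency-threshold tuning curves whose sharpness
  follows a power law in characteristic frequency, with the generating
  parameters retained per fiber.

The emission is rendered as the probe sweep passed through a delay-and-scale
operator evaluated at the instantaneous sweep frequency: at time t the probe
is at frequency f(t), and the emission sample is
``A(f(t)) * cos(phi_probe(t - tau(f(t))))``. For this construction the
phase of the extracted emission relative to the probe is (to first order in
the sweep rate) ``phi(f) = -f * tau(f)`` cycles, so the phase-gradient delay
in cycles has the closed form ``N(f) = f * d[f*tau(f)]/df``, exposed by
:func:`EmissionModel.true_n_sfoae`.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Callable, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import brentq

from .session import (
    CONDITIONS,
    DEFAULT_PROBE,
    DEFAULT_SUPPRESSOR,
    RecordingSession,
    SweepSpec,
    db_spl_to_amplitude,
)

__all__ = [
    "EmissionModel",
    "SweepSpec",
    "FiberSpec",
    "SimulatedFiber",
    "synthesize_session",
    "generate_fiber_population",
    "roex_p_for_q10",
    "v_slope_for_q10",
    "ROEX_X10",
]


# ---------------------------------------------------------------------------
# Emission model
# ---------------------------------------------------------------------------

@dataclass
class EmissionModel:
    """Ground-truth description of the embedded emission.

    Parameters
    ----------
    level_profile : callable
        Maps frequency (Hz, array-aware) to emission level (dB SPL), before
        notches are applied.
    delay_profile : callable
        Maps frequency (Hz, array-aware) to group delay in seconds (>= 0).
    notches : sequence of (center_hz, depth_db, width_octaves)
        Gaussian dips in dB on a log-frequency axis, emulating the deep
        spectral notches seen in measured emission spectra.
    suppression_fraction : float
        Fraction of the emission removed in the probe+suppressor condition;
        1.0 models an ideal suppressor.
    """

    level_profile: Callable[[np.ndarray], np.ndarray]
    delay_profile: Callable[[np.ndarray], np.ndarray]
    notches: Sequence[Tuple[float, float, float]] = ()
    suppression_fraction: float = 1.0

    def __post_init__(self):
        if not (0.0 <= self.suppression_fraction <= 1.0):
            raise ValueError("suppression_fraction must lie in [0, 1]")
        f = np.geomspace(500.0, 8000.0, 64)
        lev = np.asarray(self.level_profile(f), dtype=float)
        tau = np.asarray(self.delay_profile(f), dtype=float)
        if not np.all(np.isfinite(lev)):
            raise ValueError("level_profile must be finite on [0.5, 8] kHz")
        if np.any(tau < 0.0):
            raise ValueError("delay_profile must be non-negative")

    def level_db(self, freq) -> np.ndarray:
        """Emission level in dB SPL at `freq`, notches included."""
        freq = np.asarray(freq, dtype=float)
        level = np.asarray(self.level_profile(freq), dtype=float)
        for fc, depth, width in self.notches:
            level = level - depth * np.exp(
                -np.log2(freq / fc) ** 2 / (2.0 * width**2)
            )
        return level

    def amplitude_pa(self, freq) -> np.ndarray:
        return db_spl_to_amplitude(self.level_db(freq))

    def true_n_sfoae(self, freq) -> np.ndarray:
        """Ground-truth phase-gradient delay in stimulus cycles.

        N(f) = f * d[f*tau(f)]/df, evaluated by centered differences on a
        fine local grid (exact for the constant- and power-law profiles).
        """
        freq = np.atleast_1d(np.asarray(freq, dtype=float))
        out = np.empty_like(freq)
        for i, f0 in enumerate(freq):
            df = 1e-3 * f0
            fg = np.array([f0 - df, f0, f0 + df])
            ftau = fg * np.asarray(self.delay_profile(fg), dtype=float)
            out[i] = f0 * (ftau[2] - ftau[0]) / (2.0 * df)
        return out if out.size > 1 else float(out[0])

    # -- stock profiles ----------------------------------------------------

    @classmethod
    def constant_delay(
        cls,
        tau_s: float,
        level_db: float = 10.0,
        notches: Sequence[Tuple[float, float, float]] = (),
        suppression_fraction: float = 1.0,
    ) -> "EmissionModel":
        """Flat-level emission with a frequency-independent latency."""
        return cls(
            level_profile=lambda f: np.full_like(np.asarray(f, float), level_db),
            delay_profile=lambda f: np.full_like(np.asarray(f, float), tau_s),
            notches=notches,
            suppression_fraction=suppression_fraction,
        )

    @classmethod
    def power_law_delay(
        cls,
        n0_cycles: float = 1.5,
        exponent: float = 0.548,
        level_db: float = 10.0,
        rolloff_hz: float = 5500.0,
        rolloff_db_per_octave: float = 30.0,
        notches: Sequence[Tuple[float, float, float]] = (
            (1200.0, 18.0, 0.06),
            (2500.0, 22.0, 0.05),
            (4200.0, 16.0, 0.05),
        ),
        suppression_fraction: float = 1.0,
    ) -> "EmissionModel":
        """Emission whose delay in cycles follows N(f) = n0*(f/1 kHz)^exponent.

        The delay profile is tau(f) = (n0/exponent)*(f/1 kHz)^exponent / f so
        that the *phase-gradient* delay equals the target power law. The
        default exponent 0.548 corresponds to a 1.65 dB/octave rise of
        10*log10(N), and n0=1.5 cycles at 1 kHz places the delays in the
        range observed for small birds. Level is flat below `rolloff_hz` and
        falls off above it, so the emission descends into the noise floor at
        high frequencies; three deep notches are placed across the band.
        """
        if exponent <= 0:
            raise ValueError("exponent must be positive")

        def level(f):
            f = np.asarray(f, dtype=float)
            octs = np.log2(np.maximum(f, 1.0) / rolloff_hz)
            return level_db - rolloff_db_per_octave * np.clip(octs, 0.0, None)

        def tau(f):
            f = np.asarray(f, dtype=float)
            return (n0_cycles / exponent) * (f / 1000.0) ** exponent / f

        return cls(
            level_profile=level,
            delay_profile=tau,
            notches=notches,
            suppression_fraction=suppression_fraction,
        )

    @classmethod
    def silent(cls) -> "EmissionModel":
        """Zero-amplitude emission (level -> -inf is approximated by 0 Pa)."""
        model = cls.constant_delay(tau_s=0.0, level_db=-400.0)
        return model


def _render_emission(model: EmissionModel, probe: SweepSpec) -> np.ndarray:
    """Render the emission waveform for one probe sweep presentation."""
    t = probe.times()
    f_inst = probe.instantaneous_frequency(t)
    tau = np.asarray(model.delay_profile(f_inst), dtype=float)
    amp = model.amplitude_pa(f_inst)
    return amp * np.cos(probe.phase(t - tau)) * probe.envelope()


def _artifact_click(fs: float, width_s: float = 1e-3) -> np.ndarray:
    """Unit-amplitude raised-cosine click of the given width."""
    n = max(int(round(width_s * fs)), 3)
    x = np.arange(n) / (n - 1)
    return 0.5 * (1.0 - np.cos(2.0 * np.pi * x))


def synthesize_session(
    model: EmissionModel,
    probe: SweepSpec = DEFAULT_PROBE,
    suppressor: SweepSpec = DEFAULT_SUPPRESSOR,
    noise_rms: float = 0.0,
    n_reps: int = 40,
    artifact_rate: float = 0.0,
    artifact_amp_factor: float = 25.0,
    seed: int = 0,
    metadata: Optional[dict] = None,
) -> RecordingSession:
    """Simulate one three-condition swept-tone recording session.

    The probe-alone condition carries the full emission; the combined
    condition carries ``(1 - suppression_fraction)`` of it; the suppressor's
    own emission is not modeled (it cancels in the vector subtraction
    regardless). Independent white noise of RMS `noise_rms` (Pa) is added to
    every repetition, and transient artifacts (1-ms raised-cosine clicks of
    amplitude ``artifact_amp_factor * noise_rms``, random sign) are injected
    at Poisson-distributed times with rate `artifact_rate` events/s.

    Fully reproducible from `seed`.
    """
    if n_reps < 2 or n_reps % 2 != 0:
        raise ValueError(
            f"n_reps must be an even number >= 2 (got {n_reps}); the "
            "odd/even noise-floor split downstream requires matched halves"
        )
    if probe.duration != suppressor.duration or probe.fs != suppressor.fs:
        raise ValueError("probe and suppressor must share duration and fs")

    rng = np.random.default_rng(seed)
    stim_probe = probe.waveform()
    stim_supp = suppressor.waveform()
    emission = _render_emission(model, probe)
    sf = model.suppression_fraction

    clean = {
        "probe": stim_probe + emission,
        "suppressor": stim_supp,
        "both": stim_probe + stim_supp + (1.0 - sf) * emission,
    }

    n = probe.n_samples
    click = _artifact_click(probe.fs)
    waveforms = {}
    for cond in CONDITIONS:
        reps = np.tile(clean[cond], (n_reps, 1))
        if noise_rms > 0.0:
            reps += noise_rms * rng.standard_normal((n_reps, n))
        if artifact_rate > 0.0 and noise_rms > 0.0:
            counts = rng.poisson(artifact_rate * probe.duration, size=n_reps)
            amp = artifact_amp_factor * noise_rms
            for i, count in enumerate(counts):
                starts = rng.integers(0, n - click.size, size=count)
                signs = rng.choice([-1.0, 1.0], size=count)
                for s0, sg in zip(starts, signs):
                    reps[i, s0 : s0 + click.size] += sg * amp * click
        waveforms[cond] = reps

    meta = dict(metadata or {})
    meta.setdefault("seed", seed)
    meta.setdefault("noise_rms", noise_rms)
    meta["ground_truth"] = {
        "suppression_fraction": sf,
        "model": model,
    }
    return RecordingSession(
        waveforms=waveforms, probe=probe, suppressor=suppressor, metadata=meta
    )


# ---------------------------------------------------------------------------
# Auditory-nerve fiber population
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FiberSpec:
    """Ground truth for one simulated auditory-nerve fiber."""

    cf: float
    threshold_at_cf: float
    q10: float
    shape: str = "roex"
    sampling_density: float = 28.0

    def __post_init__(self):
        if self.cf <= 0 or self.q10 <= 0:
            raise ValueError("cf and q10 must be positive")
        if self.sampling_density < 4:
            raise ValueError("sampling_density must be >= 4 points/octave")
        if self.shape not in ("roex", "symmetric-V"):
            raise ValueError(f"unknown shape {self.shape!r}")


@dataclass
class SimulatedFiber:
    """A generated tuning curve together with its generating FiberSpec."""

    fiber_id: str
    freq: np.ndarray
    threshold: np.ndarray
    spec: FiberSpec


def _solve_roex_x10() -> float:
    """10-dB half-width of the rounded-exponential filter in units of p*g.

    Solves (1+x) e^(-x) = 0.1; the 10-dB bandwidth of a roex(p) curve is
    2*x10*CF/p, hence Q10 = p/(2*x10).
    """
    return brentq(lambda x: (1.0 + x) * np.exp(-x) - 0.1, 1.0, 10.0, xtol=1e-12)


ROEX_X10 = _solve_roex_x10()  # ~3.8897


def roex_p_for_q10(q10: float) -> float:
    """Roex slope parameter p giving the requested Q10 (Q10 = p / (2*x10))."""
    return 2.0 * ROEX_X10 * q10


def v_slope_for_q10(q10: float) -> float:
    """Flank slope (dB/octave) of a log-symmetric V giving the requested Q10.

    For straight flanks of slope s dB/octave the 10-dB points sit 10/s
    octaves either side of CF, so Q10 = 1 / (2^(10/s) - 2^(-10/s)).
    """

    def q_of_s(s):
        x = 10.0 / s
        return 1.0 / (2.0**x - 2.0**-x) - q10

    return brentq(q_of_s, 1.0, 5000.0, xtol=1e-10)


def roex_threshold(freq, cf: float, thr_cf: float, p: float) -> np.ndarray:
    """Frequency-threshold curve of a roex(p) filter: T = thr_cf - 10 log10 W."""
    g = np.abs(np.asarray(freq, dtype=float) - cf) / cf
    w = (1.0 + p * g) * np.exp(-p * g)
    return thr_cf - 10.0 * np.log10(w)


def v_threshold(freq, cf: float, thr_cf: float, slope_db_oct: float) -> np.ndarray:
    """Log-symmetric V curve with straight flanks in (log2 f, dB)."""
    return thr_cf + slope_db_oct * np.abs(np.log2(np.asarray(freq, float) / cf))


def _default_threshold_law(cf: float) -> float:
    """Bowl-shaped threshold-at-CF law: best (~8 dB SPL) near 2.8 kHz."""
    return 8.0 + 2.5 * np.log2(cf / 2800.0) ** 2


def generate_fiber_population(
    n: int,
    cf_range: Tuple[float, float] = (280.0, 5650.0),
    q_law: Tuple[float, float] = (3.0, 0.289),
    threshold_law: Optional[Callable[[float], float]] = None,
    jitter_sd: float = 0.1,
    threshold_jitter_sd: float = 3.0,
    shape: str = "roex",
    sampling_density: float = 28.0,
    f_top: float = 6000.0,
    f_bottom: float = 200.0,
    max_threshold_db: float = 80.0,
    seed: int = 0,
) -> List[SimulatedFiber]:
    """Generate a population of V-shaped tuning curves with known ground truth.

    Per-fiber CFs are log-uniform over `cf_range`; sharpness follows the
    power law Q10 = a * (CF / 1 kHz)^b with multiplicative log-normal jitter
    of standard deviation `jitter_sd` (natural-log units). Curves are sampled
    at `sampling_density` points/octave descending from `f_top` (emulating
    threshold tracking that starts high and proceeds downward) and points
    above `max_threshold_db` are dropped, as tracking fails there. The
    default law (a=3.0, b=0.289) gives a 0.87 dB/octave rise of 10*log10(Q10).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    lo, hi = cf_range
    if not (0.0 < lo < hi):
        raise ValueError("cf_range must be positive and ascending")
    a, b = q_law
    q_at_ends = a * (np.array([lo, hi]) / 1000.0) ** b
    if np.any(q_at_ends <= 0.0) or not np.all(np.isfinite(q_at_ends)):
        raise ValueError("Q10 law must be positive over cf_range")
    if threshold_law is None:
        threshold_law = _default_threshold_law

    rng = np.random.default_rng(seed)
    # Descending acquisition grid, shared across fibers.
    n_steps = int(np.floor(np.log2(f_top / f_bottom) * sampling_density)) + 1
    grid = f_top * 2.0 ** (-np.arange(n_steps) / sampling_density)

    fibers: List[SimulatedFiber] = []
    for i in range(n):
        cf = np.exp(rng.uniform(np.log(lo), np.log(hi)))
        q10 = a * (cf / 1000.0) ** b
        if jitter_sd > 0:
            q10 *= np.exp(jitter_sd * rng.standard_normal())
        thr_cf = float(threshold_law(cf))
        if threshold_jitter_sd > 0:
            thr_cf += threshold_jitter_sd * rng.standard_normal()
        if shape == "roex":
            thr = roex_threshold(grid, cf, thr_cf, roex_p_for_q10(q10))
        elif shape == "symmetric-V":
            thr = v_threshold(grid, cf, thr_cf, v_slope_for_q10(q10))
        else:
            raise ValueError(f"unknown shape {shape!r}")
        keep = thr <= max_threshold_db
        fibers.append(
            SimulatedFiber(
                fiber_id=f"fiber{i:04d}",
                freq=grid[keep][::-1].copy(),
                threshold=thr[keep][::-1].copy(),
                spec=FiberSpec(
                    cf=cf,
                    threshold_at_cf=thr_cf,
                    q10=q10,
                    shape=shape,
                    sampling_density=sampling_density,
                ),
            )
        )
    return fibers
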