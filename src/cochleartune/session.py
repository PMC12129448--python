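"""Shared containers for swept-tone ear-canal recording sessions.

A session holds the three stimulus conditions of the suppressor paradigm
(probe alone, suppressor alone, probe+suppressor) as repetition matrices at a
common sampling rate, together with the sweep specifications needed to
analyze them.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict

import numpy as np

TWO_PI = 2.0 * np.pi
#: Reference pressure for dB SPL (Pa).
P_REF = 20e-6

CONDITIONS = ("probe", "suppressor", "both")


def db_spl_to_amplitude(level_db):
    """Peak amplitude (Pa) of a sinusoid at the given RMS level in dB SPL."""
    return np.sqrt(2.0) * P_REF * 10.0 ** (np.asarray(level_db, dtype=float) / 20.0)


def amplitude_to_db_spl(amplitude_pa):
    """RMS level in dB SPL of a sinusoid with the given peak amplitude (Pa)."""
    amplitude_pa = np.asarray(amplitude_pa, dtype=float)
    with np.errstate(divide="ignore"):
        return 20.0 * np.log10(amplitude_pa / (np.sqrt(2.0) * P_REF))


@dataclass(frozen=True)
class SweepSpec:
    """A linear frequency sweep: constant-rate tone from f_start to f_end.

    Parameters
    ----------
    f_start, f_end : float
        Sweep endpoints in Hz; must satisfy 0 < f_start < f_end <= fs/2.
    duration : float
        Sweep duration in seconds.
    level_db : float
        Presentation level in dB SPL.
    ramp : float
        Raised-cosine onset/offset ramp duration in seconds.
    fs : float
        Sampling rate in Hz.
    """

    f_start: float
    f_end: float
    duration: float
    level_db: float
    ramp: float = 0.025
    fs: float = 50_000.0

    def __post_init__(self):
        if not (0.0 < self.f_start < self.f_end):
            raise ValueError("require 0 < f_start < f_end")
        if self.f_end > self.fs / 2.0:
            raise ValueError(
                f"f_end={self.f_end} Hz exceeds Nyquist ({self.fs / 2.0} Hz)"
            )
        if self.duration <= 2.0 * self.ramp:
            raise ValueError("duration must exceed twice the ramp length")

    @property
    def rate(self) -> float:
        """Sweep rate in Hz/s."""
        return (self.f_end - self.f_start) / self.duration

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.fs))

    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs

    def instantaneous_frequency(self, t) -> np.ndarray:
        return self.f_start + self.rate * np.asarray(t, dtype=float)

    def phase(self, t) -> np.ndarray:
        """Instantaneous phase in radians at time t (zero phase at t=0)."""
        t = np.asarray(t, dtype=float)
        return TWO_PI * (self.f_start * t + 0.5 * self.rate * t * t)

    def envelope(self) -> np.ndarray:
        """Raised-cosine onset/offset envelope over the sweep duration."""
        env = np.ones(self.n_samples)
        n_ramp = int(round(self.ramp * self.fs))
        if n_ramp > 0:
            x = np.arange(n_ramp) / n_ramp
            ramp = 0.5 * (1.0 - np.cos(np.pi * x))
            env[:n_ramp] = ramp
            env[-n_ramp:] = ramp[::-1]
        return env

    def waveform(self) -> np.ndarray:
        """Render the swept tone (Pa) with its raised-cosine ramps."""
        amp = db_spl_to_amplitude(self.level_db)
        return amp * np.cos(self.phase(self.times())) * self.envelope()

    def to_dict(self) -> dict:
        return {
            "f_start": self.f_start,
            "f_end": self.f_end,
            "duration": self.duration,
            "level_db": self.level_db,
            "ramp": self.ramp,
            "fs": self.fs,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SweepSpec":
        return cls(**d)


#: Probe sweep used throughout: 0.5->8 kHz over 2.05 s at 40 dB SPL.
DEFAULT_PROBE = SweepSpec(500.0, 8000.0, 2.05, 40.0)
#: Suppressor sweep: 0.54->8.04 kHz over 2.05 s at 55 dB SPL.
DEFAULT_SUPPRESSOR = SweepSpec(540.0, 8040.0, 2.05, 55.0)


@dataclass
class RecordingSession:
    """Three-condition swept-tone recording session.

    Attributes
    ----------
    waveforms : dict
        Maps condition ("probe", "suppressor", "both") to an
        (n_reps, n_samples) array of ear-canal pressure in Pa.
    probe, suppressor : SweepSpec
        Sweep specifications of the two stimulus components.
    metadata : dict
        Session/ear identifiers and, for synthetic sessions, ground truth.
    """

    waveforms: Dict[str, np.ndarray]
    probe: SweepSpec
    suppressor: SweepSpec
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        lengths = {cond: w.shape for cond, w in self.waveforms.items()}
        n_cols = {shape[1] for shape in lengths.values()}
        if len(n_cols) != 1:
            raise ValueError(f"repetition lengths differ across conditions: {lengths}")
        if self.probe.fs != self.suppressor.fs:
            raise ValueError("probe and suppressor sampling rates differ")

    @property
    def fs(self) -> float:
        return self.probe.fs

    @property
    def n_reps(self) -> int:
        return next(iter(self.waveforms.values())).shape[0]
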