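"""File layouts: WAV+JSON recording sessions, tuning-curve and result CSVs.

Sessions are stored as one IEEE-float WAV per repetition,
``{session}_{condition}_{rep:03d}.wav`` (condition in probe/suppressor/both),
with a sidecar ``{session}_session.json`` carrying the sweep specifications
and, for synthetic sessions, the sampled ground-truth delay curve.
"""
from __future__ import annotations

import json
from pathlib import Path
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.io import wavfile

from .an_tuning import TuningCurve, TuningMetrics
from .session import CONDITIONS, RecordingSession, SweepSpec
from .sfoae_extract import DelayCurve, SfoaeSpectrum
from .synthetic_ear import SimulatedFiber
from .trend_ratio import PredictionCurve, TrendCurve, TuningRatioCurve


def write_session(session: RecordingSession, outdir, name: str) -> Path:
    """Write a session's repetitions as float32 WAVs plus a JSON sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for cond in CONDITIONS:
        for i, rep in enumerate(session.waveforms[cond]):
            wavfile.write(
                outdir / f"{name}_{cond}_{i:03d}.wav",
                int(session.fs),
                rep.astype(np.float32),
            )
    sidecar = {
        "name": name,
        "n_reps": session.n_reps,
        "probe": session.probe.to_dict(),
        "suppressor": session.suppressor.to_dict(),
    }
    truth = session.metadata.get("ground_truth")
    if truth is not None and "model" in truth:
        model = truth["model"]
        f = np.geomspace(session.probe.f_start, session.probe.f_end, 128)
        sidecar["ground_truth"] = {
            "freq_hz": f.tolist(),
            "n_sfoae_cycles": np.atleast_1d(model.true_n_sfoae(f)).tolist(),
            "level_db_spl": model.level_db(f).tolist(),
            "suppression_fraction": truth.get("suppression_fraction"),
        }
    (outdir / f"{name}_session.json").write_text(json.dumps(sidecar, indent=1))
    return outdir


def read_session(indir, name: str) -> RecordingSession:
    """Read a session written by :func:`write_session` (float32 precision)."""
    indir = Path(indir)
    sidecar = json.loads((indir / f"{name}_session.json").read_text())
    waveforms = {}
    for cond in CONDITIONS:
        reps = []
        for i in range(sidecar["n_reps"]):
            fs, data = wavfile.read(indir / f"{name}_{cond}_{i:03d}.wav")
            reps.append(np.asarray(data, dtype=float))
        waveforms[cond] = np.vstack(reps)
    return RecordingSession(
        waveforms=waveforms,
        probe=SweepSpec.from_dict(sidecar["probe"]),
        suppressor=SweepSpec.from_dict(sidecar["suppressor"]),
        metadata={"name": name, "sidecar": sidecar},
    )


def write_fiber_curves(fibers: Sequence[SimulatedFiber], curves_csv, truth_csv=None):
    """Tuning curves as long-format CSV; ground truth as a per-fiber CSV."""
    rows = []
    for fib in fibers:
        for f, t in zip(fib.freq, fib.threshold):
            rows.append({"fiber_id": fib.fiber_id, "freq_hz": f, "threshold_db_spl": t})
    pd.DataFrame(rows).to_csv(curves_csv, index=False)
    if truth_csv is not None:
        pd.DataFrame(
            [
                {
                    "fiber_id": fib.fiber_id,
                    "cf_hz": fib.spec.cf,
                    "q10_true": fib.spec.q10,
                    "threshold_true": fib.spec.threshold_at_cf,
                }
                for fib in fibers
            ]
        ).to_csv(truth_csv, index=False)


def read_tuning_curves(curves_csv) -> List[TuningCurve]:
    df = pd.read_csv(curves_csv)
    curves = []
    for fiber_id, sub in df.groupby("fiber_id", sort=True):
        curves.append(
            TuningCurve(
                freq=sub["freq_hz"].to_numpy(float),
                threshold=sub["threshold_db_spl"].to_numpy(float),
                fiber_id=str(fiber_id),
            )
        )
    return curves


def metrics_frame(metrics: Sequence[TuningMetrics]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "fiber_id": m.fiber_id,
                "cf_hz": m.cf,
                "threshold_at_cf_db": m.threshold_at_cf,
                "q10": m.q10,
                "q_erb": m.q_erb,
                "erb_hz": m.erb,
                "bw10_hz": m.bw10,
                "flags": ";".join(m.flags),
            }
            for m in metrics
        ]
    )


def spectrum_frame(spectrum: SfoaeSpectrum) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "freq_hz": spectrum.freq,
            "level_db_spl": spectrum.level,
            "phase_cycles": spectrum.phase,
            "noise_floor_db_spl": (
                spectrum.noise_floor_level
                if spectrum.noise_floor_level is not None
                else np.nan
            ),
        }
    )


def delay_frame(delay: DelayCurve) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "freq_hz": delay.freq,
            "n_sfoae_cycles": delay.n_sfoae,
            "valid": delay.valid,
            "exclusion_reason": delay.exclusion_reason,
        }
    )


def trend_frame(trend: TrendCurve) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "freq_hz": trend.freq,
            "mean": trend.mean,
            "ci_lo": trend.ci_lo if trend.ci_lo is not None else np.nan,
            "ci_hi": trend.ci_hi if trend.ci_hi is not None else np.nan,
        }
    )


def ratio_frame(ratio: TuningRatioCurve) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "freq_hz": ratio.freq,
            "r": ratio.r,
            "extended": (
                ratio.extended_mask
                if ratio.extended_mask is not None
                else np.zeros(len(ratio.freq), bool)
            ),
            "r_lo": ratio.r_lo if ratio.r_lo is not None else np.nan,
            "r_hi": ratio.r_hi if ratio.r_hi is not None else np.nan,
        }
    )


def prediction_frame(pred: PredictionCurve) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "freq_hz": pred.freq,
            "q_erb_predicted": pred.q_erb_predicted,
            "se_lo": pred.se_lo if pred.se_lo is not None else np.nan,
            "se_hi": pred.se_hi if pred.se_hi is not None else np.nan,
        }
    )
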