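#!/usr/bin/env python
"""Extract emission spectra and delay curves from the simulated sessions.

Reads the WAV sessions under scratch/sessions/, runs artifact rejection,
averaging, the three-condition vector subtraction, the swept-tone
least-squares spectral fit, and the SNR/trough exclusion rules; writes the
pooled valid delay and level points to scratch/raw/sfoae_points.csv
(per-ear full curves go to scratch/ as well; summary tables from later
steps land in results/).
"""
import sys
from pathlib import Path

import numpy as np
import pandas as pd

ROOT = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(ROOT / "src"))

from cochleartune import io as ctio
from cochleartune.sfoae_extract import extract_session


def main():
    scratch = ROOT / "scratch" / "sessions"
    out_scratch = ROOT / "scratch" / "extracted"
    out_scratch.mkdir(parents=True, exist_ok=True)
    rows = []
    for sidecar in sorted(scratch.glob("*_session.json")):
        name = sidecar.name.replace("_session.json", "")
        session = ctio.read_session(scratch, name)
        spectrum, delay = extract_session(session)
        ctio.spectrum_frame(spectrum).to_csv(
            out_scratch / f"{name}_sfoae_spectrum.csv", index=False
        )
        ctio.delay_frame(delay).to_csv(
            out_scratch / f"{name}_delay_curve.csv", index=False
        )
        v = delay.valid
        rows.append(pd.DataFrame({
            "ear_id": name,
            "freq_hz": delay.freq[v],
            "n_sfoae": delay.n_sfoae[v],
            "level_db": spectrum.level[v],
        }))
        reasons = pd.Series(delay.exclusion_reason).value_counts().to_dict()
        print(f"{name}: {int(v.sum())}/{v.size} points valid "
              f"(median level {np.median(spectrum.level[v]):.1f} dB SPL; "
              f"exclusions {reasons})")
    points = pd.concat(rows, ignore_index=True)
    points.to_csv(ROOT / "scratch" / "raw" / "sfoae_points.csv", index=False)
    print(f"pooled {len(points)} valid points from "
          f"{points['ear_id'].nunique()} ears -> scratch/raw/sfoae_points.csv")

if __name__ == "__main__":
    main()
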