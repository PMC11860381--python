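#!/usr/bin/env python
"""Q-residual screening of the simulated campaign.

Loads the scan table written by 01_simulate_dataset.py (regenerating it if
absent), trims to the 9000-3952 cm^-1 analysis window, scatter-corrects
(detrend + SNV) and screens noise-studentized Q residuals at 99%
family-wise confidence.  Writes the flagged scans and the post-screening
class tallies to results/.
"""

import subprocess
import sys
from pathlib import Path

import numpy as np
import pandas as pd

import nirseed as ns
from nirseed import workflow as wf

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    scan_csv = ROOT / "scratch" / "simulated_scans.csv"
    if not scan_csv.exists():
        subprocess.run([sys.executable,
                        str(ROOT / "analysis" / "01_simulate_dataset.py")],
                       check=True)
    spectra = ns.read_csv(scan_csv)

    report, cleaned = wf.screen_outliers(spectra, confidence=0.99)
    flagged = pd.DataFrame([
        {
            "scan_row": int(i),
            "bag_id": spectra.metadata[i].bag_id,
            "cultivar": spectra.metadata[i].cultivar,
            "endophyte_strain": spectra.metadata[i].endophyte_strain,
            "q_residual": float(report.q_residuals[i]),
        }
        for i in report.flagged
    ])
    results = ROOT / "results"
    results.mkdir(exist_ok=True)
    flagged.to_csv(results / "outlier_scans.csv", index=False)

    print(f"screened {spectra.n_scans} scans at rank "
          f"{report.n_components}, threshold {report.threshold:.1f} "
          f"({report.threshold_method})")
    print(flagged.to_string(index=False) if len(flagged) else "none flagged")
    print(f"{cleaned.n_scans} scans retained "
          f"({int(np.sum(cleaned.statuses() == 'E+'))} E+, "
          f"{int(np.sum(cleaned.cultivars() == 'Alto'))} Alto)")


if __name__ == "__main__":
    main()
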