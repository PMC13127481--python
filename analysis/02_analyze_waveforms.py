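#!/usr/bin/env python
"""Run the wave-intensity / PU-loop pipeline over the cohort.

Reads the waveform CSVs written by 01_simulate_cohort.py (regenerating
them if absent), analyzes each recording — pulse wave speed, S1/S2 and
composites, wave segmentation with relative magnitudes, %Td, phasic
Pf/Pb changes — and writes the marker table to results/markers.csv plus
one example per-recording result JSON.
"""

import subprocess
import sys
from pathlib import Path

import pandas as pd

from puwave.pipeline import MARKER_COLUMNS, analyze_recording, marker_row, write_result_json
from puwave.waveio import read_waveform_csv

ROOT = Path(__file__).resolve().parents[1]


def main():
    cohort_dir = ROOT / "scratch" / "cohort"
    labels_path = ROOT / "results" / "cohort_labels.csv"
    if not labels_path.exists() or not any(cohort_dir.glob("*.csv")):
        subprocess.run([sys.executable, str(ROOT / "analysis" / "01_simulate_cohort.py")],
                       check=True)
    labels = pd.read_csv(labels_path)
    groups = dict(zip(labels["id"], labels["group"]))

    rows = []
    for csv_path in sorted(cohort_dir.glob("*.csv")):
        sid = csv_path.stem
        rec = read_waveform_csv(csv_path)
        res = analyze_recording(rec)
        rows.append(marker_row(res, sid, groups[sid]))
        if sid == "cad_01":
            write_result_json(res, ROOT / "results" / "example_recording_result.json")
    tbl = pd.DataFrame(rows, columns=MARKER_COLUMNS)
    out = ROOT / "results" / "markers.csv"
    tbl.to_csv(out, index=False)
    print(f"analyzed {len(tbl)} recordings -> {out}")
    print(tbl.groupby("group")[["pws", "s1", "s2", "s2_s1_ratio", "pct_td",
                                "rel_mfcw"]].median().round(3))


if __name__ == "__main__":
    main()
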