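#!/usr/bin/env python
"""Cohort-level statistics on the marker table.

Group summaries (median [IQR]), Mann-Whitney U with effect size r,
ROC/AUC with the Youden-index cutoff for every marker, plus the rank
correlation between the S2:S1 ratio and the midsystolic forward
compression wave's relative magnitude. Writes results/stats.json and
prints a compact comparison table.
"""

import json
import subprocess
import sys
from pathlib import Path

import pandas as pd

from puwave.stats import format_p, marker_panel_report, spearman

ROOT = Path(__file__).resolve().parents[1]


def main():
    markers_path = ROOT / "results" / "markers.csv"
    if not markers_path.exists():
        subprocess.run([sys.executable, str(ROOT / "analysis" / "02_analyze_waveforms.py")],
                       check=True)
    tbl = pd.read_csv(markers_path)
    report = marker_panel_report(tbl, positive_group="CAD")
    rho = spearman(tbl["s2_s1_ratio"], tbl["rel_mfcw"])
    report["spearman_s2s1_vs_rel_mfcw"] = {"rho": rho.statistic, "p": rho.p_value}
    out = ROOT / "results" / "stats.json"
    with open(out, "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    print(f"wrote {out}\n")
    print(f"{'marker':>14} {'CAD median':>12} {'non-CAD':>10} {'p':>8} {'r':>6} {'AUC':>6} {'cutoff':>8}")
    for m, e in report["markers"].items():
        s = e["summary"]
        print(f"{m:>14} {s['CAD']['median']:>12.3f} {s['non-CAD']['median']:>10.3f} "
              f"{e['mann_whitney']['p_printed']:>8} {e['mann_whitney']['r']:>6.2f} "
              f"{e['roc']['auc']:>6.3f} {e['roc']['youden_cutoff']:>8.3f}")
    print(f"\nSpearman S2:S1 vs rel. m-FCW: rho = {rho.statistic:.3f}, "
          f"p = {format_p(rho.p_value)}")


if __name__ == "__main__":
    main()
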