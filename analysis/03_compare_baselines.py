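#!/usr/bin/env python
"""Compare per-dataset identification rates against repository baselines.

Reads the QC report written by analysis/02_build_report.py and tabulates the
delta of every dataset's rate against the PRIDE (25.78%) and MassIVE (26.28%)
repository-wide averages, flagging datasets that fall below.
"""

import csv
import json
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    report_path = ROOT / "results" / "qc_report.json"
    if not report_path.exists():
        raise SystemExit(f"{report_path} not found — run analysis/02_build_report.py first")
    report = json.loads(report_path.read_text())
    baselines = report["corpus"]["baselines"]

    out_path = ROOT / "results" / "baseline_comparison.tsv"
    n_below_all = 0
    with open(out_path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        header = ["dataset_id", "rate_pct"]
        for b in baselines:
            header += [f"delta_vs_{b['name']}", f"below_{b['name']}"]
        w.writerow(header)
        for ds in report["datasets"]:
            rate = ds["pooled_rate_pct"]
            row = [ds["dataset_id"], rate]
            below_all = True
            for b in baselines:
                delta = round(rate - b["rate_pct"], 2)
                below = rate < b["rate_pct"]
                below_all &= below
                row += [delta, str(below).lower()]
            n_below_all += below_all
            w.writerow(row)

    n = len(report["datasets"])
    names = ", ".join(f"{b['name']} ({b['rate_pct']}%)" for b in baselines)
    print(f"baselines: {names}")
    print(f"{n_below_all} of {n} datasets fall below every baseline")
    corpus_rate = report["corpus"]["pooled_rate_pct"]
    for b in baselines:
        print(f"corpus pooled rate {corpus_rate}% vs {b['name']}: "
              f"delta {round(corpus_rate - b['rate_pct'], 2)}")
    print(f"table: {out_path}")


if __name__ == "__main__":
    main()
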