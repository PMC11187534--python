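#!/usr/bin/env python
"""Run the accounting pipeline over the worked corpus and write the QC report.

Counts submitted spectra from the MGF block counts, assigned spectra from the
deposited-style search outputs, derives the PSM-level metric set (PSMs at 1%
FDR, distinct peptides, protein groups, contaminant spectra), and emits the
standardised report (JSON + TSV + summary figure) under results/.

Run analysis/01_simulate_corpus.py first.
"""

import argparse
from pathlib import Path

from ms2qc.config import load_config
from ms2qc.pipeline import run_corpus
from ms2qc.reporting import build_report, render_json, render_summary_figure, render_tsv

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument(
        "--corpus", type=Path, default=ROOT / "scratch" / "worked_corpus"
    )
    args = parser.parse_args()

    config_path = args.corpus / "corpus_config.yaml"
    if not config_path.exists():
        raise SystemExit(
            f"{config_path} not found — run analysis/01_simulate_corpus.py first"
        )
    config = load_config(config_path)
    result = run_corpus(config)
    report = build_report(
        result.corpus, config, provenance=result.provenance, missing=result.missing
    )
    results = ROOT / "results"
    results.mkdir(exist_ok=True)
    (results / "qc_report.json").write_text(render_json(report))
    (results / "qc_report.tsv").write_text(render_tsv(report))
    render_summary_figure(report, results / "qc_summary.png")

    d = report.to_dict()["corpus"]
    print(f"{d['total_assigned']:,} of {d['total_submitted']:,} submitted MS2 "
          f"spectra assigned across {d['n_datasets']} datasets")
    print(f"pooled identification rate: {d['pooled_rate_pct']}%")
    print(f"unidentified (dark) fraction: {d['pct_unidentified']}%")
    print(f"mean per-dataset rate: {d['mean_dataset_rate_pct']}%")
    print(f"report: {results / 'qc_report.json'}")


if __name__ == "__main__":
    main()
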