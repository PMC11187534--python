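"""End-to-end corpus accounting: files in, CorpusAccounting out.

For each dataset the denominator (submitted MS2 spectra) comes from counting
``BEGIN IONS`` blocks in the deposited peak lists (or, optionally, from
MaxQuant's own ``MS/MS`` tallies), and the numerator (assigned spectra) from
the deposited search results. PSM-level QC metrics are derived wherever a
PSM-level file (msms.txt or .mzid) is present; otherwise they are explicit
nulls with a reason code.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .accounting import (
    CorpusAccounting,
    DatasetAccounting,
    RunAccounting,
    build_corpus_accounting,
    contaminant_partition,
    distinct_peptides,
    protein_groups,
    psms_at_fdr,
    tdc_qvalues,
)
from .config import CorpusManifestConfig
from .peaklist_io import summarize_peaklist
from .searchresult_io import (
    PsmRecord,
    parse_maxquant_msms,
    parse_maxquant_summary,
    parse_mzid,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineResult", "run_corpus"]

#: reason codes for metrics that are null rather than zero
REASON_NO_PSM_FILE = "no_psms_file"
REASON_NO_DECOYS = "no_decoys_present"


@dataclass
class PipelineResult:
    corpus: CorpusAccounting
    provenance: dict
    #: per (dataset_id, metric) reason codes for null metrics
    missing: dict[str, dict[str, str]] = field(default_factory=dict)


def _dataset_mzid(
    entry, config: CorpusManifestConfig, provenance_files: list[dict]
) -> tuple[list[RunAccounting], list[PsmRecord]]:
    """mzIdentML path: one .mzid per run, matched to MGFs by stem."""
    summaries = {Path(p).stem: summarize_peaklist(p) for p in entry.peaklists}
    runs: list[RunAccounting] = []
    psms: list[PsmRecord] = []
    for result_path in entry.results:
        stem = Path(result_path).stem
        res = parse_mzid(result_path, run_id=stem, decoy_prefixes=config.decoy_prefixes)
        provenance_files.append(
            {
                "path": str(result_path),
                "n_records": res.report.n_records,
                "n_skipped": res.report.n_skipped,
                "errors": res.report.errors,
                "warnings": res.report.warnings,
            }
        )
        if stem not in summaries:
            raise FileNotFoundError(
                f"{entry.dataset_id}: no peak list matches result {result_path!r} "
                f"(available runs: {sorted(summaries)})"
            )
        summary = summaries.pop(stem)
        runs.append(
            RunAccounting(
                run_id=stem,
                n_submitted=summary.n_ms2,
                n_assigned=res.n_spectra_assigned,
            )
        )
        psms.extend(res.psms)
    for leftover in summaries.values():
        logger.warning(
            "%s: peak list %s has no matching search result; counted with 0 assigned",
            entry.dataset_id, leftover.path,
        )
        runs.append(
            RunAccounting(run_id=leftover.run_id, n_submitted=leftover.n_ms2, n_assigned=0)
        )
    return runs, psms


def _dataset_maxquant(
    entry, config: CorpusManifestConfig, provenance_files: list[dict]
) -> tuple[list[RunAccounting], list[PsmRecord], str | None]:
    """MaxQuant path: summary.txt for counts, optional msms.txt for PSMs."""
    summary_paths = [p for p in entry.results if Path(p).name.lower() == "summary.txt"]
    msms_paths = [p for p in entry.results if Path(p).name.lower() == "msms.txt"]
    if not summary_paths:
        raise FileNotFoundError(
            f"{entry.dataset_id}: MaxQuant datasets need a summary.txt among results"
        )
    mq = parse_maxquant_summary(summary_paths[0])
    provenance_files.append(
        {
            "path": summary_paths[0],
            "n_records": mq.report.n_records,
            "n_skipped": mq.report.n_skipped,
            "errors": mq.report.errors,
            "warnings": mq.report.warnings,
        }
    )
    mgf_counts = {Path(p).stem: summarize_peaklist(p).n_ms2 for p in entry.peaklists}
    runs = []
    for rec in mq.runs:
        if config.denominator == "mgf" and rec.raw_file in mgf_counts:
            n_sub = mgf_counts[rec.raw_file]
        else:
            n_sub = rec.n_submitted
        runs.append(
            RunAccounting(
                run_id=rec.raw_file, n_submitted=n_sub, n_assigned=rec.n_identified
            )
        )
    psms: list[PsmRecord] = []
    psm_reason: str | None = REASON_NO_PSM_FILE
    if msms_paths:
        psms, report = parse_maxquant_msms(msms_paths[0])
        psm_reason = None
        provenance_files.append(
            {
                "path": msms_paths[0],
                "n_records": report.n_records,
                "n_skipped": report.n_skipped,
                "errors": report.errors,
                "warnings": report.warnings,
            }
        )
    return runs, psms, psm_reason


def _fill_psm_metrics(
    ds: DatasetAccounting,
    psms: list[PsmRecord],
    config: CorpusManifestConfig,
    missing: dict[str, str],
) -> None:
    """Dataset- and run-level PSM metrics from one pooled competition."""
    rank1 = [p for p in psms if p.rank == 1]
    table = tdc_qvalues(rank1)
    if not any(p.is_decoy for p in rank1):
        missing["fdr_note"] = REASON_NO_DECOYS
    ds.n_psms_at_fdr = psms_at_fdr(table, config.fdr_alpha)
    ds.n_peptides = distinct_peptides(psms)
    ds.n_protein_groups = protein_groups(psms)
    n_con, _ = contaminant_partition(psms, config.contaminant_rules)
    ds.n_contaminant_spectra = n_con

    accepted = {
        (p.run_id, p.spectrum_key)
        for p, q in zip(table.psms, table.q_values)
        if not p.is_decoy and q <= config.fdr_alpha
    }
    for run in ds.runs:
        run_psms = [p for p in psms if p.run_id == run.run_id]
        if not run_psms:
            continue
        run.n_psms_at_fdr = sum(
            1 for key in accepted if key[0] == run.run_id
        )
        run.n_peptides = distinct_peptides(run_psms)
        run.n_protein_groups = protein_groups(run_psms)
        n_con_run, _ = contaminant_partition(run_psms, config.contaminant_rules)
        run.n_contaminant_spectra = min(n_con_run, run.n_assigned)


def run_corpus(config: CorpusManifestConfig) -> PipelineResult:
    """Run the full accounting over every dataset in the corpus config."""
    config.validate()
    provenance_files: list[dict] = []
    missing: dict[str, dict[str, str]] = {}
    datasets: list[DatasetAccounting] = []
    for entry in config.datasets:
        ds_missing: dict[str, str] = {}
        if entry.engine == "mzid":
            runs, psms = _dataset_mzid(entry, config, provenance_files)
            psm_reason = None
        else:
            runs, psms, psm_reason = _dataset_maxquant(entry, config, provenance_files)
        ds = DatasetAccounting(
            dataset_id=entry.dataset_id, engine=entry.engine, runs=runs
        )
        if psms and psm_reason is None:
            _fill_psm_metrics(ds, psms, config, ds_missing)
        else:
            for metric in (
                "n_psms_at_fdr", "n_peptides", "n_protein_groups",
                "n_contaminant_spectra",
            ):
                ds_missing[metric] = psm_reason or REASON_NO_PSM_FILE
        if ds_missing:
            missing[entry.dataset_id] = ds_missing
        datasets.append(ds)

    corpus = build_corpus_accounting(datasets, config.baselines)
    provenance = {
        "tool": "ms2qc",
        "tool_version": __version__,
        "config_digest": config.digest(),
        "fdr_alpha": config.fdr_alpha,
        "denominator_convention": config.denominator,
        "threshold_convention": "passThreshold-only, rank 1",
        "decoy_prefixes": list(config.decoy_prefixes),
        "parse_reports": provenance_files,
    }
    return PipelineResult(corpus=corpus, provenance=provenance, missing=missing)
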