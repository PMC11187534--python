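"""Standardised QC report: JSON, TSV, and a summary figure.

The report carries, at run, dataset and corpus level, the metric set that
makes deposited corpora comparable: submitted and assigned MS2 spectra, the
bulk identification rate, PSMs at a predefined FDR, distinct peptides,
protein groups and the contaminant fraction, plus repository baseline
comparisons and a provenance block recording exactly which conventions were
applied. Metrics that cannot be computed (e.g. no PSM-level file deposited)
are explicit nulls with a reason code — never silent zeros.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from importlib import resources
from pathlib import Path

from .accounting import CorpusAccounting, DatasetAccounting, RunAccounting, round_half_up
from .config import CorpusManifestConfig

__all__ = [
    "QcReport",
    "SCHEMA_VERSION",
    "build_report",
    "render_json",
    "render_tsv",
    "parse_report",
    "render_summary_figure",
    "load_schema",
    "validate_report_dict",
]

SCHEMA_VERSION = "1.0"

_OPTIONAL_METRICS = (
    "n_psms_at_fdr",
    "n_peptides",
    "n_protein_groups",
    "n_contaminant_spectra",
)


@dataclass
class QcReport:
    corpus: CorpusAccounting
    provenance: dict
    missing: dict[str, dict[str, str]] = field(default_factory=dict)
    generated_at: str = ""
    schema_version: str = SCHEMA_VERSION
    rounding_decimals: int = 2

    def _r(self, x: float) -> float:
        return round_half_up(x, self.rounding_decimals)

    def _run_dict(self, ds: DatasetAccounting, run: RunAccounting) -> dict:
        d: dict = {
            "run_id": run.run_id,
            "n_submitted": run.n_submitted,
            "n_assigned": run.n_assigned,
            "rate_pct": self._r(run.rate_pct),
        }
        reasons = self.missing.get(ds.dataset_id, {})
        for metric in _OPTIONAL_METRICS:
            value = getattr(run, metric)
            d[metric] = value
            if value is None:
                d[f"{metric}_reason"] = reasons.get(metric, "not_computed")
        return d

    def _dataset_dict(self, ds: DatasetAccounting) -> dict:
        reasons = self.missing.get(ds.dataset_id, {})
        d: dict = {
            "dataset_id": ds.dataset_id,
            "engine": ds.engine,
            "n_submitted": ds.n_submitted,
            "n_assigned": ds.n_assigned,
            "pooled_rate_pct": self._r(ds.pooled_rate_pct),
            "mean_rate_pct": self._r(ds.mean_rate_pct),
        }
        for metric in _OPTIONAL_METRICS:
            value = getattr(ds, metric)
            d[metric] = value
            if value is None:
                d[f"{metric}_reason"] = reasons.get(metric, "not_computed")
        d["runs"] = [self._run_dict(ds, r) for r in ds.runs]
        return d

    def to_dict(self) -> dict:
        c = self.corpus
        return {
            "schema_version": self.schema_version,
            "generated_at": self.generated_at,
            "provenance": self.provenance,
            "corpus": {
                "n_datasets": len(c.datasets),
                "total_submitted": c.total_submitted,
                "total_assigned": c.total_assigned,
                "pooled_rate_pct": self._r(c.pooled_rate_pct),
                "mean_dataset_rate_pct": self._r(c.mean_dataset_rate_pct),
                "pct_unidentified": self._r(c.pct_unidentified),
                "baselines": [
                    {
                        "name": b.name,
                        "rate_pct": b.rate_pct,
                        "source_note": b.source_note,
                    }
                    for b in c.baselines
                ],
                "baseline_comparisons": [
                    {
                        "name": bc.name,
                        "baseline_rate_pct": bc.baseline_rate_pct,
                        "delta_pct": self._r(bc.delta_pct),
                        "below": bc.below,
                    }
                    for bc in c.baseline_comparisons
                ],
            },
            "datasets": [self._dataset_dict(d) for d in c.datasets],
        }


def build_report(
    corpus: CorpusAccounting,
    config: CorpusManifestConfig,
    provenance: dict | None = None,
    missing: dict[str, dict[str, str]] | None = None,
    generated_at: str | None = None,
) -> QcReport:
    """Assemble the QC report; ``generated_at`` may be pinned for determinism."""
    if generated_at is None:
        generated_at = datetime.now(timezone.utc).isoformat(timespec="seconds")
    return QcReport(
        corpus=corpus,
        provenance=provenance or {"config_digest": config.digest()},
        missing=missing or {},
        generated_at=generated_at,
        rounding_decimals=config.rounding_decimals,
    )


def render_json(report: QcReport) -> str:
    """Serialise with stable key order; rates at 2 decimals, counts raw."""
    return json.dumps(report.to_dict(), indent=2) + "\n"


def parse_report(text: str) -> dict:
    """Parse a rendered report; equal to ``report.to_dict()`` by identity."""
    return json.loads(text)


def render_tsv(report: QcReport) -> str:
    """Flat export: one row per run, one per dataset, one corpus summary."""
    columns = [
        "level", "dataset_id", "run_id", "engine",
        "n_submitted", "n_assigned", "rate_pct",
        "pooled_rate_pct", "mean_rate_pct", "pct_unidentified",
        "n_psms_at_fdr", "n_peptides", "n_protein_groups",
        "n_contaminant_spectra",
    ]

    def _cell(v) -> str:
        return "" if v is None else str(v)

    d = report.to_dict()
    lines = ["\t".join(columns)]
    for ds in d["datasets"]:
        for run in ds["runs"]:
            lines.append("\t".join(_cell(v) for v in (
                "run", ds["dataset_id"], run["run_id"], ds["engine"],
                run["n_submitted"], run["n_assigned"], run["rate_pct"],
                None, None, None,
                run["n_psms_at_fdr"], run["n_peptides"],
                run["n_protein_groups"], run["n_contaminant_spectra"],
            )))
        lines.append("\t".join(_cell(v) for v in (
            "dataset", ds["dataset_id"], None, ds["engine"],
            ds["n_submitted"], ds["n_assigned"], None,
            ds["pooled_rate_pct"], ds["mean_rate_pct"], None,
            ds["n_psms_at_fdr"], ds["n_peptides"],
            ds["n_protein_groups"], ds["n_contaminant_spectra"],
        )))
    c = d["corpus"]
    lines.append("\t".join(_cell(v) for v in (
        "corpus", None, None, None,
        c["total_submitted"], c["total_assigned"], None,
        c["pooled_rate_pct"], c["mean_dataset_rate_pct"], c["pct_unidentified"],
        None, None, None, None,
    )))
    return "\n".join(lines) + "\n"


def render_summary_figure(report: QcReport, out_path: str | Path) -> Path | None:
    """Pie of assigned vs unassigned spectra plus per-dataset rate bars.

    Purely presentational; returns None (skipping cleanly) when matplotlib
    is unavailable.
    """
    try:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
    except ImportError:
        return None
    d = report.to_dict()
    c = d["corpus"]
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(11, 4.5))
    assigned = c["total_assigned"]
    dark = c["total_submitted"] - assigned
    ax1.pie(
        [assigned, dark],
        labels=[f"assigned\n{assigned:,}", f"unassigned\n{dark:,}"],
        colors=["#2b8cbe", "#bdbdbd"],
        startangle=90,
        autopct="%1.2f%%",
    )
    ax1.set_title("Submitted MS2 spectra")
    names = [ds["dataset_id"] for ds in d["datasets"]]
    rates = [ds["pooled_rate_pct"] for ds in d["datasets"]]
    ax2.bar(range(len(names)), rates, color="#2b8cbe")
    ax2.set_xticks(range(len(names)))
    ax2.set_xticklabels(names, rotation=90, fontsize=7)
    ax2.set_ylabel("identification rate (%)")
    for b in c["baselines"]:
        ax2.axhline(b["rate_pct"], linestyle="--", linewidth=1, color="#e34a33")
        ax2.annotate(
            f"{b['name']} {b['rate_pct']}%",
            xy=(0.99, b["rate_pct"]),
            xycoords=("axes fraction", "data"),
            ha="right", va="bottom", fontsize=7, color="#e34a33",
        )
    ax2.set_title("Per-dataset rates vs repository baselines")
    fig.tight_layout()
    out_path = Path(out_path)
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
    return out_path


# ---------------------------------------------------------------------------
# schema validation (structural subset: type / required / properties / items)
# ---------------------------------------------------------------------------

_TYPES = {
    "object": dict,
    "array": list,
    "string": str,
    "boolean": bool,
    "integer": int,
    "number": (int, float),
    "null": type(None),
}


def load_schema() -> dict:
    with resources.files("ms2qc.schema").joinpath("qc_report.schema.json").open() as fh:
        return json.load(fh)


def validate_report_dict(data: dict, schema: dict | None = None, path: str = "$") -> list[str]:
    """Check a report dict against the shipped schema (structural subset).

    Returns a list of violation messages; empty means valid. Supports the
    ``type`` (including union lists), ``required``, ``properties`` and
    ``items`` keywords, which is all the shipped schema uses.
    """
    schema = schema if schema is not None else load_schema()
    errors: list[str] = []
    stype = schema.get("type")
    if stype is not None:
        allowed = stype if isinstance(stype, list) else [stype]
        ok = False
        for t in allowed:
            py = _TYPES[t]
            if isinstance(data, py) and not (t in ("integer", "number") and isinstance(data, bool)):
                ok = True
                break
        if not ok:
            errors.append(f"{path}: expected {stype}, got {type(data).__name__}")
            return errors
    if isinstance(data, dict):
        for req in schema.get("required", []):
            if req not in data:
                errors.append(f"{path}: missing required key {req!r}")
        for key, subschema in schema.get("properties", {}).items():
            if key in data:
                errors.extend(validate_report_dict(data[key], subschema, f"{path}.{key}"))
    if isinstance(data, list) and "items" in schema:
        for i, item in enumerate(data):
            errors.extend(validate_report_dict(item, schema["items"], f"{path}[{i}]"))
    return errors
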