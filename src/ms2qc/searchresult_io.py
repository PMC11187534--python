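"""Readers for deposited search-engine outputs.

Two families of deposited results are supported, matching what public
palaeoproteomics datasets actually contain:

* an mzIdentML 1.1/1.2 subset (Mascot and friends) — ``SequenceCollection``
  plus ``SpectrumIdentificationList``;
* MaxQuant text outputs — ``summary.txt`` (per-raw-file submitted/identified
  tallies) and ``msms.txt`` (PSM-level detail).

An *assigned spectrum* is a distinct spectrum having at least one rank-1
identification with ``passThreshold`` true; co-ranked or lower-rank items
never double-count a spectrum.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
from lxml import etree

logger = logging.getLogger(__name__)

__all__ = [
    "PsmRecord",
    "MaxQuantRunSummary",
    "ParseReport",
    "MzidResult",
    "MaxQuantSummaryResult",
    "SearchResultFormatError",
    "DEFAULT_DECOY_PREFIXES",
    "parse_mzid",
    "parse_maxquant_summary",
    "parse_maxquant_msms",
]

#: Decoy accession prefixes seen across deposited files; checked only when the
#: file itself carries no isDecoy flag.
DEFAULT_DECOY_PREFIXES: tuple[str, ...] = ("REV__", "DECOY_", "rev_", "XXX_")


class SearchResultFormatError(ValueError):
    """The file is not in the expected search-result format."""


@dataclass(frozen=True)
class PsmRecord:
    """One peptide-spectrum match, normalised across engines.

    ``score`` is oriented so that higher is better (expectation values are
    converted to their negated natural log upstream). ``peptide`` keeps
    bracketed modification mass tags verbatim, e.g. ``PEPT[+15.995]IDE``.
    """

    run_id: str
    spectrum_key: str
    peptide: str
    accessions: tuple[str, ...]
    score: float
    rank: int = 1
    pass_threshold: bool = True
    is_decoy: bool = False
    is_contaminant: bool = False


@dataclass
class MaxQuantRunSummary:
    """One raw-file row of MaxQuant ``summary.txt``."""

    raw_file: str
    n_submitted: int
    n_identified: int
    pct_identified: float


@dataclass
class ParseReport:
    """Record-level problems collected while reading one file."""

    path: str
    n_records: int = 0
    n_skipped: int = 0
    errors: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)


@dataclass
class MzidResult:
    psms: list[PsmRecord]
    n_spectra_queried: int | None
    n_spectra_assigned: int
    report: ParseReport


@dataclass
class MaxQuantSummaryResult:
    runs: list[MaxQuantRunSummary]
    total: MaxQuantRunSummary | None
    report: ParseReport


def _localname(el) -> str:
    tag = el.tag
    return tag.rsplit("}", 1)[-1] if isinstance(tag, str) else str(tag)


def _is_decoy_accession(accession: str, decoy_prefixes: Sequence[str]) -> bool:
    return any(accession.startswith(p) for p in decoy_prefixes)


# cvParam accessions recognised as PSM scores, in priority order.  All are
# already higher-is-better except the expectation values, which are negated
# natural logs after conversion.
_SCORE_CV = {
    "MS:1001171": ("mascot_score", False),        # Mascot:score
    "MS:1002257": ("comet_evalue", True),         # Comet:expectation value
    "MS:1001172": ("mascot_expect", True),        # Mascot:expectation value
    "MS:1001330": ("xtandem_expect", True),       # X!Tandem:expect
    "MS:1002466": ("peptideshaker_score", False),
}


def _extract_score(item_el) -> float | None:
    fallback = None
    for cv in item_el:
        if _localname(cv) != "cvParam":
            continue
        acc = cv.get("accession", "")
        value = cv.get("value")
        if value is None:
            continue
        if acc in _SCORE_CV:
            _, is_expect = _SCORE_CV[acc]
            try:
                v = float(value)
            except ValueError:
                continue
            if is_expect:
                return -math.log(max(v, 1e-300))
            return v
        name = (cv.get("name") or "").lower()
        if fallback is None and name.endswith("score"):
            try:
                fallback = float(value)
            except ValueError:
                pass
    return fallback


def parse_mzid(
    path: str | Path,
    run_id: str | None = None,
    decoy_prefixes: Sequence[str] = DEFAULT_DECOY_PREFIXES,
) -> MzidResult:
    """Parse an mzIdentML file into PSM records and assigned-spectrum count.

    ``n_spectra_assigned`` counts distinct ``SpectrumIdentificationResult``
    elements with at least one rank-1 item whose ``passThreshold`` is true.
    ``n_spectra_queried`` is reported only when the file records the searched
    spectrum count, which the supported subset does not; it is then ``None``.

    Decoy status precedence: an explicit ``isDecoy`` attribute on any mapped
    ``PeptideEvidence``/``DBSequence`` wins; otherwise the configured decoy
    accession prefixes are consulted; otherwise the match is a target.
    """
    path = Path(path)
    rid = run_id if run_id is not None else path.stem
    report = ParseReport(path=str(path))

    # pass 1: reference tables (peptides, evidences, db sequences); also
    # validates the root element early.
    peptides: dict[str, str] = {}
    evidences: dict[str, tuple[str, bool | None]] = {}  # id -> (dbseq_ref, isDecoy)
    dbseqs: dict[str, tuple[str, bool | None]] = {}  # id -> (accession, isDecoy)

    root_checked = False
    context = etree.iterparse(
        str(path), events=("start", "end"), remove_blank_text=True, recover=False
    )
    for event, el in context:
        name = _localname(el)
        if not root_checked and event == "start":
            if name != "MzIdentML":
                raise SearchResultFormatError(
                    f"{path}: root element is <{name}>, not <MzIdentML>"
                )
            root_checked = True
            continue
        if event != "end":
            continue
        if name == "Peptide":
            peptides[el.get("id", "")] = _peptide_with_mods(el)
            el.clear()
        elif name == "PeptideEvidence":
            decoy_attr = el.get("isDecoy")
            evidences[el.get("id", "")] = (
                el.get("dBSequence_ref", ""),
                None if decoy_attr is None else decoy_attr.lower() == "true",
            )
            el.clear()
        elif name == "DBSequence":
            decoy_attr = el.get("isDecoy")
            dbseqs[el.get("id", "")] = (
                el.get("accession", el.get("id", "")),
                None if decoy_attr is None else decoy_attr.lower() == "true",
            )
            el.clear()
        elif name == "SequenceCollection":
            el.clear()

    psms: list[PsmRecord] = []
    n_assigned = 0

    context = etree.iterparse(str(path), events=("end",))
    for _, el in context:
        if _localname(el) != "SpectrumIdentificationResult":
            continue
        spectrum_id = el.get("spectrumID", "")
        spectrum_key = _spectrum_key_from_id(spectrum_id, el)
        assigned_here = False
        for item in el:
            if _localname(item) != "SpectrumIdentificationItem":
                continue
            pep_ref = item.get("peptide_ref")
            if pep_ref is None or pep_ref not in peptides:
                report.n_skipped += 1
                report.errors.append(
                    f"SpectrumIdentificationItem {item.get('id')!r} lacks a "
                    "resolvable peptide reference; skipped"
                )
                continue
            rank = int(item.get("rank", "1"))
            passing = (item.get("passThreshold", "true").lower() == "true")
            accessions: list[str] = []
            any_decoy_attr: bool | None = None
            for child in item:
                if _localname(child) != "PeptideEvidenceRef":
                    continue
                ev_ref = child.get("peptideEvidence_ref", "")
                dbref, ev_decoy = evidences.get(ev_ref, ("", None))
                acc, db_decoy = dbseqs.get(dbref, (dbref, None))
                if acc:
                    accessions.append(acc)
                for flag in (ev_decoy, db_decoy):
                    if flag is not None:
                        any_decoy_attr = (any_decoy_attr or False) or flag
            if not accessions:
                report.n_skipped += 1
                report.errors.append(
                    f"SpectrumIdentificationItem {item.get('id')!r} maps to no "
                    "protein accession; skipped"
                )
                continue
            if any_decoy_attr is not None:
                is_decoy = any_decoy_attr
            else:
                is_decoy = any(
                    _is_decoy_accession(a, decoy_prefixes) for a in accessions
                )
            score = _extract_score(item)
            if score is None:
                report.warnings.append(
                    f"no recognised score on item {item.get('id')!r}; using 0.0"
                )
                score = 0.0
            psms.append(
                PsmRecord(
                    run_id=rid,
                    spectrum_key=spectrum_key,
                    peptide=peptides[pep_ref],
                    accessions=tuple(accessions),
                    score=score,
                    rank=rank,
                    pass_threshold=passing,
                    is_decoy=is_decoy,
                )
            )
            report.n_records += 1
            if rank == 1 and passing:
                assigned_here = True
        if assigned_here:
            n_assigned += 1
        el.clear()

    return MzidResult(
        psms=psms,
        n_spectra_queried=None,
        n_spectra_assigned=n_assigned,
        report=report,
    )


def _peptide_with_mods(pep_el) -> str:
    """Render a Peptide element as sequence with bracketed mass tags."""
    sequence = ""
    mods: list[tuple[int, float]] = []
    for child in pep_el:
        name = _localname(child)
        if name == "PeptideSequence":
            sequence = (child.text or "").strip().upper()
        elif name == "Modification":
            loc = int(child.get("location", "0"))
            delta = float(child.get("monoisotopicMassDelta", "0"))
            mods.append((loc, delta))
    if not mods:
        return sequence
    # insert tags right-to-left so earlier locations stay valid; location 0 is
    # the N-terminus, location len(seq)+1 the C-terminus
    out = sequence
    for loc, delta in sorted(mods, reverse=True):
        pos = min(max(loc, 0), len(sequence))
        tag = f"[{delta:+.6g}]"
        out = out[:pos] + tag + out[pos:]
    return out


def _spectrum_key_from_id(spectrum_id: str, result_el) -> str:
    """Prefer a spectrum title cvParam; fall back to the spectrumID."""
    for cv in result_el:
        if _localname(cv) == "cvParam" and cv.get("accession") == "MS:1000796":
            value = cv.get("value")
            if value:
                return value
    return spectrum_id


# ---------------------------------------------------------------------------
# MaxQuant text outputs
# ---------------------------------------------------------------------------

_SUBMITTED_ALIASES = ("ms/ms", "ms/ms submitted")
_IDENTIFIED_ALIASES = ("ms/ms identified",)
_PCT_ALIASES = ("ms/ms identified [%]",)


def _find_column(columns: Sequence[str], aliases: Sequence[str]) -> str | None:
    lowered = {c.lower().strip(): c for c in columns}
    for alias in aliases:
        if alias in lowered:
            return lowered[alias]
    return None


def parse_maxquant_summary(path: str | Path) -> MaxQuantSummaryResult:
    """Read MaxQuant ``summary.txt`` into per-run submitted/identified tallies.

    The aggregate row (``Raw file == "Total"``) is excluded from ``runs`` but
    kept in ``total`` for cross-checks. A deposited percentage that disagrees
    with the counts by more than 0.05 raises a warning in the parse report,
    not an error.
    """
    path = Path(path)
    report = ParseReport(path=str(path))
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    columns = list(df.columns)
    raw_col = _find_column(columns, ("raw file",))
    sub_col = _find_column(columns, _SUBMITTED_ALIASES)
    id_col = _find_column(columns, _IDENTIFIED_ALIASES)
    pct_col = _find_column(columns, _PCT_ALIASES)
    if raw_col is None or sub_col is None:
        raise SearchResultFormatError(
            f"{path}: no submitted-count column among {columns!r} "
            f"(expected one of {_SUBMITTED_ALIASES})"
        )
    runs: list[MaxQuantRunSummary] = []
    total: MaxQuantRunSummary | None = None
    for _, row in df.iterrows():
        raw_file = row[raw_col].strip()
        if not raw_file:
            continue
        n_sub = int(float(row[sub_col])) if row[sub_col] else 0
        n_id = int(float(row[id_col])) if id_col and row[id_col] else 0
        pct = float(row[pct_col]) if pct_col and row[pct_col] else (
            100.0 * n_id / n_sub if n_sub else 0.0
        )
        rec = MaxQuantRunSummary(
            raw_file=raw_file, n_submitted=n_sub, n_identified=n_id,
            pct_identified=pct,
        )
        if n_id > n_sub:
            report.warnings.append(
                f"{raw_file}: identified ({n_id}) exceeds submitted ({n_sub})"
            )
        elif n_sub > 0 and abs(pct - 100.0 * n_id / n_sub) > 0.05:
            report.warnings.append(
                f"{raw_file}: deposited percentage {pct} disagrees with "
                f"counts {100.0 * n_id / n_sub:.4f}"
            )
        if raw_file.lower() == "total":
            total = rec
        else:
            runs.append(rec)
            report.n_records += 1
    return MaxQuantSummaryResult(runs=runs, total=total, report=report)


def parse_maxquant_msms(
    path: str | Path,
) -> tuple[list[PsmRecord], ParseReport]:
    """Read MaxQuant ``msms.txt`` into PSM records.

    Decoy rows carry ``Reverse == "+"``; contaminant rows carry
    ``Potential contaminant`` (or older ``Contaminant``) ``== "+"``. The
    spectrum key is ``<raw_file>.<scan>``.
    """
    path = Path(path)
    report = ParseReport(path=str(path))
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    columns = list(df.columns)
    raw_col = _find_column(columns, ("raw file",))
    scan_col = _find_column(columns, ("scan number", "scan index"))
    seq_col = _find_column(columns, ("sequence",))
    prot_col = _find_column(columns, ("proteins",))
    score_col = _find_column(columns, ("score",))
    rev_col = _find_column(columns, ("reverse",))
    con_col = _find_column(columns, ("potential contaminant", "contaminant"))
    mods_seq_col = _find_column(columns, ("modified sequence",))
    missing = [
        label
        for label, col in (("Sequence", seq_col), ("Proteins", prot_col))
        if col is None
    ]
    if missing:
        raise SearchResultFormatError(
            f"{path}: missing required column(s) {missing} among {columns!r}"
        )
    psms: list[PsmRecord] = []
    for idx, row in df.iterrows():
        sequence = row[seq_col].strip().upper()
        proteins = row[prot_col].strip()
        if sequence and not proteins:
            report.n_skipped += 1
            report.errors.append(f"row {idx}: non-empty Sequence with empty Proteins; skipped")
            continue
        if not sequence:
            report.n_skipped += 1
            report.errors.append(f"row {idx}: empty Sequence; skipped")
            continue
        raw_file = row[raw_col].strip() if raw_col else path.stem
        scan = row[scan_col].strip() if scan_col else str(idx)
        peptide = sequence
        if mods_seq_col and row[mods_seq_col]:
            peptide = _normalise_mq_modified_sequence(row[mods_seq_col]) or sequence
        psms.append(
            PsmRecord(
                run_id=raw_file,
                spectrum_key=f"{raw_file}.{scan}",
                peptide=peptide,
                accessions=tuple(p.strip() for p in proteins.split(";") if p.strip()),
                score=float(row[score_col]) if score_col and row[score_col] else 0.0,
                rank=1,
                pass_threshold=True,
                is_decoy=bool(rev_col) and row[rev_col].strip() == "+",
                is_contaminant=bool(con_col) and row[con_col].strip() == "+",
            )
        )
        report.n_records += 1
    return psms, report


def _normalise_mq_modified_sequence(mod_seq: str) -> str:
    """Turn MaxQuant ``_PEPT(ox)IDE_`` notation into bracketed-tag form."""
    s = mod_seq.strip().strip("_")
    out: list[str] = []
    depth = 0
    buf: list[str] = []
    for ch in s:
        if ch == "(":
            depth += 1
            if depth == 1:
                buf = []
                continue
        if ch == ")":
            depth -= 1
            if depth == 0:
                out.append(f"[{''.join(buf)}]")
                continue
        if depth > 0:
            buf.append(ch)
        else:
            out.append(ch.upper())
    return "".join(out)
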