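"""Identification-rate accounting and QC statistics.

Core statistic: the bulk identification rate, 100 · (assigned MS2 spectra) /
(submitted MS2 spectra), at run, dataset and corpus level. The corpus
headline uses the pooled (spectrum-weighted) rate; the unweighted mean of
per-run rates is carried alongside since repository-wide "average" rates may
follow either convention.

Also here: target-decoy competition q-values, PSM counts at a predefined FDR,
distinct-peptide and protein-group tallies, the contaminant partition of
assigned spectra, and comparison against repository baseline rates.

Everything in this module is pure computation over already-parsed records.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence

import numpy as np

from .searchresult_io import PsmRecord

__all__ = [
    "AccountingError",
    "UndefinedRateError",
    "InconsistentCountsError",
    "RunAccounting",
    "DatasetAccounting",
    "CorpusAccounting",
    "Baseline",
    "BaselineComparison",
    "QValueTable",
    "ContaminantRules",
    "round_half_up",
    "identification_rate",
    "pct_unidentified",
    "pooled_rate",
    "tdc_qvalues",
    "psms_at_fdr",
    "distinct_peptides",
    "protein_groups",
    "contaminant_partition",
    "compare_to_baselines",
    "build_dataset_accounting",
    "build_corpus_accounting",
]


class AccountingError(ValueError):
    pass


class UndefinedRateError(AccountingError):
    """Rate requested with zero submitted spectra."""


class InconsistentCountsError(AccountingError):
    """More assigned than submitted spectra."""


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round half away from zero at the reporting layer (94.125 -> 94.13)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def identification_rate(n_assigned: int, n_submitted: int) -> float:
    """Percentage of submitted MS2 spectra that were assigned (unrounded)."""
    if n_submitted == 0:
        raise UndefinedRateError("identification rate undefined for 0 submitted spectra")
    if n_assigned > n_submitted:
        raise InconsistentCountsError(
            f"assigned ({n_assigned}) exceeds submitted ({n_submitted})"
        )
    if n_assigned < 0 or n_submitted < 0:
        raise AccountingError("negative spectrum counts")
    return 100.0 * n_assigned / n_submitted


def pct_unidentified(n_assigned: int, n_submitted: int) -> float:
    """Percentage of submitted spectra left unassigned — the dark fraction."""
    return 100.0 - identification_rate(n_assigned, n_submitted)


@dataclass
class RunAccounting:
    """Per-run tallies and optional PSM-level QC metrics.

    The optional metrics are ``None`` (with a reason recorded by the report
    builder) when the dataset ships no PSM-level file.
    """

    run_id: str
    n_submitted: int
    n_assigned: int
    rate_pct: float = field(init=False)
    n_psms_at_fdr: int | None = None
    n_peptides: int | None = None
    n_protein_groups: int | None = None
    n_contaminant_spectra: int | None = None

    def __post_init__(self) -> None:
        self.rate_pct = identification_rate(self.n_assigned, self.n_submitted)
        if (
            self.n_contaminant_spectra is not None
            and self.n_contaminant_spectra > self.n_assigned
        ):
            raise InconsistentCountsError(
                f"{self.run_id}: contaminant spectra ({self.n_contaminant_spectra}) "
                f"exceed assigned ({self.n_assigned})"
            )


@dataclass
class DatasetAccounting:
    dataset_id: str
    engine: str  # "maxquant" | "mzid"
    runs: list[RunAccounting]
    pooled_rate_pct: float = field(init=False)
    mean_rate_pct: float = field(init=False)
    n_psms_at_fdr: int | None = None
    n_peptides: int | None = None
    n_protein_groups: int | None = None
    n_contaminant_spectra: int | None = None

    def __post_init__(self) -> None:
        pooled, mean = pooled_rate(self.runs)
        self.pooled_rate_pct = pooled
        self.mean_rate_pct = mean

    @property
    def n_submitted(self) -> int:
        return sum(r.n_submitted for r in self.runs)

    @property
    def n_assigned(self) -> int:
        return sum(r.n_assigned for r in self.runs)


@dataclass
class Baseline:
    """A repository-wide reference identification rate."""

    name: str
    rate_pct: float
    source_note: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.rate_pct <= 100.0:
            raise AccountingError(f"baseline rate {self.rate_pct} outside [0, 100]")


@dataclass
class BaselineComparison:
    name: str
    baseline_rate_pct: float
    delta_pct: float
    below: bool


@dataclass
class CorpusAccounting:
    datasets: list[DatasetAccounting]
    baselines: list[Baseline] = field(default_factory=list)
    total_submitted: int = field(init=False)
    total_assigned: int = field(init=False)
    pooled_rate_pct: float = field(init=False)
    mean_dataset_rate_pct: float = field(init=False)
    pct_unidentified: float = field(init=False)
    baseline_comparisons: list[BaselineComparison] = field(init=False)

    def __post_init__(self) -> None:
        if not self.datasets:
            raise AccountingError("corpus accounting needs at least one dataset")
        self.total_submitted = sum(d.n_submitted for d in self.datasets)
        self.total_assigned = sum(d.n_assigned for d in self.datasets)
        self.pooled_rate_pct = identification_rate(
            self.total_assigned, self.total_submitted
        )
        self.mean_dataset_rate_pct = float(
            np.mean([d.pooled_rate_pct for d in self.datasets])
        )
        self.pct_unidentified = 100.0 - self.pooled_rate_pct
        self.baseline_comparisons = compare_to_baselines(
            self.pooled_rate_pct, self.baselines
        )


def pooled_rate(runs: Sequence[RunAccounting]) -> tuple[float, float]:
    """Spectrum-weighted pooled rate and unweighted mean of run rates.

    The pooled rate (Σ assigned / Σ submitted) is the headline convention;
    the mean treats every run equally regardless of size.
    """
    if not runs:
        raise UndefinedRateError("pooled rate undefined for an empty run list")
    total_sub = sum(r.n_submitted for r in runs)
    total_asg = sum(r.n_assigned for r in runs)
    pooled = identification_rate(total_asg, total_sub)
    mean = float(np.mean([r.rate_pct for r in runs]))
    return pooled, mean


# ---------------------------------------------------------------------------
# Target-decoy competition
# ---------------------------------------------------------------------------


@dataclass
class QValueTable:
    """Rank-1 PSMs sorted by descending score with monotone q-values.

    ``cum_targets``/``cum_decoys`` count targets and decoys at-or-above each
    row's score (ties share the counts of the whole tie group, so equal scores
    always receive equal q-values regardless of within-tie order).
    """

    psms: list[PsmRecord]
    scores: np.ndarray
    is_decoy: np.ndarray
    q_values: np.ndarray
    cum_targets: np.ndarray
    cum_decoys: np.ndarray


def tdc_qvalues(psms: Iterable[PsmRecord], plus_one: bool = False) -> QValueTable:
    """Estimate q-values by concatenated-search target-decoy competition.

    At each score threshold s the FDR estimate is D(s) / max(T(s), 1), with
    D and T the decoy and target counts at-or-above s (``plus_one`` switches
    to the conservative (D+1) / max(T, 1) estimator). q-values are the
    running minimum of the estimate from the permissive end upward, hence
    non-decreasing down the sorted table.

    Ordering within the table is deterministic: descending score, decoys
    before targets in ties, then spectrum key.
    """
    psms = list(psms)
    for p in psms:
        if p.rank != 1:
            raise AccountingError(
                "target-decoy competition requires rank-1 PSMs only; "
                f"got rank {p.rank} for {p.spectrum_key!r}"
            )
        if not np.isfinite(p.score):
            raise AccountingError(f"non-finite score for {p.spectrum_key!r}")
    psms.sort(key=lambda p: (-p.score, p.is_decoy is False, p.run_id, p.spectrum_key))
    scores = np.array([p.score for p in psms], dtype=float)
    decoy = np.array([p.is_decoy for p in psms], dtype=bool)
    n = len(psms)
    if n == 0:
        empty = np.array([])
        return QValueTable(psms, empty, empty.astype(bool), empty, empty, empty)

    cum_t = np.cumsum(~decoy)
    cum_d = np.cumsum(decoy)
    # extend counts over tie groups: every row of a tie group gets the counts
    # at the group's end, so FDR depends on the score only
    group_end = np.empty(n, dtype=int)
    i = 0
    while i < n:
        j = i
        while j + 1 < n and scores[j + 1] == scores[i]:
            j += 1
        group_end[i : j + 1] = j
        i = j + 1
    t_ge = cum_t[group_end]
    d_ge = cum_d[group_end]
    numer = d_ge + 1 if plus_one else d_ge
    fdr = numer / np.maximum(t_ge, 1)
    q = np.minimum.accumulate(fdr[::-1])[::-1]
    q = np.clip(q, 0.0, 1.0)
    return QValueTable(
        psms=psms,
        scores=scores,
        is_decoy=decoy,
        q_values=q,
        cum_targets=t_ge,
        cum_decoys=d_ge,
    )


def psms_at_fdr(table: QValueTable, alpha: float) -> int:
    """Number of target PSMs accepted at q-value ≤ alpha."""
    if not 0.0 < alpha < 1.0:
        raise AccountingError(f"alpha must lie in (0, 1); got {alpha}")
    if len(table.psms) == 0:
        return 0
    return int(np.sum(~table.is_decoy & (table.q_values <= alpha)))


# ---------------------------------------------------------------------------
# Peptide / protein-group tallies
# ---------------------------------------------------------------------------

_MOD_TAG = re.compile(r"\[[^\]]+\]")


def strip_modifications(peptide: str) -> str:
    return _MOD_TAG.sub("", peptide)


def _target_passing(psms: Iterable[PsmRecord]) -> list[PsmRecord]:
    return [p for p in psms if not p.is_decoy and p.pass_threshold]


def distinct_peptides(psms: Iterable[PsmRecord], strip_mods: bool = True) -> int:
    """Unique peptide strings among target, pass-threshold PSMs."""
    seqs = (p.peptide for p in _target_passing(psms))
    if strip_mods:
        return len({strip_modifications(s) for s in seqs})
    return len(set(seqs))


def protein_groups(psms: Iterable[PsmRecord]) -> int:
    """Count protein groups by identical-evidence merge plus subset removal.

    Accessions sharing an identical set of (stripped) peptides collapse into
    one group; a group whose peptide set is a strict subset of another's is
    subsumed. Deterministic and invariant under PSM or accession order.
    """
    by_acc: dict[str, set[str]] = {}
    for p in _target_passing(psms):
        pep = strip_modifications(p.peptide)
        for acc in p.accessions:
            by_acc.setdefault(acc, set()).add(pep)
    groups = {frozenset(v) for v in by_acc.values() if v}
    surviving = [
        g for g in groups if not any(g < other for other in groups)
    ]
    return len(surviving)


# ---------------------------------------------------------------------------
# Contaminant partition
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ContaminantRules:
    """Accession-based contaminant matching: prefixes plus an explicit list."""

    prefixes: tuple[str, ...] = ("CON__",)
    accessions: frozenset[str] = frozenset()

    def matches(self, accession: str) -> bool:
        return accession in self.accessions or any(
            accession.startswith(p) for p in self.prefixes
        )


def contaminant_partition(
    psms: Iterable[PsmRecord], rules: ContaminantRules | None = None
) -> tuple[int, int]:
    """Partition assigned spectra into (contaminant, other).

    A spectrum is contaminant only when *every* accession of its rank-1
    passing target PSM matches the rules: peptides shared with
    non-contaminant proteins are conservatively kept as non-contaminant.
    Flags set upstream (e.g. MaxQuant's contaminant column) are honoured.
    """
    rules = rules if rules is not None else ContaminantRules()
    spectra: dict[tuple[str, str], bool] = {}
    for p in _target_passing(psms):
        if p.rank != 1:
            continue
        key = (p.run_id, p.spectrum_key)
        is_con = p.is_contaminant or all(rules.matches(a) for a in p.accessions)
        # a spectrum with any non-contaminant interpretation stays non-contaminant
        spectra[key] = spectra.get(key, True) and is_con
    n_con = sum(spectra.values())
    return n_con, len(spectra) - n_con


# ---------------------------------------------------------------------------
# Baselines and aggregation
# ---------------------------------------------------------------------------


def compare_to_baselines(
    rate_pct: float, baselines: Sequence[Baseline]
) -> list[BaselineComparison]:
    """Delta (rate − baseline) and a below-baseline flag per baseline."""
    return [
        BaselineComparison(
            name=b.name,
            baseline_rate_pct=b.rate_pct,
            delta_pct=rate_pct - b.rate_pct,
            below=rate_pct < b.rate_pct,
        )
        for b in baselines
    ]


def build_dataset_accounting(
    dataset_id: str,
    engine: str,
    runs: Sequence[RunAccounting],
    psms: Sequence[PsmRecord] | None = None,
    fdr_alpha: float = 0.01,
    contaminant_rules: ContaminantRules | None = None,
) -> DatasetAccounting:
    """Assemble a dataset's accounting, deriving PSM-level metrics when given.

    q-values are computed across the dataset's pooled PSMs (one search, one
    competition); per-run PSM metrics are filled in by the pipeline.
    """
    ds = DatasetAccounting(dataset_id=dataset_id, engine=engine, runs=list(runs))
    if psms:
        table = tdc_qvalues([p for p in psms if p.rank == 1])
        ds.n_psms_at_fdr = psms_at_fdr(table, fdr_alpha)
        ds.n_peptides = distinct_peptides(psms)
        ds.n_protein_groups = protein_groups(psms)
        n_con, _ = contaminant_partition(psms, contaminant_rules)
        ds.n_contaminant_spectra = n_con
    return ds


def build_corpus_accounting(
    datasets: Sequence[DatasetAccounting],
    baselines: Sequence[Baseline] = (),
) -> CorpusAccounting:
    return CorpusAccounting(datasets=list(datasets), baselines=list(baselines))
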