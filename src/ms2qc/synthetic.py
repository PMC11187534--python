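"""Synthetic corpora with known ground truth.

Generates matched MGF peak lists and search outputs (a minimal mzIdentML
subset, or MaxQuant-style ``summary.txt``/``msms.txt``) plus a manifest of
every planted quantity, so the whole accounting pipeline can be exercised
and checked exactly without downloading any public dataset.

The emulated shape follows the mined palaeoproteomics corpora: Orbitrap-style
DDA acquisitions (precursor m/z 300–1600, charge 2–4), a small fraction of
spectra carrying passing identifications, decoy matches drawn from a
lower-scoring Gaussian, and a configurable contaminant fraction among the
assigned spectra. Identified counts are planted as exact integers
(``floor(spectra_per_run · id_rate)``), so rate recovery is exact and only
FDR-derived quantities are stochastic.

Fixed seed ⇒ byte-identical files and manifest.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml
from lxml import etree

from .peaklist_io import SpectrumRecord, write_mgf

__all__ = [
    "SynthConfig",
    "DatasetSpec",
    "SynthManifest",
    "generate_corpus",
    "worked_corpus",
    "WORKED_DATASETS",
]

_AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Common laboratory contaminant accessions (MaxQuant-style CON__ prefix):
#: trypsin and human skin keratins dominate real contaminant hits.
_CONTAMINANT_ACCESSIONS = (
    "CON__TRYP_PIG",
    "CON__K1C10_HUMAN",
    "CON__K2C1_HUMAN",
    "CON__K1C9_HUMAN",
    "CON__ALBU_BOVIN",
)


@dataclass
class DatasetSpec:
    """Resolved per-dataset generation parameters."""

    dataset_id: str
    engine: str  # "mzid" | "maxquant"
    spectra_per_run: int
    n_assigned_per_run: int
    runs: int = 1


@dataclass
class SynthConfig:
    """Ground-truth parameters of a synthetic corpus.

    ``id_rates`` may be a single fraction applied to every dataset or one
    fraction per dataset (to emulate the wide spread of rates across real
    deposited datasets). ``dataset_specs`` overrides the uniform parameters
    entirely when given (used by :func:`worked_corpus`).

    The score model is two Gaussians on an arbitrary search-engine score
    scale: targets ~ N(mu_target, sigma), decoys ~ N(mu_decoy, sigma) with
    mu_target > mu_decoy. ``decoy_count`` of None plants one decoy match per
    assigned spectrum.
    """

    n_datasets: int = 15
    runs_per_dataset: int = 1
    spectra_per_run: int = 1000
    id_rates: float | Sequence[float] = 0.0588
    contaminant_fraction: float = 0.10
    decoy_count: int | None = None
    mu_target: float = 60.0
    mu_decoy: float = 20.0
    sigma: float = 8.0
    peptide_length: tuple[int, int] = (7, 20)
    alphabet: str = _AMINO_ACIDS
    engine_flavor: str = "mzid"  # applied to every dataset unless overridden
    seed: int = 0
    dataset_specs: list[DatasetSpec] | None = None
    peaks_per_spectrum: tuple[int, int] = (5, 12)

    def __post_init__(self) -> None:
        if not 0.0 <= self.contaminant_fraction <= 1.0:
            raise ValueError("contaminant_fraction must lie in [0, 1]")
        if self.mu_target <= self.mu_decoy:
            raise ValueError("score model requires mu_target > mu_decoy")
        rates = self._rate_list()
        if any(not 0.0 <= r <= 1.0 for r in rates):
            raise ValueError("id_rates must lie in [0, 1]")

    def _rate_list(self) -> list[float]:
        if isinstance(self.id_rates, (int, float)):
            return [float(self.id_rates)] * self.n_datasets
        rates = [float(r) for r in self.id_rates]
        if len(rates) != self.n_datasets:
            raise ValueError(
                f"id_rates has {len(rates)} entries for {self.n_datasets} datasets"
            )
        return rates

    def resolve_specs(self) -> list[DatasetSpec]:
        if self.dataset_specs is not None:
            return list(self.dataset_specs)
        if self.spectra_per_run <= 0:
            raise ValueError("spectra_per_run must be positive")
        specs = []
        for i, rate in enumerate(self._rate_list(), start=1):
            specs.append(
                DatasetSpec(
                    dataset_id=f"SYND{i:03d}",
                    engine=self.engine_flavor,
                    spectra_per_run=self.spectra_per_run,
                    n_assigned_per_run=math.floor(self.spectra_per_run * rate + 1e-9),
                    runs=self.runs_per_dataset,
                )
            )
        return specs


@dataclass
class SynthManifest:
    """Ground-truth ledger for one generated corpus (paths relative)."""

    out_dir: str
    datasets: list[dict]
    total_submitted: int
    total_assigned: int
    total_contaminant: int
    total_decoys: int
    n_true_positive_psms: int
    config: dict = field(default_factory=dict)
    corpus_config_path: str = "corpus_config.yaml"

    def to_dict(self) -> dict:
        return {
            "datasets": self.datasets,
            "total_submitted": self.total_submitted,
            "total_assigned": self.total_assigned,
            "total_contaminant": self.total_contaminant,
            "total_decoys": self.total_decoys,
            "n_true_positive_psms": self.n_true_positive_psms,
            "config": self.config,
            "corpus_config_path": self.corpus_config_path,
        }

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")


def _random_peptide(rng: np.random.Generator, config: SynthConfig) -> str:
    lo, hi = config.peptide_length
    length = int(rng.integers(lo, hi + 1))
    letters = rng.integers(0, len(config.alphabet), size=length)
    return "".join(config.alphabet[i] for i in letters)


def _unique_peptides(rng: np.random.Generator, config: SynthConfig, n: int,
                     taken: set[str]) -> list[str]:
    out: list[str] = []
    while len(out) < n:
        pep = _random_peptide(rng, config)
        if pep not in taken:
            taken.add(pep)
            out.append(pep)
    return out


def _make_spectra(
    rng: np.random.Generator, run_id: str, n: int, config: SynthConfig
) -> list[SpectrumRecord]:
    """DDA-plausible MS2 spectra: m/z 300–1600, charge 2–4, HCD-like peaks."""
    prec_mz = rng.uniform(300.0, 1600.0, size=n)
    charges = rng.integers(2, 5, size=n)
    rts = np.sort(rng.uniform(0.0, 3600.0, size=n))
    lo, hi = config.peaks_per_spectrum
    n_peaks = rng.integers(lo, hi + 1, size=n)
    records = []
    for i in range(n):
        k = int(n_peaks[i])
        mz = np.sort(rng.uniform(100.0, 1500.0, size=k))
        inten = np.round(10.0 ** rng.uniform(2.0, 6.0, size=k), 1)
        records.append(
            SpectrumRecord(
                run_id=run_id,
                ordinal=i,
                title=f"{run_id}.{i}.{i}.{int(charges[i])}",
                precursor_mz=round(float(prec_mz[i]), 4),
                charge=int(charges[i]),
                rt_seconds=round(float(rts[i]), 2),
                mz=[round(float(x), 4) for x in mz],
                intensity=[float(x) for x in inten],
            )
        )
    return records


@dataclass
class _PlantedRun:
    run_id: str
    mgf_path: str
    n_submitted: int
    assigned: list[dict]  # ordinal, title, peptide, accession, score, contaminant
    decoys: list[dict]    # ordinal, title, peptide, accession, score


def _plant_run(
    rng: np.random.Generator,
    run_id: str,
    spec: DatasetSpec,
    config: SynthConfig,
    target_pool: list[tuple[str, str]],       # (peptide, accession)
    contaminant_pool: list[tuple[str, str]],
    spectra: list[SpectrumRecord],
) -> _PlantedRun:
    n = spec.spectra_per_run
    n_assigned = spec.n_assigned_per_run
    if n_assigned > n:
        raise ValueError(f"{run_id}: more assignments than spectra")
    assigned_ord = np.sort(rng.choice(n, size=n_assigned, replace=False))
    n_con = math.floor(n_assigned * config.contaminant_fraction + 1e-9)
    con_positions = set(
        rng.choice(n_assigned, size=n_con, replace=False).tolist()
    ) if n_con else set()
    target_scores = rng.normal(config.mu_target, config.sigma, size=n_assigned)

    assigned = []
    for j, ordinal in enumerate(assigned_ord.tolist()):
        if j in con_positions:
            pep, acc = contaminant_pool[int(rng.integers(0, len(contaminant_pool)))]
            contaminant = True
        else:
            pep, acc = target_pool[int(rng.integers(0, len(target_pool)))]
            contaminant = False
        assigned.append(
            {
                "ordinal": int(ordinal),
                "title": spectra[ordinal].title,
                "peptide": pep,
                "accession": acc,
                "score": round(float(target_scores[j]), 3),
                "contaminant": contaminant,
            }
        )

    n_decoys = config.decoy_count if config.decoy_count is not None else n_assigned
    unassigned = np.setdiff1d(np.arange(n), assigned_ord)
    n_decoys = min(n_decoys, len(unassigned))
    decoy_ord = np.sort(rng.choice(unassigned, size=n_decoys, replace=False)) if n_decoys else []
    decoy_scores = rng.normal(config.mu_decoy, config.sigma, size=n_decoys)
    decoys = []
    for j, ordinal in enumerate(list(decoy_ord)):
        decoys.append(
            {
                "ordinal": int(ordinal),
                "title": spectra[int(ordinal)].title,
                "peptide": _random_peptide(rng, config),
                "accession": f"REV__SYNP{int(rng.integers(0, 10_000)):05d}",
                "score": round(float(decoy_scores[j]), 3),
            }
        )
    return _PlantedRun(
        run_id=run_id,
        mgf_path="",
        n_submitted=n,
        assigned=assigned,
        decoys=decoys,
    )


# ---------------------------------------------------------------------------
# result writers
# ---------------------------------------------------------------------------

_MZID_NS = "http://psidev.info/psi/pi/mzIdentML/1.1"


def _write_mzid(path: Path, run: _PlantedRun) -> None:
    """Emit the minimal mzIdentML 1.1 subset the reader consumes.

    SequenceCollection (DBSequence with isDecoy, Peptide, PeptideEvidence)
    plus one SpectrumIdentificationResult per matched spectrum; decoy matches
    carry ``passThreshold="false"`` and their lower planted scores.
    """
    root = etree.Element("MzIdentML", nsmap={None: _MZID_NS})
    root.set("version", "1.1.0")
    root.set("id", f"synthetic_{run.run_id}")

    seq_coll = etree.SubElement(root, "SequenceCollection")
    matches = [(m, False) for m in run.assigned] + [(m, True) for m in run.decoys]

    accessions: dict[str, bool] = {}
    peptides: dict[str, str] = {}
    for m, is_decoy in matches:
        accessions.setdefault(m["accession"], is_decoy)
        peptides.setdefault(m["peptide"], f"Pep_{len(peptides) + 1}")
    for acc, is_decoy in accessions.items():
        db = etree.SubElement(seq_coll, "DBSequence")
        db.set("id", f"DBSeq_{acc}")
        db.set("accession", acc)
        db.set("isDecoy", "true" if is_decoy else "false")
        db.set("searchDatabase_ref", "SDB1")
    for pep, pid in peptides.items():
        pel = etree.SubElement(seq_coll, "Peptide")
        pel.set("id", pid)
        seq_el = etree.SubElement(pel, "PeptideSequence")
        seq_el.text = pep
    evidence_ids: dict[tuple[str, str], str] = {}
    for m, is_decoy in matches:
        key = (m["peptide"], m["accession"])
        if key in evidence_ids:
            continue
        eid = f"PE_{len(evidence_ids) + 1}"
        evidence_ids[key] = eid
        ev = etree.SubElement(seq_coll, "PeptideEvidence")
        ev.set("id", eid)
        ev.set("peptide_ref", peptides[m["peptide"]])
        ev.set("dBSequence_ref", f"DBSeq_{m['accession']}")
        ev.set("isDecoy", "true" if is_decoy else "false")

    data_coll = etree.SubElement(root, "DataCollection")
    analysis = etree.SubElement(data_coll, "AnalysisData")
    sil = etree.SubElement(analysis, "SpectrumIdentificationList")
    sil.set("id", "SIL_1")

    by_ordinal = sorted(matches, key=lambda t: t[0]["ordinal"])
    for i, (m, is_decoy) in enumerate(by_ordinal, start=1):
        sir = etree.SubElement(sil, "SpectrumIdentificationResult")
        sir.set("id", f"SIR_{i}")
        sir.set("spectrumID", f"index={m['ordinal']}")
        sir.set("spectraData_ref", "SD_1")
        sii = etree.SubElement(sir, "SpectrumIdentificationItem")
        sii.set("id", f"SII_{i}")
        sii.set("rank", "1")
        sii.set("passThreshold", "false" if is_decoy else "true")
        sii.set("peptide_ref", peptides[m["peptide"]])
        cv = etree.SubElement(sii, "cvParam")
        cv.set("cvRef", "PSI-MS")
        cv.set("accession", "MS:1001171")
        cv.set("name", "Mascot:score")
        cv.set("value", f"{m['score']:.3f}")
        per = etree.SubElement(sii, "PeptideEvidenceRef")
        per.set(
            "peptideEvidence_ref", evidence_ids[(m["peptide"], m["accession"])]
        )
        title_cv = etree.SubElement(sir, "cvParam")
        title_cv.set("cvRef", "PSI-MS")
        title_cv.set("accession", "MS:1000796")
        title_cv.set("name", "spectrum title")
        title_cv.set("value", m["title"])

    tree = etree.ElementTree(root)
    tree.write(
        str(path), pretty_print=True, xml_declaration=True, encoding="UTF-8"
    )


def _write_maxquant(dataset_dir: Path, runs: list[_PlantedRun]) -> list[str]:
    """Write summary.txt and msms.txt for one dataset; returns the paths."""
    summary_path = dataset_dir / "summary.txt"
    msms_path = dataset_dir / "msms.txt"
    with open(summary_path, "w") as fh:
        fh.write("Raw file\tMS/MS\tMS/MS Identified\tMS/MS Identified [%]\n")
        tot_sub = tot_id = 0
        for run in runs:
            n_id = len(run.assigned)
            pct = 100.0 * n_id / run.n_submitted if run.n_submitted else 0.0
            fh.write(f"{run.run_id}\t{run.n_submitted}\t{n_id}\t{pct:.2f}\n")
            tot_sub += run.n_submitted
            tot_id += n_id
        tot_pct = 100.0 * tot_id / tot_sub if tot_sub else 0.0
        fh.write(f"Total\t{tot_sub}\t{tot_id}\t{tot_pct:.2f}\n")
    with open(msms_path, "w") as fh:
        fh.write(
            "Raw file\tScan number\tSequence\tModified sequence\tProteins\t"
            "Score\tReverse\tPotential contaminant\n"
        )
        for run in runs:
            for m in run.assigned:
                con = "+" if m["contaminant"] else ""
                fh.write(
                    f"{run.run_id}\t{m['ordinal']}\t{m['peptide']}\t"
                    f"_{m['peptide']}_\t{m['accession']}\t{m['score']:.3f}\t\t{con}\n"
                )
            for m in run.decoys:
                fh.write(
                    f"{run.run_id}\t{m['ordinal']}\t{m['peptide']}\t"
                    f"_{m['peptide']}_\t{m['accession']}\t{m['score']:.3f}\t+\t\n"
                )
    return [str(summary_path), str(msms_path)]


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------


def generate_corpus(config: SynthConfig, out_dir: str | Path) -> SynthManifest:
    """Write a full synthetic corpus and return its ground-truth manifest.

    Layout: one subdirectory per dataset holding the per-run MGFs plus either
    one .mzid per run or a dataset-level summary.txt/msms.txt pair, a
    ``manifest.json`` ground-truth ledger, and a pipeline-ready
    ``corpus_config.yaml`` with relative paths.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    specs = config.resolve_specs()
    if not specs:
        raise ValueError("config resolves to zero datasets")
    for spec in specs:
        if spec.spectra_per_run <= 0:
            raise ValueError(f"{spec.dataset_id}: spectra_per_run must be positive")
    rng = np.random.default_rng(config.seed)

    manifest_datasets: list[dict] = []
    config_datasets: list[dict] = []
    totals = {"submitted": 0, "assigned": 0, "contaminant": 0, "decoys": 0}

    taken_peptides: set[str] = set()
    for spec in specs:
        dataset_dir = out_dir / spec.dataset_id
        dataset_dir.mkdir(exist_ok=True)
        ds_assigned_total = spec.n_assigned_per_run * spec.runs

        # disjoint peptide→protein planting: every peptide belongs to exactly
        # one accession, so the planted protein-group count is simply the
        # number of accessions observed (no identical sets, no subsumption)
        pool_size = max(1, math.ceil(0.8 * max(ds_assigned_total, 1)))
        peptides = _unique_peptides(rng, config, pool_size, taken_peptides)
        target_pool = [
            (pep, f"{spec.dataset_id}_PROT{1 + i // 5:04d}")
            for i, pep in enumerate(peptides)
        ]
        n_con_pep = max(1, pool_size // 10)
        con_peptides = _unique_peptides(rng, config, n_con_pep, taken_peptides)
        contaminant_pool = [
            (pep, _CONTAMINANT_ACCESSIONS[i % len(_CONTAMINANT_ACCESSIONS)])
            for i, pep in enumerate(con_peptides)
        ]

        runs: list[_PlantedRun] = []
        run_entries: list[dict] = []
        mgf_paths: list[str] = []
        for k in range(1, spec.runs + 1):
            run_id = f"{spec.dataset_id}_r{k}"
            spectra = _make_spectra(rng, run_id, spec.spectra_per_run, config)
            planted = _plant_run(
                rng, run_id, spec, config, target_pool, contaminant_pool, spectra
            )
            mgf_path = dataset_dir / f"{run_id}.mgf"
            with open(mgf_path, "w") as fh:
                write_mgf(spectra, fh)
            planted.mgf_path = str(mgf_path.relative_to(out_dir))
            runs.append(planted)
            mgf_paths.append(planted.mgf_path)

        result_paths: list[str] = []
        if spec.engine == "mzid":
            for run in runs:
                mzid_path = dataset_dir / f"{run.run_id}.mzid"
                _write_mzid(mzid_path, run)
                result_paths.append(str(mzid_path.relative_to(out_dir)))
        elif spec.engine == "maxquant":
            written = _write_maxquant(dataset_dir, runs)
            result_paths = [str(Path(p).relative_to(out_dir)) for p in written]
        else:
            raise ValueError(f"{spec.dataset_id}: unknown engine flavour {spec.engine!r}")

        used_peptides = set()
        used_accessions = set()
        ds_con = ds_dec = 0
        for run in runs:
            for m in run.assigned:
                used_peptides.add(m["peptide"])
                used_accessions.add(m["accession"])
            ds_con += sum(1 for m in run.assigned if m["contaminant"])
            ds_dec += len(run.decoys)
            run_entries.append(
                {
                    "run_id": run.run_id,
                    "mgf": run.mgf_path,
                    "n_submitted": run.n_submitted,
                    "n_assigned": len(run.assigned),
                    "n_contaminant": sum(1 for m in run.assigned if m["contaminant"]),
                    "n_decoys": len(run.decoys),
                }
            )
        ds_sub = sum(r.n_submitted for r in runs)
        ds_asg = sum(len(r.assigned) for r in runs)
        manifest_datasets.append(
            {
                "dataset_id": spec.dataset_id,
                "engine": spec.engine,
                "runs": run_entries,
                "results": result_paths,
                "n_submitted": ds_sub,
                "n_assigned": ds_asg,
                "n_contaminant": ds_con,
                "n_decoys": ds_dec,
                "n_distinct_peptides": len(used_peptides),
                "n_protein_groups": len(used_accessions),
            }
        )
        config_datasets.append(
            {
                "dataset_id": spec.dataset_id,
                "engine": spec.engine,
                "peaklists": mgf_paths,
                "results": result_paths,
            }
        )
        totals["submitted"] += ds_sub
        totals["assigned"] += ds_asg
        totals["contaminant"] += ds_con
        totals["decoys"] += ds_dec

    corpus_config = {
        "datasets": config_datasets,
        "fdr_alpha": 0.01,
        "denominator": "mgf",
    }
    config_path = out_dir / "corpus_config.yaml"
    with open(config_path, "w") as fh:
        yaml.safe_dump(corpus_config, fh, sort_keys=False)

    manifest = SynthManifest(
        out_dir=str(out_dir),
        datasets=manifest_datasets,
        total_submitted=totals["submitted"],
        total_assigned=totals["assigned"],
        total_contaminant=totals["contaminant"],
        total_decoys=totals["decoys"],
        n_true_positive_psms=totals["assigned"],
        config={
            "seed": config.seed,
            "contaminant_fraction": config.contaminant_fraction,
            "mu_target": config.mu_target,
            "mu_decoy": config.mu_decoy,
            "sigma": config.sigma,
            "n_datasets": len(specs),
        },
    )
    manifest.save(out_dir / "manifest.json")
    return manifest


#: The deterministic 1:1000-scale corpus used throughout the documentation:
#: 15 datasets, 14,970 submitted and 880 assigned spectra in total, dataset
#: rates spanning 0.47%–12.61%, and 11 of 15 datasets MaxQuant-flavoured
#: (the remaining 4 deposited as mzIdentML). Individual dataset sizes are
#: fixed arbitrary values consistent with those totals.
WORKED_DATASETS: tuple[tuple[str, str, int, int], ...] = (
    ("SYND001", "mzid", 1700, 8),       # 0.47 %
    ("SYND002", "maxquant", 1110, 140), # 12.61 %
    ("SYND003", "maxquant", 1020, 9),
    ("SYND004", "maxquant", 980, 12),
    ("SYND005", "mzid", 1050, 21),
    ("SYND006", "maxquant", 870, 22),
    ("SYND007", "maxquant", 1040, 35),
    ("SYND008", "mzid", 760, 31),
    ("SYND009", "maxquant", 990, 50),
    ("SYND010", "maxquant", 1200, 101),
    ("SYND011", "maxquant", 840, 57),
    ("SYND012", "maxquant", 1010, 109),
    ("SYND013", "mzid", 700, 82),
    ("SYND014", "maxquant", 950, 115),
    ("SYND015", "maxquant", 750, 88),
)


def worked_corpus(out_dir: str | Path | None = None, seed: int = 7) -> SynthManifest:
    """Generate the deterministic worked corpus (14,970 / 880 spectra).

    A 1:1000-scale stand-in for a 15-dataset corpus of 14.97 million
    submitted and 0.88 million assigned MS2 spectra: pooled rate 5.88%,
    unidentified fraction 94.12%, dataset rates from 0.47% to 12.61%.
    """
    if out_dir is None:
        import tempfile

        out_dir = tempfile.mkdtemp(prefix="ms2qc_worked_")
    specs = [
        DatasetSpec(
            dataset_id=ds_id,
            engine=engine,
            spectra_per_run=n_spectra,
            n_assigned_per_run=n_assigned,
            runs=1,
        )
        for ds_id, engine, n_spectra, n_assigned in WORKED_DATASETS
    ]
    config = SynthConfig(seed=seed, dataset_specs=specs)
    return generate_corpus(config, out_dir)
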