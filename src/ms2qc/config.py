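"""Corpus configuration: dataset manifests, thresholds, baselines, rules.

A corpus manifest lists, per dataset, the peak lists (.mgf) and the search
results (.mzid or MaxQuant summary.txt / msms.txt). Only complete datasets —
at least one peak list and one result file — are accepted; incomplete entries
fail loading rather than silently shrinking the denominator.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .accounting import Baseline, ContaminantRules
from .searchresult_io import DEFAULT_DECOY_PREFIXES

__all__ = [
    "DatasetEntry",
    "CorpusManifestConfig",
    "CompletenessError",
    "default_baselines",
    "load_config",
    "dump_config",
    "default_config_yaml",
]

#: Repository-wide average MS2 identification rates used as reference points.
_PRIDE_BASELINE = 25.78
_MASSIVE_BASELINE = 26.28


def default_baselines() -> list[Baseline]:
    return [
        Baseline("PRIDE", _PRIDE_BASELINE, "average identification rate of PRIDE MS2 data"),
        Baseline("MassIVE", _MASSIVE_BASELINE, "average identification rate of the MassIVE depository"),
    ]


class CompletenessError(ValueError):
    """A dataset lacks peak lists or search results."""


@dataclass
class DatasetEntry:
    dataset_id: str
    engine: str  # "maxquant" | "mzid"
    peaklists: list[str]
    results: list[str]

    def validate(self) -> None:
        if self.engine not in ("maxquant", "mzid"):
            raise ValueError(
                f"{self.dataset_id}: unknown engine {self.engine!r} "
                "(expected 'maxquant' or 'mzid')"
            )
        if not self.peaklists or not self.results:
            raise CompletenessError(
                f"{self.dataset_id}: complete datasets need at least one peak "
                "list (.mgf) and one search-result file"
            )


@dataclass
class CorpusManifestConfig:
    datasets: list[DatasetEntry]
    fdr_alpha: float = 0.01
    contaminant_rules: ContaminantRules = field(default_factory=ContaminantRules)
    baselines: list[Baseline] = field(default_factory=default_baselines)
    decoy_prefixes: tuple[str, ...] = DEFAULT_DECOY_PREFIXES
    rounding_decimals: int = 2
    #: denominator convention: "mgf" counts BEGIN IONS blocks in the peak
    #: lists; "maxquant" trusts summary.txt "MS/MS" tallies where available.
    denominator: str = "mgf"

    def validate(self) -> None:
        if not self.datasets:
            raise CompletenessError("corpus config lists no datasets")
        for d in self.datasets:
            d.validate()
        if not 0.0 < self.fdr_alpha < 1.0:
            raise ValueError(f"fdr_alpha must lie in (0, 1); got {self.fdr_alpha}")
        if self.denominator not in ("mgf", "maxquant"):
            raise ValueError(f"unknown denominator convention {self.denominator!r}")

    def to_dict(self) -> dict:
        return {
            "datasets": [
                {
                    "dataset_id": d.dataset_id,
                    "engine": d.engine,
                    "peaklists": list(d.peaklists),
                    "results": list(d.results),
                }
                for d in self.datasets
            ],
            "fdr_alpha": self.fdr_alpha,
            "contaminant_rules": {
                "prefixes": list(self.contaminant_rules.prefixes),
                "accessions": sorted(self.contaminant_rules.accessions),
            },
            "baselines": [
                {"name": b.name, "rate_pct": b.rate_pct, "source_note": b.source_note}
                for b in self.baselines
            ],
            "decoy_prefixes": list(self.decoy_prefixes),
            "rounding_decimals": self.rounding_decimals,
            "denominator": self.denominator,
        }

    def digest(self) -> str:
        """Stable sha256 of the normalised config, for report provenance."""
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(text.encode()).hexdigest()[:16]


def _config_from_dict(data: dict, base_dir: Path | None = None) -> CorpusManifestConfig:
    def _resolve(p: str) -> str:
        path = Path(p)
        if base_dir is not None and not path.is_absolute():
            path = base_dir / path
        return str(path)

    datasets = [
        DatasetEntry(
            dataset_id=d["dataset_id"],
            engine=d.get("engine", "maxquant"),
            peaklists=[_resolve(p) for p in d.get("peaklists", [])],
            results=[_resolve(p) for p in d.get("results", [])],
        )
        for d in data.get("datasets", [])
    ]
    rules_d = data.get("contaminant_rules", {})
    rules = ContaminantRules(
        prefixes=tuple(rules_d.get("prefixes", ("CON__",))),
        accessions=frozenset(rules_d.get("accessions", ())),
    )
    baselines = [
        Baseline(b["name"], float(b["rate_pct"]), b.get("source_note", ""))
        for b in data.get("baselines", [])
    ] or default_baselines()
    cfg = CorpusManifestConfig(
        datasets=datasets,
        fdr_alpha=float(data.get("fdr_alpha", 0.01)),
        contaminant_rules=rules,
        baselines=baselines,
        decoy_prefixes=tuple(data.get("decoy_prefixes", DEFAULT_DECOY_PREFIXES)),
        rounding_decimals=int(data.get("rounding_decimals", 2)),
        denominator=data.get("denominator", "mgf"),
    )
    cfg.validate()
    return cfg


def load_config(path: str | Path) -> CorpusManifestConfig:
    """Load and validate a corpus config; relative paths resolve against it."""
    path = Path(path)
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return _config_from_dict(data, base_dir=path.parent)


def dump_config(config: CorpusManifestConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)


def default_config_yaml() -> str:
    """The full default configuration as YAML, for ``--show-config``."""
    skeleton = CorpusManifestConfig(
        datasets=[
            DatasetEntry(
                dataset_id="EXAMPLE001",
                engine="maxquant",
                peaklists=["runs/example_run1.mgf"],
                results=["search/summary.txt", "search/msms.txt"],
            )
        ]
    )
    return yaml.safe_dump(skeleton.to_dict(), sort_keys=False)
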