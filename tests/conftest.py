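import pytest

from ms2qc.config import load_config
from ms2qc.pipeline import run_corpus
from ms2qc.reporting import build_report
from ms2qc.searchresult_io import PsmRecord
from ms2qc.synthetic import worked_corpus


def make_psm(
    score: float,
    is_decoy: bool = False,
    key: str = "s0",
    peptide: str = "PEPTIDEK",
    accessions: tuple[str, ...] = ("PROT0001",),
    run_id: str = "run1",
    rank: int = 1,
    pass_threshold: bool = True,
    is_contaminant: bool = False,
) -> PsmRecord:
    return PsmRecord(
        run_id=run_id,
        spectrum_key=key,
        peptide=peptide,
        accessions=accessions,
        score=score,
        rank=rank,
        pass_threshold=pass_threshold,
        is_decoy=is_decoy,
        is_contaminant=is_contaminant,
    )


@pytest.fixture(scope="session")
def worked(tmp_path_factory):
    """The deterministic 1:1000-scale corpus, run end to end once."""
    out = tmp_path_factory.mktemp("worked_corpus")
    manifest = worked_corpus(out)
    config = load_config(out / "corpus_config.yaml")
    result = run_corpus(config)
    report = build_report(
        result.corpus, config, provenance=result.provenance, missing=result.missing,
        generated_at="1970-01-01T00:00:00+00:00",
    )
    return {
        "manifest": manifest,
        "config": config,
        "result": result,
        "report": report,
        "report_dict": report.to_dict(),
    }
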