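"""mzIdentML and MaxQuant output parsing."""

import textwrap

import pytest

from ms2qc.searchresult_io import (
    SearchResultFormatError,
    parse_maxquant_msms,
    parse_maxquant_summary,
    parse_mzid,
)

MZID_HEADER = """\
<?xml version="1.0" encoding="UTF-8"?>
<MzIdentML xmlns="http://psidev.info/psi/pi/mzIdentML/1.1" version="1.1.0" id="fixture">
  <SequenceCollection>
    <DBSequence id="DB_T1" accession="COL1A1_BOVIN" searchDatabase_ref="SDB1"/>
    <DBSequence id="DB_T2" accession="ALBU_HUMAN" searchDatabase_ref="SDB1"/>
    <DBSequence id="DB_D1" accession="REV__COL1A1_BOVIN" isDecoy="true" searchDatabase_ref="SDB1"/>
    <Peptide id="Pep_A"><PeptideSequence>GPPGPAGER</PeptideSequence></Peptide>
    <Peptide id="Pep_B"><PeptideSequence>LVNELTEFAK</PeptideSequence></Peptide>
    <Peptide id="Pep_C">
      <PeptideSequence>MPEPTIDEK</PeptideSequence>
      <Modification location="1" monoisotopicMassDelta="15.994915"/>
    </Peptide>
    <PeptideEvidence id="PE_A" peptide_ref="Pep_A" dBSequence_ref="DB_T1" isDecoy="false"/>
    <PeptideEvidence id="PE_B" peptide_ref="Pep_B" dBSequence_ref="DB_T2" isDecoy="false"/>
    <PeptideEvidence id="PE_C" peptide_ref="Pep_C" dBSequence_ref="DB_T1" isDecoy="false"/>
    <PeptideEvidence id="PE_D" peptide_ref="Pep_A" dBSequence_ref="DB_D1" isDecoy="true"/>
  </SequenceCollection>
  <DataCollection>
    <AnalysisData>
      <SpectrumIdentificationList id="SIL_1">
"""

MZID_FOOTER = """\
      </SpectrumIdentificationList>
    </AnalysisData>
  </DataCollection>
</MzIdentML>
"""


def _item(iid, rank, passing, pep_ref, pe_ref, score):
    return f"""\
        <SpectrumIdentificationItem id="{iid}" rank="{rank}" passThreshold="{passing}" peptide_ref="{pep_ref}">
          <PeptideEvidenceRef peptideEvidence_ref="{pe_ref}"/>
          <cvParam cvRef="PSI-MS" accession="MS:1001171" name="Mascot:score" value="{score}"/>
        </SpectrumIdentificationItem>
"""


def _result(rid, spectrum_id, items):
    return (
        f'        <SpectrumIdentificationResult id="{rid}" spectrumID="{spectrum_id}" spectraData_ref="SD_1">\n'
        + "".join(items)
        + "        </SpectrumIdentificationResult>\n"
    )


@pytest.fixture
def four_result_mzid(tmp_path):
    """4 spectra; 3 have a rank-1 passing item; one has co-ranked passing items."""
    body = (
        _result("SIR_1", "index=0", [_item("SII_1", 1, "true", "Pep_A", "PE_A", 55.0)])
        + _result(
            "SIR_2", "index=1",
            [
                _item("SII_2a", 1, "true", "Pep_B", "PE_B", 48.0),
                _item("SII_2b", 2, "true", "Pep_A", "PE_A", 30.0),
            ],
        )
        + _result("SIR_3", "index=2", [_item("SII_3", 1, "false", "Pep_C", "PE_C", 9.0)])
        + _result("SIR_4", "index=3", [_item("SII_4", 1, "true", "Pep_A", "PE_D", 41.0)])
    )
    path = tmp_path / "fixture.mzid"
    path.write_text(MZID_HEADER + body + MZID_FOOTER)
    return path


class TestParseMzid:
    def test_assigned_counts_distinct_passing_spectra(self, four_result_mzid):
        res = parse_mzid(four_result_mzid)
        # SIR_2's two passing items count once; SIR_3 fails threshold
        assert res.n_spectra_assigned == 3
        assert res.n_spectra_queried is None
        assert len(res.psms) == 5

    def test_decoy_flag_from_is_decoy_attribute(self, four_result_mzid):
        res = parse_mzid(four_result_mzid)
        by_key = {(p.spectrum_key, p.rank): p for p in res.psms}
        assert by_key[("index=3", 1)].is_decoy is True
        assert by_key[("index=0", 1)].is_decoy is False

    def test_modification_rendered_as_bracket_tag(self, four_result_mzid):
        res = parse_mzid(four_result_mzid)
        peptides = {p.peptide for p in res.psms}
        assert "M[+15.9949]PEPTIDEK" in peptides

    def test_insensitive_to_child_order(self, tmp_path, four_result_mzid):
        body = (
            _result("SIR_3", "index=2", [_item("SII_3", 1, "false", "Pep_C", "PE_C", 9.0)])
            + _result("SIR_4", "index=3", [_item("SII_4", 1, "true", "Pep_A", "PE_D", 41.0)])
            + _result(
                "SIR_2", "index=1",
                [
                    _item("SII_2b", 2, "true", "Pep_A", "PE_A", 30.0),
                    _item("SII_2a", 1, "true", "Pep_B", "PE_B", 48.0),
                ],
            )
            + _result("SIR_1", "index=0", [_item("SII_1", 1, "true", "Pep_A", "PE_A", 55.0)])
        )
        path = tmp_path / "shuffled.mzid"
        path.write_text(MZID_HEADER + body + MZID_FOOTER)
        a = parse_mzid(four_result_mzid)
        b = parse_mzid(path)
        assert b.n_spectra_assigned == a.n_spectra_assigned
        assert sorted((p.spectrum_key, p.rank, p.peptide) for p in b.psms) == sorted(
            (p.spectrum_key, p.rank, p.peptide) for p in a.psms
        )

    def test_assigned_bounded_by_results(self, four_result_mzid):
        res = parse_mzid(four_result_mzid)
        assert res.n_spectra_assigned <= 4

    def test_not_mzid_root_rejected(self, tmp_path):
        path = tmp_path / "not.mzid"
        path.write_text("<mzML xmlns='http://example.org'><run/></mzML>")
        with pytest.raises(SearchResultFormatError):
            parse_mzid(path)

    def test_missing_peptide_ref_collected_not_fatal(self, tmp_path):
        body = (
            _result("SIR_1", "index=0", [_item("SII_1", 1, "true", "Pep_A", "PE_A", 55.0)])
            + _result(
                "SIR_2", "index=1",
                ['        <SpectrumIdentificationItem id="SII_bad" rank="1" passThreshold="true"/>\n'],
            )
        )
        path = tmp_path / "bad_item.mzid"
        path.write_text(MZID_HEADER + body + MZID_FOOTER)
        res = parse_mzid(path)
        assert res.n_spectra_assigned == 1
        assert res.report.n_skipped == 1
        assert "peptide reference" in res.report.errors[0]


class TestMaxQuantSummary:
    def _write(self, tmp_path, text):
        p = tmp_path / "summary.txt"
        p.write_text(textwrap.dedent(text))
        return p

    def test_rows_and_total_exclusion(self, tmp_path):
        p = self._write(
            tmp_path,
            """\
            Raw file\tMS/MS\tMS/MS Identified\tMS/MS Identified [%]
            runA\t1000\t59\t5.90
            runB\t500\t10\t2.00
            Total\t1500\t69\t4.60
            """,
        )
        res = parse_maxquant_summary(p)
        assert [r.raw_file for r in res.runs] == ["runA", "runB"]
        assert res.runs[0].n_submitted == 1000
        assert res.runs[0].n_identified == 59
        assert res.total is not None and res.total.n_submitted == 1500

    def test_submitted_alias_accepted(self, tmp_path):
        p = self._write(
            tmp_path,
            """\
            Raw file\tMS/MS Submitted\tMS/MS identified\tMS/MS identified [%]
            runA\t200\t20\t10.00
            """,
        )
        res = parse_maxquant_summary(p)
        assert res.runs[0].n_submitted == 200

    def test_pct_mismatch_warns(self, tmp_path):
        p = self._write(
            tmp_path,
            """\
            Raw file\tMS/MS\tMS/MS Identified\tMS/MS Identified [%]
            runA\t1000\t59\t7.50
            """,
        )
        res = parse_maxquant_summary(p)
        assert any("disagrees" in w for w in res.report.warnings)

    def test_missing_submitted_column_fails(self, tmp_path):
        p = self._write(tmp_path, "Raw file\tSomething\nrunA\t1\n")
        with pytest.raises(SearchResultFormatError):
            parse_maxquant_summary(p)


class TestMaxQuantMsms:
    def _write(self, tmp_path, text):
        p = tmp_path / "msms.txt"
        p.write_text(textwrap.dedent(text))
        return p

    def test_decoy_and_contaminant_flags(self, tmp_path):
        p = self._write(
            tmp_path,
            """\
            Raw file\tScan number\tSequence\tProteins\tScore\tReverse\tPotential contaminant
            runA\t10\tGPPGPAGER\tCOL1A1_BOVIN\t80.1\t\t
            runA\t11\tLVNELTEFAK\tCON__P00761\t50.0\t\t+
            runA\t12\tQQQQQQK\tREV__COL1A1_BOVIN\t12.0\t+\t
            """,
        )
        psms, report = parse_maxquant_msms(p)
        assert [p_.is_decoy for p_ in psms] == [False, False, True]
        assert [p_.is_contaminant for p_ in psms] == [False, True, False]
        assert psms[0].spectrum_key == "runA.10"
        assert report.n_records == 3

    def test_empty_proteins_row_skipped(self, tmp_path):
        p = self._write(
            tmp_path,
            """\
            Raw file\tScan number\tSequence\tProteins\tScore
            runA\t10\tGPPGPAGER\t\t80.1
            runA\t11\tLVNELTEFAK\tALBU_HUMAN\t60.0
            """,
        )
        psms, report = parse_maxquant_msms(p)
        assert len(psms) == 1
        assert report.n_skipped == 1

    def test_missing_required_column_fails(self, tmp_path):
        p = self._write(tmp_path, "Raw file\tScan number\tScore\nrunA\t1\t5\n")
        with pytest.raises(SearchResultFormatError):
            parse_maxquant_msms(p)
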