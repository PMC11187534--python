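"""Identification-rate arithmetic, target-decoy q-values, QC tallies."""

import random

import numpy as np
import pytest

from ms2qc.accounting import (
    AccountingError,
    Baseline,
    ContaminantRules,
    InconsistentCountsError,
    RunAccounting,
    UndefinedRateError,
    compare_to_baselines,
    contaminant_partition,
    distinct_peptides,
    identification_rate,
    pct_unidentified,
    pooled_rate,
    protein_groups,
    psms_at_fdr,
    round_half_up,
    tdc_qvalues,
)

from conftest import make_psm


class TestRates:
    def test_corpus_headline_arithmetic(self):
        """0.88 M assigned of 14.97 M submitted: 5.88% identified, 94.12% dark."""
        rate = identification_rate(880_000, 14_970_000)
        assert round_half_up(rate) == 5.88
        assert round_half_up(pct_unidentified(880_000, 14_970_000)) == 94.12

    def test_bounds(self):
        assert identification_rate(0, 100) == 0.0
        assert identification_rate(100, 100) == 100.0
        assert pct_unidentified(50, 50) == 0.0
        assert pct_unidentified(0, 7) == 100.0

    def test_zero_submitted_undefined(self):
        with pytest.raises(UndefinedRateError):
            identification_rate(0, 0)

    def test_assigned_exceeding_submitted_rejected(self):
        with pytest.raises(InconsistentCountsError):
            identification_rate(101, 100)

    @pytest.mark.parametrize("n_assigned,n_submitted", [(1, 3), (7, 11), (880, 14970)])
    def test_rate_and_dark_fraction_sum_to_100(self, n_assigned, n_submitted):
        total = identification_rate(n_assigned, n_submitted) + pct_unidentified(
            n_assigned, n_submitted
        )
        assert total == pytest.approx(100.0)

    def test_rounding_is_half_up(self):
        assert round_half_up(2.005) == 2.01
        assert round_half_up(2.004) == 2.0


class TestPooledRate:
    def test_pooled_vs_mean(self):
        runs = [
            RunAccounting("a", n_submitted=100, n_assigned=10),
            RunAccounting("b", n_submitted=50, n_assigned=30),
        ]
        pooled, mean = pooled_rate(runs)
        assert round_half_up(pooled) == 26.67
        assert mean == pytest.approx(35.0)

    def test_single_run_identity(self):
        runs = [RunAccounting("a", n_submitted=1000, n_assigned=59)]
        pooled, mean = pooled_rate(runs)
        assert pooled == runs[0].rate_pct == mean

    def test_pooled_bounded_by_run_rates(self):
        rng = random.Random(5)
        for _ in range(30):
            runs = [
                RunAccounting(f"r{i}", n_submitted=(n := rng.randint(1, 500)),
                              n_assigned=rng.randint(0, n))
                for i in range(rng.randint(1, 6))
            ]
            pooled, _ = pooled_rate(runs)
            rates = [r.rate_pct for r in runs]
            assert min(rates) - 1e-9 <= pooled <= max(rates) + 1e-9

    def test_empty_undefined(self):
        with pytest.raises(UndefinedRateError):
            pooled_rate([])


# ---------------------------------------------------------------------------
# target-decoy competition against a brute-force threshold oracle
# ---------------------------------------------------------------------------


def oracle_qvalues(scores, labels, plus_one=False):
    """Enumerate every score threshold, compute D/T, then monotonize.

    Independent of the implementation: no sorting tricks, no cumulative
    arrays — literally every distinct score is tried as a cutoff.
    """
    thresholds = sorted(set(scores))
    fdr_at = {}
    for t in thresholds:
        T = sum(1 for s, d in zip(scores, labels) if s >= t and not d)
        D = sum(1 for s, d in zip(scores, labels) if s >= t and d)
        fdr_at[t] = (D + (1 if plus_one else 0)) / max(T, 1)
    return [
        min(min(fdr_at[t] for t in thresholds if t <= s), 1.0) for s in scores
    ]


class TestTdcQvalues:
    def test_worked_six_psm_example(self):
        """T10 T9 D8 T7 D6 T5: q = 0, 0, 1/3, 1/3, 1/2, 1/2 down the table."""
        psms = [
            make_psm(10, False, "s0"), make_psm(9, False, "s1"),
            make_psm(8, True, "s2"), make_psm(7, False, "s3"),
            make_psm(6, True, "s4"), make_psm(5, False, "s5"),
        ]
        table = tdc_qvalues(psms)
        assert [p.spectrum_key for p in table.psms] == [f"s{i}" for i in range(6)]
        assert table.q_values == pytest.approx([0, 0, 1 / 3, 1 / 3, 0.5, 0.5])
        assert table.q_values.tolist() == oracle_qvalues(
            [10, 9, 8, 7, 6, 5], [False, False, True, False, True, False]
        )
        assert psms_at_fdr(table, 0.25) == 2

    def test_all_targets_all_zero(self):
        psms = [make_psm(s, False, f"s{s}") for s in (3, 1, 4, 1.5)]
        table = tdc_qvalues(psms)
        assert np.all(table.q_values == 0.0)
        assert psms_at_fdr(table, 0.01) == 4

    @pytest.mark.parametrize("seed", range(200))
    def test_matches_bruteforce_oracle(self, seed):
        """Random instances of ≤ 12 PSMs, integer scores to force ties."""
        rng = random.Random(seed)
        n = rng.randint(1, 12)
        scores = [float(rng.randint(0, 6)) for _ in range(n)]
        labels = [rng.random() < 0.4 for _ in range(n)]
        plus_one = rng.random() < 0.3
        psms = [
            make_psm(s, d, f"s{i}") for i, (s, d) in enumerate(zip(scores, labels))
        ]
        table = tdc_qvalues(psms, plus_one=plus_one)
        expected = dict(
            zip((f"s{i}" for i in range(n)), oracle_qvalues(scores, labels, plus_one))
        )
        for p, q in zip(table.psms, table.q_values):
            assert q == pytest.approx(expected[p.spectrum_key]), (
                f"seed {seed}: q mismatch at {p.spectrum_key}"
            )

    def test_qvalues_monotone_down_the_table(self):
        rng = random.Random(11)
        for _ in range(20):
            psms = [
                make_psm(rng.randint(0, 8), rng.random() < 0.5, f"s{i}")
                for i in range(rng.randint(2, 15))
            ]
            q = tdc_qvalues(psms).q_values
            assert np.all(np.diff(q) >= -1e-12)

    def test_ties_share_qvalues(self):
        psms = [
            make_psm(5, False, "a"), make_psm(5, True, "b"), make_psm(5, False, "c")
        ]
        q = tdc_qvalues(psms).q_values
        assert len(set(q.tolist())) == 1

    def test_non_rank1_rejected(self):
        with pytest.raises(AccountingError):
            tdc_qvalues([make_psm(5, False, "a", rank=2)])

    def test_alpha_outside_unit_interval_rejected(self):
        table = tdc_qvalues([make_psm(5, False, "a")])
        with pytest.raises(AccountingError):
            psms_at_fdr(table, 1.5)


class TestPeptidesAndGroups:
    def test_distinct_peptides_mod_stripping(self):
        psms = [
            make_psm(1, key="a", peptide="PEPT[+15.99]IDE"),
            make_psm(1, key="b", peptide="PEPTIDE"),
        ]
        assert distinct_peptides(psms, strip_mods=True) == 1
        assert distinct_peptides(psms, strip_mods=False) == 2

    def test_distinct_peptides_excludes_decoys_and_failing(self):
        psms = [
            make_psm(1, key="a", peptide="AAAAAAK"),
            make_psm(1, key="b", peptide="CCCCCCK", is_decoy=True),
            make_psm(1, key="c", peptide="DDDDDDK", pass_threshold=False),
        ]
        assert distinct_peptides(psms) == 1

    def test_identical_evidence_merges(self):
        psms = [
            make_psm(1, key="a", peptide="PEPONE", accessions=("A", "B")),
            make_psm(1, key="b", peptide="PEPTWO", accessions=("A", "B")),
        ]
        assert protein_groups(psms) == 1

    def test_subset_group_subsumed(self):
        psms = [
            make_psm(1, key="a", peptide="PEPONE", accessions=("A",)),
            make_psm(1, key="b", peptide="PEPTWO", accessions=("A",)),
            make_psm(1, key="c", peptide="PEPONE", accessions=("B",)),
        ]
        assert protein_groups(psms) == 1

    def test_overlapping_but_not_nested(self):
        psms = [
            make_psm(1, key="a", peptide="PEPONE", accessions=("A",)),
            make_psm(1, key="b", peptide="PEPTWO", accessions=("A", "B")),
            make_psm(1, key="c", peptide="PEPTRI", accessions=("B",)),
        ]
        assert protein_groups(psms) == 2

    def test_permutation_invariance(self):
        rng = random.Random(17)
        base = [
            make_psm(1, key=f"s{i}", peptide=p, accessions=tuple(a))
            for i, (p, a) in enumerate(
                [
                    ("PEPAAA", ["A"]), ("PEPBBB", ["A", "B"]), ("PEPCCC", ["B", "C"]),
                    ("PEPDDD", ["C"]), ("PEPAAA", ["D"]), ("PEPEEE", ["D", "A"]),
                ]
            )
        ]
        expected = protein_groups(base)
        for _ in range(10):
            shuffled = base[:]
            rng.shuffle(shuffled)
            shuffled = [
                make_psm(
                    1, key=p.spectrum_key, peptide=p.peptide,
                    accessions=tuple(sorted(p.accessions, key=lambda _: rng.random())),
                )
                for p in shuffled
            ]
            assert protein_groups(shuffled) == expected


class TestContaminantPartition:
    def test_pure_contaminant_counts(self):
        psms = [make_psm(1, key="a", accessions=("CON__P00761",))]
        assert contaminant_partition(psms) == (1, 0)

    def test_shared_peptide_stays_non_contaminant(self):
        psms = [make_psm(1, key="a", accessions=("CON__P00761", "COL1A1_BOVIN"))]
        assert contaminant_partition(psms) == (0, 1)

    def test_explicit_accession_list_and_flag(self):
        rules = ContaminantRules(prefixes=(), accessions=frozenset({"TRY1_BOVIN"}))
        psms = [
            make_psm(1, key="a", accessions=("TRY1_BOVIN",)),
            make_psm(1, key="b", accessions=("ALBU_HUMAN",), is_contaminant=True),
            make_psm(1, key="c", accessions=("ALBU_HUMAN",)),
        ]
        assert contaminant_partition(psms, rules) == (2, 1)

    def test_partition_over_assigned_spectra_only(self):
        psms = [
            make_psm(1, key="a", accessions=("CON__X",), is_decoy=True),
            make_psm(1, key="b", accessions=("CON__X",), pass_threshold=False),
        ]
        assert contaminant_partition(psms) == (0, 0)


class TestBaselines:
    def test_below_both_repository_baselines(self):
        baselines = [Baseline("PRIDE", 25.78), Baseline("MassIVE", 26.28)]
        comps = compare_to_baselines(5.88, baselines)
        assert comps[0].below and comps[1].below
        assert round_half_up(comps[0].delta_pct) == -19.90

    def test_equal_rate_is_not_below(self):
        (comp,) = compare_to_baselines(25.78, [Baseline("PRIDE", 25.78)])
        assert comp.below is False and comp.delta_pct == pytest.approx(0.0)

    def test_top_of_range_still_below_massive(self):
        (comp,) = compare_to_baselines(12.61, [Baseline("MassIVE", 26.28)])
        assert comp.below is True

    def test_baseline_outside_range_rejected(self):
        with pytest.raises(AccountingError):
            Baseline("bad", 101.0)
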