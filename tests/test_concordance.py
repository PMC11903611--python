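"""Pairing, contingency tabulation, concordance accounting, chi-square."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hpaconcord import concordance
from hpaconcord.categories import ExpressionCategory
from hpaconcord.concordance import (
    ContingencyMatrix,
    build_contingency,
    chi_square_independence,
    classify_pair,
    emit_pair_table,
    pair_records,
    read_pair_table,
    summarize_concordance,
)
from hpaconcord.errors import TableValidationError
from hpaconcord.formatting import percentage


def _transcripts(genes, categories=None, ntpm=None):
    n = len(genes)
    return pd.DataFrame(
        {
            "gene_id": genes,
            "gene_name": [g.lower() for g in genes],
            "tissue": "kidney",
            "ntpm": ntpm if ntpm is not None else [5.0] * n,
            "rna_category": categories if categories is not None else [2] * n,
        }
    )


def _proteins(genes, levels=None):
    n = len(genes)
    return pd.DataFrame(
        {
            "gene_id": genes,
            "gene_name": [g.lower() for g in genes],
            "tissue": "kidney",
            "cell_type": "cells in glomeruli",
            "level": levels if levels is not None else ["Medium"] * n,
            "reliability": "Approved",
        }
    )


def _pairs_frame(rna_codes, protein_codes, compartment="glomeruli", ntpm=None):
    n = len(rna_codes)
    return pd.DataFrame(
        {
            "gene_id": [f"ENSG{i}" for i in range(n)],
            "gene_name": [f"g{i}" for i in range(n)],
            "compartment": compartment,
            "ntpm": ntpm if ntpm is not None else [5.0] * n,
            "rna_category": rna_codes,
            "protein_category": protein_codes,
            "discordance_class": [
                classify_pair(r, p) for r, p in zip(rna_codes, protein_codes)
            ],
        }
    )


class TestPairRecords:
    def test_inner_join_reports_unmatched_both_sides(self):
        pairs, diags = pair_records(
            _transcripts(["A", "B", "C"]),
            {"glomeruli": _proteins(["B", "C", "D"])},
        )
        assert sorted(pairs["glomeruli"]["gene_id"]) == ["B", "C"]
        (diag,) = diags
        assert (diag.n_transcript_only, diag.n_protein_only) == (1, 1)

    def test_gene_in_both_compartments_pairs_twice(self):
        pairs, _ = pair_records(
            _transcripts(["A"]),
            {"glomeruli": _proteins(["A"]), "tubules": _proteins(["A"])},
        )
        assert len(pairs["glomeruli"]) == len(pairs["tubules"]) == 1

    def test_known_overlap_from_generator_truth(self):
        from hpaconcord.synthetic_data import GeneratorConfig, generate

        cfg = GeneratorConfig(
            n_genes=1000, overlap_frac=0.812, seed=11,
            reliability_probs=(0.2, 0.3, 0.5, 0.0),  # no excludable records
        )
        ds = generate(cfg)
        from hpaconcord import run_from_frames

        res = run_from_frames(ds.rna_typed, ds.ihc_typed)
        assert all(len(p) == 812 for p in res.pairs.values())

    def test_uncategorized_transcripts_rejected(self):
        with pytest.raises(TableValidationError, match="categorized"):
            pair_records(
                _transcripts(["A"]).drop(columns="rna_category"),
                {"glomeruli": _proteins(["A"])},
            )

    def test_strict_empty_join_errors(self):
        with pytest.raises(TableValidationError, match="empty"):
            pair_records(
                _transcripts(["A"]), {"glomeruli": _proteins(["B"])}, strict=True
            )


class TestClassifyPair:
    @pytest.mark.parametrize("rna, protein", list(itertools.product(range(4), range(4))))
    def test_exhaustive_classification(self, rna, protein):
        got = classify_pair(rna, protein)
        if rna == protein:
            assert got == "concordant"
        elif protein == 0 and rna > 0:
            assert got == "protein_null_rna_detected"
        elif rna == 0 and protein > 0:
            assert got == "rna_null_protein_detected"
        else:
            assert got == "discordant_other"

    def test_named_extreme_examples(self):
        high, nd = ExpressionCategory.HIGH, ExpressionCategory.NOT_DETECTED
        assert classify_pair(high, nd) == "protein_null_rna_detected"
        assert classify_pair(nd, high) == "rna_null_protein_detected"
        assert classify_pair(ExpressionCategory.MEDIUM, ExpressionCategory.MEDIUM) == "concordant"


class TestBuildContingency:
    def test_single_cell(self):
        m = build_contingency(_pairs_frame([3] * 4, [3] * 4))
        assert m.counts[3, 3] == 4 and m.total == 4

    def test_all_cells_once(self):
        codes = list(itertools.product(range(4), range(4)))
        m = build_contingency(
            _pairs_frame([r for r, _ in codes], [p for _, p in codes])
        )
        assert (m.counts == 1).all()

    def test_matches_bruteforce_double_loop(self):
        rng = np.random.default_rng(5)
        rna = rng.integers(0, 4, 500)
        prot = rng.integers(0, 4, 500)
        m = build_contingency(_pairs_frame(rna, prot))
        brute = np.zeros((4, 4), dtype=int)
        for r, p in zip(rna, prot):
            brute[r, p] += 1
        assert (m.counts == brute).all()

    def test_empty_input_rejected(self):
        with pytest.raises(TableValidationError):
            build_contingency(_pairs_frame([], []))


class TestSummarizeConcordance:
    def test_identity_matrix_fully_concordant(self):
        m = ContingencyMatrix(np.diag([3, 3, 3, 3]), "glomeruli")
        s = summarize_concordance(m)
        assert (s.concordant, s.discordant) == (12, 0)
        assert s.pct(s.concordant) == 100.0

    def test_published_glomerular_percentage(self):
        assert percentage(2682, 11157) == 24.04

    def test_all_ones_matrix_hand_count(self):
        s = summarize_concordance(ContingencyMatrix(np.ones((4, 4)), "x"))
        assert s.total == 16 and s.concordant == 4 and s.discordant == 12
        assert s.protein_null_rna_detected == 3
        assert s.rna_null_protein_detected == 3

    def test_conservation_over_random_matrices(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            m = ContingencyMatrix(rng.integers(0, 30, (4, 4)), "x")
            if m.total == 0:
                continue
            s = summarize_concordance(m)
            assert s.concordant + s.discordant == s.total == m.total
            assert s.concordant == int(np.trace(m.counts))


class TestChiSquare:
    def test_exact_independence_gives_zero_statistic(self):
        m = ContingencyMatrix(np.outer([1, 2, 3, 4], [1, 2, 3, 4]), "x")
        res = chi_square_independence(m)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_2x2_closed_formula(self):
        counts = np.zeros((4, 4))
        counts[1, 1], counts[1, 2], counts[2, 1], counts[2, 2] = 10, 20, 20, 10
        res = chi_square_independence(ContingencyMatrix(counts, "x"))
        n, a, b, c, d = 60, 10, 20, 20, 10
        closed = n * (a * d - b * c) ** 2 / (30 * 30 * 30 * 30)
        assert res.statistic == pytest.approx(closed, rel=1e-12)
        assert res.degrees_of_freedom == 1

    def test_matches_scipy_on_random_tables(self):
        rng = np.random.default_rng(2)
        checked = 0
        while checked < 50:
            table = rng.integers(0, 40, (4, 4))
            if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
                continue
            res = chi_square_independence(ContingencyMatrix(table, "x"))
            ref = stats.chi2_contingency(table, correction=False)
            assert res.statistic == pytest.approx(ref.statistic, rel=1e-10)
            assert res.p_value == pytest.approx(ref.pvalue, rel=1e-8)
            assert res.degrees_of_freedom == 9
            checked += 1

    def test_transpose_symmetry(self):
        rng = np.random.default_rng(4)
        table = rng.integers(1, 40, (4, 4))
        a = chi_square_independence(ContingencyMatrix(table, "x"))
        b = chi_square_independence(ContingencyMatrix(table.T, "x"))
        assert a.statistic == pytest.approx(b.statistic, rel=1e-12)

    def test_degenerate_table_rejected(self):
        counts = np.zeros((4, 4))
        counts[2] = [5, 6, 7, 8]  # single nonzero row
        with pytest.raises(TableValidationError, match="single row"):
            chi_square_independence(ContingencyMatrix(counts, "x"))

    def test_low_expected_counts_flagged(self):
        counts = np.zeros((4, 4))
        counts[:2, :2] = [[2, 1], [1, 2]]
        res = chi_square_independence(ContingencyMatrix(counts, "x"))
        assert res.validity_warning


class TestPairTable:
    def test_roundtrip_preserves_classifications(self, tmp_path):
        rng = np.random.default_rng(0)
        pairs = _pairs_frame(rng.integers(0, 4, 50), rng.integers(0, 4, 50))
        path = tmp_path / "pairs.tsv"
        emit_pair_table(pairs, path)
        again = read_pair_table(path)
        assert len(again) == 50
        pd.testing.assert_frame_equal(
            again.sort_values("gene_id").reset_index(drop=True),
            pairs.sort_values("gene_id").reset_index(drop=True),
            check_dtype=False,
        )

    def test_class_frequencies_match_summary(self, tmp_path):
        rng = np.random.default_rng(1)
        pairs = _pairs_frame(rng.integers(0, 4, 1000), rng.integers(0, 4, 1000))
        emit_pair_table(pairs, tmp_path / "p.tsv")
        again = read_pair_table(tmp_path / "p.tsv")
        s = summarize_concordance(build_contingency(again))
        freq = again["discordance_class"].value_counts()
        assert freq.get("concordant", 0) == s.concordant
        assert freq.get("protein_null_rna_detected", 0) == s.protein_null_rna_detected
        assert freq.get("rna_null_protein_detected", 0) == s.rna_null_protein_detected
        assert freq.sum() == s.total
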