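"""Cross-platform validation joins and the assembled summary."""

import numpy as np
import pandas as pd
import pytest

from hpaconcord.concordance import CompartmentConcordance, classify_pair
from hpaconcord.crossval import (
    ConcordanceSummary,
    ValidationResult,
    ValidationThresholds,
    assemble_summary,
    validate_protein_nulls,
    validate_rna_nulls,
)
from hpaconcord.errors import InternalConsistencyError, TableValidationError
from hpaconcord.formatting import format_count

from conftest import make_compartment_summary


def _pairs(records, compartment="glomeruli"):
    """records: (gene_name, ntpm, rna_cat, protein_cat)"""
    rows = []
    for i, (name, ntpm, r, p) in enumerate(records):
        rows.append(
            {
                "gene_id": f"ENSG{i}",
                "gene_name": name,
                "compartment": compartment,
                "ntpm": ntpm,
                "rna_category": r,
                "protein_category": p,
                "discordance_class": classify_pair(r, p),
            }
        )
    return pd.DataFrame(rows)


def _ms(rows, compartment="glomeruli"):
    return pd.DataFrame(
        rows, columns=["gene_name", "mean_spectral_count"]
    ).assign(compartment=compartment)


def _ext(rows, compartment="glomeruli"):
    return pd.DataFrame(rows, columns=["gene_name", "tpm"]).assign(
        compartment=compartment
    )


class TestThresholds:
    def test_negative_rejected(self):
        with pytest.raises(TableValidationError):
            ValidationThresholds(spectral_min=-1)

    def test_strict_below_detect_rejected(self):
        with pytest.raises(TableValidationError):
            ValidationThresholds(ntpm_detect=2.0, ntpm_strict=1.0)


class TestValidateProteinNulls:
    def test_robust_ms_signal_counted(self):
        pairs = _pairs([("COL6A1", 24.6, 3, 0)])
        res = validate_protein_nulls(pairs, _ms([("COL6A1", 82.0)]))
        assert res.counts == {"n_detect": 1, "n_strict": 1, "n_ms": 1}
        assert res.validated_genes.loc[0, "mean_spectral_count"] == 82.0

    def test_subthreshold_spectral_count_not_counted(self):
        res = validate_protein_nulls(
            _pairs([("A", 5.0, 2, 0)]), _ms([("A", 0.4)])
        )
        assert res.counts["n_ms"] == 0

    def test_absent_gene_reported_unmatched(self):
        res = validate_protein_nulls(
            _pairs([("A", 5.0, 2, 0), ("B", 5.0, 2, 0)]), _ms([("A", 3.0)])
        )
        assert res.counts["n_ms"] == 1 and res.n_unmatched == 1

    def test_planted_validation_fraction(self):
        # 40 protein-null pairs; exactly 25 get spectral count >= 1
        records = [(f"G{i}", 2.0, 2, 0) for i in range(40)]
        ms_rows = [(f"G{i}", 5.0) for i in range(25)] + [
            (f"G{i}", 0.2) for i in range(25, 40)
        ]
        res = validate_protein_nulls(_pairs(records), _ms(ms_rows))
        assert res.counts == {"n_detect": 40, "n_strict": 40, "n_ms": 25}

    def test_tubules_map_to_tubulointerstitium(self):
        pairs = _pairs([("HSP90AA1", 436.6, 3, 0)], compartment="tubules")
        ms = _ms([("HSP90AA1", 97.0)], compartment="tubulointerstitium")
        assert validate_protein_nulls(pairs, ms).counts["n_ms"] == 1

    def test_missing_ms_data_reported_as_missing_not_zero(self, caplog):
        with caplog.at_level("WARNING"):
            res = validate_protein_nulls(_pairs([("A", 5.0, 2, 0)]), None)
        assert res.counts["n_ms"] is None
        assert "missing" in caplog.text

    def test_raising_threshold_never_increases_count(self):
        rng = np.random.default_rng(6)
        records = [(f"G{i}", 2.0, 2, 0) for i in range(50)]
        ms_rows = [(f"G{i}", float(v)) for i, v in enumerate(rng.gamma(2, 2, 50))]
        previous = None
        for spectral_min in [0.0, 0.5, 1.0, 2.0, 8.0]:
            res = validate_protein_nulls(
                _pairs(records), _ms(ms_rows),
                ValidationThresholds(spectral_min=spectral_min),
            )
            if previous is not None:
                assert res.counts["n_ms"] <= previous
            previous = res.counts["n_ms"]

    def test_join_invariant_under_row_shuffle(self):
        rng = np.random.default_rng(8)
        records = [(f"G{i}", 2.0, 2, 0) for i in range(30)]
        ms_rows = [(f"G{i}", float(v)) for i, v in enumerate(rng.gamma(1, 3, 30))]
        base = validate_protein_nulls(_pairs(records), _ms(ms_rows))
        shuffled = _ms(ms_rows).sample(frac=1, random_state=1).reset_index(drop=True)
        assert validate_protein_nulls(_pairs(records), shuffled).counts == base.counts


class TestValidateRnaNulls:
    def test_detect_but_not_strict(self):
        res = validate_rna_nulls(_pairs([("A", 0.0, 0, 2)]), _ext([("A", 0.3)]))
        assert res.counts == {"n_total": 1, "n_tpm_detect": 1, "n_tpm_strict": 0}

    def test_absent_gene_counts_total_only(self):
        res = validate_rna_nulls(_pairs([("A", 0.0, 0, 2)]), _ext([("B", 5.0)]))
        assert res.counts == {"n_total": 1, "n_tpm_detect": 0, "n_tpm_strict": 0}
        assert res.n_unmatched == 1

    def test_planted_strict_fraction(self):
        # 30 rna-null pairs, exactly 7 with external TPM >= 1
        records = [(f"G{i}", 0.0, 0, 1) for i in range(30)]
        ext_rows = [(f"G{i}", 2.5) for i in range(7)] + [
            (f"G{i}", 0.4) for i in range(7, 30)
        ]
        res = validate_rna_nulls(_pairs(records), _ext(ext_rows))
        assert res.counts == {"n_total": 30, "n_tpm_detect": 30, "n_tpm_strict": 7}

    def test_missing_external_data(self):
        res = validate_rna_nulls(_pairs([("A", 0.0, 0, 2)]), None)
        assert res.counts["n_tpm_detect"] is None
        assert res.counts["n_tpm_strict"] is None


class TestAssembleSummary:
    @staticmethod
    def _components(total=11157, concordant=2682, pn=4953, pn_strict=3773,
                    pn_ms=637, rn=76, rn_tpm=62, rn_strict=5, name="glomeruli"):
        concord = CompartmentConcordance(
            compartment=name, total=total, concordant=concordant,
            discordant=total - concordant,
            protein_null_rna_detected=pn, rna_null_protein_detected=rn,
        )
        pv = ValidationResult(
            name, {"n_detect": pn, "n_strict": pn_strict, "n_ms": pn_ms}
        )
        rv = ValidationResult(
            name, {"n_total": rn, "n_tpm_detect": rn_tpm, "n_tpm_strict": rn_strict}
        )
        return {name: concord}, {name: pv}, {name: rv}

    def test_published_validation_row_rendering(self):
        summary = assemble_summary(*self._components())
        assert "637 (5.71%)" in summary.to_tsv()
        assert "62 (0.56%)" in summary.to_tsv()

    def test_zero_validated_renders_zero_percent(self):
        assert format_count(0, 10108) == "0 (0.00%)"

    def test_none_renders_missing(self):
        summary = ConcordanceSummary(
            compartments={"tubules": make_compartment_summary(
                compartment="tubules", protein_null_ms=None
            )}
        )
        frame = summary.to_frame()
        assert (frame["tubules"] == "missing").sum() == 1

    def test_nesting_violation_fails_loudly(self):
        concord, pv, rv = self._components()
        pv["glomeruli"].counts["n_ms"] = 5000  # > protein_null count
        with pytest.raises(InternalConsistencyError, match="nesting"):
            assemble_summary(concord, pv, rv)

    def test_mismatched_pair_sets_rejected(self):
        concord, pv, rv = self._components()
        pv["glomeruli"].counts["n_detect"] = 6000  # more than classified nulls
        with pytest.raises(InternalConsistencyError, match="different pair set"):
            assemble_summary(concord, pv, rv)
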