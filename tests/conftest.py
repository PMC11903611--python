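import pandas as pd
import pytest

from hpaconcord.crossval import CompartmentSummary


def write_tsv(path, rows, columns):
    pd.DataFrame(rows, columns=columns).to_csv(path, sep="\t", index=False)
    return path


PROTEIN_DIALECT = ["Gene", "Gene name", "Tissue", "Cell type", "Level", "Reliability"]
RNA_DIALECT = ["Gene", "Gene name", "Tissue", "nTPM"]


@pytest.fixture
def protein_tsv(tmp_path):
    def _make(rows, name="ihc.tsv"):
        return write_tsv(tmp_path / name, rows, PROTEIN_DIALECT)

    return _make


@pytest.fixture
def rna_tsv(tmp_path):
    def _make(rows, name="rna.tsv"):
        return write_tsv(tmp_path / name, rows, RNA_DIALECT)

    return _make


def make_compartment_summary(
    compartment="glomeruli",
    total=10,
    concordant=4,
    protein_null=3,
    protein_null_strict=2,
    protein_null_ms=1,
    rna_null=2,
    rna_null_tpm=1,
    rna_null_tpm_strict=0,
    **kwargs,
):
    return CompartmentSummary(
        compartment=compartment,
        total=total,
        concordant=concordant,
        discordant=total - concordant,
        protein_null_rna_detected=protein_null,
        protein_null_ntpm_strict=protein_null_strict,
        protein_null_ms_validated=protein_null_ms,
        rna_null_protein_detected=rna_null,
        rna_null_tpm_detected=rna_null_tpm,
        rna_null_tpm_strict=rna_null_tpm_strict,
        **kwargs,
    )
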