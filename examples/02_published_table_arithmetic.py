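"""Desk-scale arithmetic on a published count summary.

Feeds per-compartment counts (as printed in an HPA kidney concordance
count table) through the summary assembler and percentage formatter,
then shows the internal-consistency checker catching a row whose
printed percentage does not follow from its own count and total.
"""

from hpaconcord.concordance import CompartmentConcordance
from hpaconcord.crossval import ValidationResult, assemble_summary
from hpaconcord.errors import InternalConsistencyError
from hpaconcord.formatting import check_printed_percentage

concord = {
    "glomeruli": CompartmentConcordance(
        compartment="glomeruli", total=11157, concordant=2682, discordant=8475,
        protein_null_rna_detected=4953, rna_null_protein_detected=76,
    ),
    "tubules": CompartmentConcordance(
        compartment="tubules", total=10108, concordant=3808, discordant=6300,
        protein_null_rna_detected=2122, rna_null_protein_detected=141,
    ),
}
protein_val = {
    "glomeruli": ValidationResult(
        "glomeruli", {"n_detect": 4953, "n_strict": 3773, "n_ms": 637}
    ),
    "tubules": ValidationResult(
        "tubules", {"n_detect": 2122, "n_strict": 1172, "n_ms": 171}
    ),
}
rna_val = {
    "glomeruli": ValidationResult(
        "glomeruli", {"n_total": 76, "n_tpm_detect": 62, "n_tpm_strict": 5}
    ),
    "tubules": ValidationResult(
        "tubules", {"n_total": 141, "n_tpm_detect": 120, "n_tpm_strict": 3}
    ),
}

summary = assemble_summary(concord, protein_val, rna_val)
print(summary.to_frame().to_string())
print()

# A published glomerular row prints "3773 (33.46%)", but 3773/11157 is
# 33.82% under the formatter's rounding rule — the checker refuses it:
try:
    check_printed_percentage(3773, 11157, 33.46, label="protein-null nTPM>=1")
except InternalConsistencyError as exc:
    print(f"consistency checker: {exc}")
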