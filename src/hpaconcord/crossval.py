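"""Cross-platform validation of the extreme-discordant pairs, and the
assembled count summary.

Pairs where IHC sees no protein despite detected mRNA are re-examined
against compartment-resolved mass-spectrometry spectral counts (a
platform with a far wider dynamic range than chromogenic IHC); pairs
where the bulk transcriptome sees no mRNA despite an IHC signal are
re-examined against an external compartment-resolved RNA-seq dataset.
The assembled :class:`ConcordanceSummary` is the machine form of the
published per-compartment count table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .concordance import ChiSquareResult, CompartmentConcordance
from .errors import InternalConsistencyError, TableValidationError
from .formatting import format_count, percentage

logger = logging.getLogger(__name__)

__all__ = [
    "ValidationThresholds",
    "ValidationResult",
    "MS_COMPARTMENT_MAP",
    "validate_protein_nulls",
    "validate_rna_nulls",
    "CompartmentSummary",
    "ConcordanceSummary",
    "assemble_summary",
]

#: Pipeline compartment -> compartment label in the MS (KPMP-style) table.
MS_COMPARTMENT_MAP = {"glomeruli": "glomeruli", "tubules": "tubulointerstitium"}

#: Pipeline compartment -> compartment label in the external RNA table.
EXT_COMPARTMENT_MAP = {"glomeruli": "glomeruli", "tubules": "tubules"}


@dataclass(frozen=True)
class ValidationThresholds:
    """Detection thresholds for the cross-platform validation joins.

    ``*_detect`` bounds are exclusive (value > threshold counts as
    detected), ``*_strict`` and ``spectral_min`` inclusive (value >=
    threshold), matching how the published table states them.
    """

    ntpm_detect: float = 0.0
    ntpm_strict: float = 1.0
    spectral_min: float = 1.0
    tpm_detect: float = 0.0
    tpm_strict: float = 1.0

    def __post_init__(self) -> None:
        for name, value in asdict(self).items():
            if value < 0:
                raise TableValidationError(f"threshold {name} must be >= 0: {value}")
        if self.ntpm_strict < self.ntpm_detect or self.tpm_strict < self.tpm_detect:
            raise TableValidationError("strict thresholds must be >= detect thresholds")


@dataclass
class ValidationResult:
    """Counts from one validation join, plus per-gene detail.

    ``counts`` values may be ``None`` when the validation table carried
    no data for the compartment (reported as *missing*, which is
    distinct from a genuine zero). ``n_unmatched`` counts genes absent
    from the validation table — these are never validated but are kept
    separate from genes present-but-below-threshold.
    """

    compartment: str
    counts: dict[str, int | None]
    n_unmatched: int = 0
    validated_genes: pd.DataFrame = field(default_factory=pd.DataFrame, repr=False)


def _lower_name(s: pd.Series) -> pd.Series:
    return s.astype(str).str.strip().str.casefold()


def validate_protein_nulls(
    pairs: pd.DataFrame,
    ms: pd.DataFrame | None,
    thresholds: ValidationThresholds = ValidationThresholds(),
    *,
    compartment_map: dict[str, str] | None = None,
) -> ValidationResult:
    """Re-examine IHC-undetected pairs against MS spectral counts.

    ``n_detect`` counts pairs classified ``protein_null_rna_detected``
    with ``ntpm > ntpm_detect``; ``n_strict`` is its ``ntpm >=
    ntpm_strict`` subset; ``n_ms`` is the subset of ``n_detect`` whose
    gene reaches ``mean_spectral_count >= spectral_min`` in the MS
    compartment matched to the pairs' compartment (tubular IHC pairs
    match the MS "tubulointerstitium"). With no MS data for the
    compartment, ``n_ms`` is reported as missing (``None``), not 0.
    """
    compartment_map = compartment_map or MS_COMPARTMENT_MAP
    compartment = str(pairs["compartment"].iloc[0]) if len(pairs) else ""
    nulls = pairs[pairs["discordance_class"] == "protein_null_rna_detected"]
    detect = nulls[nulls["ntpm"] > thresholds.ntpm_detect]
    counts: dict[str, int | None] = {
        "n_detect": len(detect),
        "n_strict": int((detect["ntpm"] >= thresholds.ntpm_strict).sum()),
    }
    ms_compartment = compartment_map.get(compartment, compartment)
    ms_here = (
        ms[_lower_name(ms["compartment"]) == ms_compartment]
        if ms is not None and len(ms)
        else None
    )
    if ms_here is None or len(ms_here) == 0:
        logger.warning(
            "validate_protein_nulls[%s]: no MS data for compartment %r; "
            "MS-validated count reported as missing",
            compartment, ms_compartment,
        )
        counts["n_ms"] = None
        return ValidationResult(compartment=compartment, counts=counts)

    ms_counts = ms_here.set_index(_lower_name(ms_here["gene_name"]))[
        "mean_spectral_count"
    ]
    joined = detect.assign(
        mean_spectral_count=_lower_name(detect["gene_name"]).map(ms_counts)
    )
    unmatched = joined["mean_spectral_count"].isna()
    validated = joined[joined["mean_spectral_count"] >= thresholds.spectral_min]
    counts["n_ms"] = len(validated)
    return ValidationResult(
        compartment=compartment,
        counts=counts,
        n_unmatched=int(unmatched.sum()),
        validated_genes=validated[
            ["gene_id", "gene_name", "compartment", "ntpm", "mean_spectral_count"]
        ].reset_index(drop=True),
    )


def validate_rna_nulls(
    pairs: pd.DataFrame,
    ext: pd.DataFrame | None,
    thresholds: ValidationThresholds = ValidationThresholds(),
    *,
    compartment_map: dict[str, str] | None = None,
) -> ValidationResult:
    """Re-examine mRNA-undetected pairs against external RNA-seq TPM.

    ``n_total`` counts pairs classified ``rna_null_protein_detected``;
    ``n_tpm_detect``/``n_tpm_strict`` are the subsets whose gene shows
    external ``TPM > tpm_detect`` / ``TPM >= tpm_strict`` in the
    matching compartment. Genes absent from the external table count
    only toward ``n_total`` (and the unmatched diagnostic).
    """
    compartment_map = compartment_map or EXT_COMPARTMENT_MAP
    compartment = str(pairs["compartment"].iloc[0]) if len(pairs) else ""
    nulls = pairs[pairs["discordance_class"] == "rna_null_protein_detected"]
    counts: dict[str, int | None] = {"n_total": len(nulls)}
    ext_compartment = compartment_map.get(compartment, compartment)
    ext_here = (
        ext[_lower_name(ext["compartment"]) == ext_compartment]
        if ext is not None and len(ext)
        else None
    )
    if ext_here is None or len(ext_here) == 0:
        logger.warning(
            "validate_rna_nulls[%s]: no external RNA data for compartment %r; "
            "TPM-validated counts reported as missing",
            compartment, ext_compartment,
        )
        counts["n_tpm_detect"] = None
        counts["n_tpm_strict"] = None
        return ValidationResult(compartment=compartment, counts=counts)

    tpm = ext_here.set_index(_lower_name(ext_here["gene_name"]))["tpm"]
    joined = nulls.assign(tpm=_lower_name(nulls["gene_name"]).map(tpm))
    unmatched = joined["tpm"].isna()
    detected = joined[joined["tpm"] > thresholds.tpm_detect]
    counts["n_tpm_detect"] = len(detected)
    counts["n_tpm_strict"] = int((detected["tpm"] >= thresholds.tpm_strict).sum())
    return ValidationResult(
        compartment=compartment,
        counts=counts,
        n_unmatched=int(unmatched.sum()),
        validated_genes=detected[
            ["gene_id", "gene_name", "compartment", "ntpm", "tpm"]
        ].reset_index(drop=True),
    )


@dataclass
class CompartmentSummary:
    """All published count rows for one compartment, plus diagnostics."""

    compartment: str
    total: int
    concordant: int
    discordant: int
    protein_null_rna_detected: int
    protein_null_ntpm_strict: int
    protein_null_ms_validated: int | None
    rna_null_protein_detected: int
    rna_null_tpm_detected: int | None
    rna_null_tpm_strict: int | None
    chi_square: dict | None = None
    unmatched: dict = field(default_factory=dict)

    def check_invariants(self) -> None:
        """Conservation and nesting; violation is an internal error."""
        if self.total <= 0:
            raise InternalConsistencyError(f"{self.compartment}: empty summary")
        if self.concordant + self.discordant != self.total:
            raise InternalConsistencyError(
                f"{self.compartment}: concordant + discordant != total"
            )
        nestings = [
            ("protein_null_ntpm_strict", self.protein_null_ntpm_strict,
             "protein_null_rna_detected", self.protein_null_rna_detected),
            ("protein_null_ms_validated", self.protein_null_ms_validated,
             "protein_null_rna_detected", self.protein_null_rna_detected),
            ("rna_null_tpm_detected", self.rna_null_tpm_detected,
             "rna_null_protein_detected", self.rna_null_protein_detected),
            ("rna_null_tpm_strict", self.rna_null_tpm_strict,
             "rna_null_tpm_detected", self.rna_null_tpm_detected),
        ]
        for inner_name, inner, outer_name, outer in nestings:
            if inner is None or outer is None:
                continue
            if inner > outer:
                raise InternalConsistencyError(
                    f"{self.compartment}: nesting violated, "
                    f"{inner_name}={inner} > {outer_name}={outer}"
                )

    def pct(self, count: int) -> float:
        return percentage(count, self.total)


def _fmt_threshold(value: float) -> str:
    return str(int(value)) if float(value).is_integer() else str(value)


@dataclass
class ConcordanceSummary:
    """Machine form of the per-compartment count-summary table."""

    compartments: dict[str, CompartmentSummary]
    thresholds: ValidationThresholds = field(default_factory=ValidationThresholds)

    def row_labels(self) -> list[tuple[str, str]]:
        """(field, printed row label) in the published table's order."""
        t = self.thresholds
        return [
            ("total", "Number of reliable paired mRNA-protein expression measurements"),
            ("concordant", "mRNA-protein pairs with concordant abundance levels"),
            ("discordant", "mRNA-protein pairs with discordant abundance levels"),
            ("protein_null_rna_detected",
             "mRNA-protein pairs with no IHC signals but with detected kidney "
             f"mRNA expression (nTPM > {_fmt_threshold(t.ntpm_detect)})"),
            ("protein_null_ntpm_strict",
             "mRNA-protein pairs with no IHC signals but with detected kidney "
             f"mRNA expression (nTPM >= {_fmt_threshold(t.ntpm_strict)})"),
            ("protein_null_ms_validated",
             "mRNA-protein pairs with no IHC signals but with detected kidney "
             f"mRNA expression (nTPM > {_fmt_threshold(t.ntpm_detect)}) and "
             "measured using compartment-specific mass-spectrometry data "
             f"(mean spectral count >= {_fmt_threshold(t.spectral_min)})"),
            ("rna_null_protein_detected",
             "mRNA-protein pairs with no detectable mRNA but with IHC signals"),
            ("rna_null_tpm_detected",
             "mRNA-protein pairs with no detectable mRNA but with IHC signals "
             "and detected by compartment-specific RNA-seq "
             f"(TPM > {_fmt_threshold(t.tpm_detect)})"),
            ("rna_null_tpm_strict",
             "mRNA-protein pairs with no detectable mRNA but with IHC signals "
             "and detected by compartment-specific RNA-seq "
             f"(TPM >= {_fmt_threshold(t.tpm_strict)})"),
        ]

    def to_frame(self) -> pd.DataFrame:
        """One row per named count, one column per compartment."""
        cols = {}
        for name, cs in self.compartments.items():
            cs.check_invariants()
            col = {}
            for fld, label in self.row_labels():
                value = getattr(cs, fld)
                if fld == "total":
                    col[label] = str(cs.total)
                elif value is None:
                    col[label] = "missing"
                else:
                    col[label] = format_count(value, cs.total)
            cols[name] = col
        return pd.DataFrame(cols)

    def to_tsv(self) -> str:
        return self.to_frame().to_csv(sep="\t", index_label="row")

    def to_dict(self) -> dict:
        out: dict = {"thresholds": asdict(self.thresholds), "compartments": {}}
        for name, cs in self.compartments.items():
            cs.check_invariants()
            entry: dict = {"compartment": cs.compartment, "total": cs.total}
            for fld, _ in self.row_labels()[1:]:
                value = getattr(cs, fld)
                entry[fld] = value
                entry[f"{fld}_pct"] = None if value is None else cs.pct(value)
            entry["chi_square"] = cs.chi_square
            entry["unmatched"] = cs.unmatched
            out["compartments"][name] = entry
        return out

    @classmethod
    def from_dict(cls, data: dict) -> "ConcordanceSummary":
        thresholds = ValidationThresholds(**data["thresholds"])
        compartments = {}
        for name, entry in data["compartments"].items():
            compartments[name] = CompartmentSummary(
                compartment=entry["compartment"],
                total=entry["total"],
                concordant=entry["concordant"],
                discordant=entry["discordant"],
                protein_null_rna_detected=entry["protein_null_rna_detected"],
                protein_null_ntpm_strict=entry["protein_null_ntpm_strict"],
                protein_null_ms_validated=entry["protein_null_ms_validated"],
                rna_null_protein_detected=entry["rna_null_protein_detected"],
                rna_null_tpm_detected=entry["rna_null_tpm_detected"],
                rna_null_tpm_strict=entry["rna_null_tpm_strict"],
                chi_square=entry.get("chi_square"),
                unmatched=entry.get("unmatched", {}),
            )
        return cls(compartments=compartments, thresholds=thresholds)


def assemble_summary(
    concord: dict[str, CompartmentConcordance],
    protein_val: dict[str, ValidationResult],
    rna_val: dict[str, ValidationResult],
    chi: dict[str, ChiSquareResult] | None = None,
    thresholds: ValidationThresholds = ValidationThresholds(),
    unmatched: dict[str, dict] | None = None,
) -> ConcordanceSummary:
    """Combine per-compartment accounting into one summary.

    All components must derive from the same pair sets; the nesting
    invariants (e.g. MS-validated <= protein-null with detected mRNA)
    are enforced and any violation raises
    :class:`InternalConsistencyError` rather than producing a silently
    inconsistent table. Percentages always use the compartment's total
    pair count as denominator.
    """
    chi = chi or {}
    unmatched = unmatched or {}
    compartments: dict[str, CompartmentSummary] = {}
    for name in sorted(concord):
        cc = concord[name]
        pv = protein_val[name]
        rv = rna_val[name]
        if pv.counts["n_detect"] > cc.protein_null_rna_detected:
            raise InternalConsistencyError(
                f"{name}: validation ran on a different pair set than the summary"
            )
        diag = dict(unmatched.get(name, {}))
        diag.setdefault("ms_unmatched_genes", pv.n_unmatched)
        diag.setdefault("ext_unmatched_genes", rv.n_unmatched)
        cs = CompartmentSummary(
            compartment=name,
            total=cc.total,
            concordant=cc.concordant,
            discordant=cc.discordant,
            protein_null_rna_detected=pv.counts["n_detect"],
            protein_null_ntpm_strict=pv.counts["n_strict"],
            protein_null_ms_validated=pv.counts["n_ms"],
            rna_null_protein_detected=rv.counts["n_total"],
            rna_null_tpm_detected=rv.counts["n_tpm_detect"],
            rna_null_tpm_strict=rv.counts["n_tpm_strict"],
            chi_square=chi[name].to_dict() if name in chi else None,
            unmatched=diag,
        )
        cs.check_invariants()
        compartments[name] = cs
    return ConcordanceSummary(compartments=compartments, thresholds=thresholds)
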