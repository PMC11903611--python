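"""Pairing, contingency tabulation, concordance accounting and the
chi-square test of independence.

A *pair* is one gene observed in one kidney compartment with both a
discretized transcript category and an IHC protein category. The 4x4
ordinal contingency matrix over pairs drives everything downstream:
the concordant fraction is its trace, the extreme-discordance counts
are the Not-detected row and column off the diagonal, and the
chi-square test asks whether the two ordinal variables are independent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .categories import ExpressionCategory, normalize_ihc_level
from .errors import TableValidationError
from .formatting import percentage

logger = logging.getLogger(__name__)

__all__ = [
    "DISCORDANCE_CLASSES",
    "ContingencyMatrix",
    "ChiSquareResult",
    "CompartmentConcordance",
    "PairingDiagnostics",
    "classify_pair",
    "pair_records",
    "build_contingency",
    "summarize_concordance",
    "chi_square_independence",
    "emit_pair_table",
    "read_pair_table",
]

DISCORDANCE_CLASSES = (
    "concordant",
    "discordant_other",
    "protein_null_rna_detected",
    "rna_null_protein_detected",
)

PAIR_COLUMNS = [
    "gene_id",
    "gene_name",
    "compartment",
    "ntpm",
    "rna_category",
    "protein_category",
    "discordance_class",
]


def classify_pair(
    rna: ExpressionCategory | int, protein: ExpressionCategory | int
) -> str:
    """Discordance class of one (mRNA category, protein category) pair.

    Equal categories are concordant. The two *extreme* discordance
    classes single out detection mismatches: protein Not detected with
    any mRNA signal, and mRNA Not detected with any IHC signal. All
    remaining combinations are ``discordant_other``.
    """
    rna, protein = int(rna), int(protein)
    nd = int(ExpressionCategory.NOT_DETECTED)
    if rna == protein:
        return "concordant"
    if protein == nd and rna > nd:
        return "protein_null_rna_detected"
    if rna == nd and protein > nd:
        return "rna_null_protein_detected"
    return "discordant_other"


@dataclass
class PairingDiagnostics:
    """Unmatched-gene accounting for one compartment join."""

    compartment: str
    n_pairs: int
    n_transcript_only: int
    n_protein_only: int


def _join_key(transcripts: pd.DataFrame, proteins: pd.DataFrame) -> str:
    """Primary join key: gene_id when both sides carry one, else gene_name."""
    for side in (transcripts, proteins):
        if "gene_id" not in side.columns or side["gene_id"].eq("").all():
            return "gene_name"
    return "gene_id"


def pair_records(
    transcripts: pd.DataFrame,
    protein_buckets: dict[str, pd.DataFrame],
    *,
    strict: bool = False,
) -> tuple[dict[str, pd.DataFrame], list[PairingDiagnostics]]:
    """Inner-join categorized transcripts with each compartment's IHC records.

    ``transcripts`` must already carry an ``rna_category`` column (see
    :func:`hpaconcord.classify.categorize_transcripts`); protein buckets
    must be reliability-filtered. Each gene contributes at most one
    pair per compartment. Genes found on only one side are never
    silently discarded: they are counted per compartment in the
    returned :class:`PairingDiagnostics`.
    """
    if "rna_category" not in transcripts.columns:
        raise TableValidationError("transcripts must be categorized before pairing")
    pairs: dict[str, pd.DataFrame] = {}
    diagnostics: list[PairingDiagnostics] = []
    for compartment in sorted(protein_buckets):
        proteins = protein_buckets[compartment]
        key = _join_key(transcripts, proteins)
        t = transcripts.drop_duplicates(key)
        p = proteins.drop_duplicates(key)
        merged = t.merge(p[[key, "level"]], on=key, how="inner")
        merged["protein_category"] = merged["level"].map(
            lambda s: int(normalize_ihc_level(s))
        )
        merged["rna_category"] = merged["rna_category"].astype(int)
        merged["compartment"] = compartment
        merged["discordance_class"] = [
            classify_pair(r, q)
            for r, q in zip(merged["rna_category"], merged["protein_category"])
        ]
        if "gene_name" not in merged.columns:
            merged["gene_name"] = merged[key]
        if "gene_id" not in merged.columns:
            merged["gene_id"] = merged[key]
        out = merged[PAIR_COLUMNS].sort_values("gene_id", kind="stable")
        diag = PairingDiagnostics(
            compartment=compartment,
            n_pairs=len(out),
            n_transcript_only=int((~t[key].isin(p[key])).sum()),
            n_protein_only=int((~p[key].isin(t[key])).sum()),
        )
        if strict and diag.n_pairs == 0:
            raise TableValidationError(
                f"empty transcript/protein join for compartment {compartment!r}"
            )
        logger.info(
            "pair_records[%s]: %d pairs, %d transcript-only, %d protein-only",
            compartment, diag.n_pairs, diag.n_transcript_only, diag.n_protein_only,
        )
        pairs[compartment] = out.reset_index(drop=True)
        diagnostics.append(diag)
    return pairs, diagnostics


@dataclass
class ContingencyMatrix:
    """4x4 pair counts indexed ``[rna_category][protein_category]``."""

    counts: np.ndarray
    compartment: str = ""

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (4, 4) or (self.counts < 0).any():
            raise TableValidationError(
                "contingency matrix must be 4x4 with non-negative counts"
            )

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        labels = [c.label for c in ExpressionCategory]
        return pd.DataFrame(self.counts, index=labels, columns=labels).rename_axis(
            index="mRNA", columns="protein"
        )


def build_contingency(pairs: pd.DataFrame, compartment: str = "") -> ContingencyMatrix:
    """Tabulate pairs into the 4x4 ordinal contingency matrix."""
    if len(pairs) == 0:
        raise TableValidationError("cannot build a contingency matrix from zero pairs")
    counts = np.zeros((4, 4), dtype=np.int64)
    np.add.at(
        counts,
        (
            pairs["rna_category"].to_numpy(dtype=int),
            pairs["protein_category"].to_numpy(dtype=int),
        ),
        1,
    )
    compartment = compartment or (
        str(pairs["compartment"].iloc[0]) if "compartment" in pairs.columns else ""
    )
    return ContingencyMatrix(counts=counts, compartment=compartment)


@dataclass
class CompartmentConcordance:
    """Concordance accounting for one compartment (one column of the
    published count-summary table, before cross-platform validation)."""

    compartment: str
    total: int
    concordant: int
    discordant: int
    protein_null_rna_detected: int
    rna_null_protein_detected: int

    def __post_init__(self) -> None:
        if self.concordant + self.discordant != self.total:
            raise TableValidationError(
                f"{self.compartment}: concordant + discordant != total "
                f"({self.concordant} + {self.discordant} != {self.total})"
            )

    def pct(self, count: int) -> float:
        return percentage(count, self.total)


def summarize_concordance(matrix: ContingencyMatrix) -> CompartmentConcordance:
    """Derive concordant/discordant and extreme-discordance counts.

    Concordant pairs are the matrix trace; ``protein_null_rna_detected``
    is the Not-detected protein column for mRNA Low..High, and
    ``rna_null_protein_detected`` the Not-detected mRNA row for protein
    Low..High.
    """
    if matrix.total == 0:
        raise TableValidationError("cannot summarize an empty contingency matrix")
    c = matrix.counts
    concordant = int(np.trace(c))
    return CompartmentConcordance(
        compartment=matrix.compartment,
        total=matrix.total,
        concordant=concordant,
        discordant=matrix.total - concordant,
        protein_null_rna_detected=int(c[1:, 0].sum()),
        rna_null_protein_detected=int(c[0, 1:].sum()),
    )


@dataclass
class ChiSquareResult:
    """Pearson chi-square test of independence on the contingency matrix."""

    statistic: float
    degrees_of_freedom: int
    p_value: float
    expected_counts: np.ndarray = field(repr=False)
    validity_warning: bool = False

    def to_dict(self) -> dict:
        return {
            "statistic": self.statistic,
            "degrees_of_freedom": self.degrees_of_freedom,
            "p_value": self.p_value,
            "validity_warning": self.validity_warning,
        }


def chi_square_independence(matrix: ContingencyMatrix) -> ChiSquareResult:
    """Pearson chi-square test on the full table, Not-detected included.

    All-zero rows and columns are dropped before computing degrees of
    freedom ``(r-1)(c-1)``; expected counts are the product of the
    margins over the grand total, and the statistic sums
    ``(obs-exp)^2/exp`` over the retained cells. ``validity_warning``
    flags any retained expected count below 5, the usual rule of thumb
    for the asymptotic approximation.
    """
    obs = matrix.counts
    if obs.sum() == 0:
        raise TableValidationError("chi-square test needs a non-empty table")
    obs = obs[obs.sum(axis=1) > 0][:, obs.sum(axis=0) > 0]
    r, c = obs.shape
    if r < 2 or c < 2:
        raise TableValidationError(
            "chi-square test undefined: table reduces to a single row or column"
        )
    total = obs.sum()
    expected = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / total
    statistic = float(((obs - expected) ** 2 / expected).sum())
    df = (r - 1) * (c - 1)
    return ChiSquareResult(
        statistic=statistic,
        degrees_of_freedom=df,
        p_value=float(stats.chi2.sf(statistic, df)),
        expected_counts=expected,
        validity_warning=bool((expected < 5).any()),
    )


def emit_pair_table(pairs: pd.DataFrame, path: str | Path) -> None:
    """Write classified pairs as TSV, one row per pair.

    Categories are written as their labels ("Not detected" .. "High");
    rows are sorted by (compartment, gene_id) so repeated runs produce
    byte-identical files suitable for stripchart plotting or diffing.
    """
    out = pairs[PAIR_COLUMNS].copy()
    for col in ("rna_category", "protein_category"):
        out[col] = out[col].map(lambda v: ExpressionCategory(int(v)).label)
    out = out.sort_values(["compartment", "gene_id"], kind="stable")
    out.to_csv(path, sep="\t", index=False)


def read_pair_table(path: str | Path) -> pd.DataFrame:
    """Inverse of :func:`emit_pair_table` (labels parsed back to codes)."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "gene_name": str})
    for col in ("rna_category", "protein_category"):
        df[col] = df[col].map(lambda s: int(normalize_ihc_level(s)))
    return df[PAIR_COLUMNS]
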