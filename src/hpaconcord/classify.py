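"""Reliability filtering, compartment selection, and ordinal discretization.

The analysis keeps only IHC observations with a trustworthy antibody
(reliability grade other than "Uncertain") and only the two kidney
compartments with dense protein coverage: "cells in glomeruli" and
"cells in tubules". Continuous transcript abundance (nTPM) is mapped
onto the shared four-level scale by the zero/tertile rule: nTPM equal
to zero is Not detected, and the positive values are split into
tertiles giving Low, Medium and High.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .categories import ExpressionCategory, normalize_ihc_level
from .errors import ConfigurationError, TableValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "KIDNEY_CELL_TYPES",
    "DEFAULT_KEEP_CELL_TYPES",
    "COMPARTMENT_LABELS",
    "TertileThresholds",
    "filter_reliability",
    "select_cell_types",
    "compute_tertiles",
    "categorize_transcript",
    "categorize_transcripts",
    "normalize_ihc_level",
]

#: Kidney cell-type annotations present in the HPA normal-tissue export.
KIDNEY_CELL_TYPES = frozenset(
    {
        "bowman's capsule",
        "cells in glomeruli",
        "cells in tubules",
        "collecting ducts",
        "distal tubules",
        "proximal tubules (cell body)",
        "proximal tubules (microvilli)",
    }
)

DEFAULT_KEEP_CELL_TYPES = frozenset({"cells in glomeruli", "cells in tubules"})

#: Canonical compartment label for each kept cell type.
COMPARTMENT_LABELS = {
    "cells in glomeruli": "glomeruli",
    "cells in tubules": "tubules",
}


def filter_reliability(proteins: pd.DataFrame) -> pd.DataFrame:
    """Drop IHC records with "Uncertain" antibody reliability.

    Cell-type buckets keep every other grade (Enhanced, Supported,
    Approved). The removed count is logged; an empty result is allowed.
    """
    keep = proteins["reliability"] != "Uncertain"
    n_removed = int((~keep).sum())
    if n_removed:
        logger.info("filter_reliability: removed %d 'Uncertain' record(s)", n_removed)
    return proteins[keep].reset_index(drop=True)


def select_cell_types(
    proteins: pd.DataFrame,
    keep: frozenset[str] | set[str] | None = None,
) -> dict[str, pd.DataFrame]:
    """Bucket IHC records by compartment, keeping only listed cell types.

    Matching is exact-string after whitespace/case canonicalization:
    "distal tubules" is NOT part of the "cells in tubules" bucket.
    Compartment keys are canonicalized via :data:`COMPARTMENT_LABELS`
    ("cells in glomeruli" -> "glomeruli", "cells in tubules" ->
    "tubules"); other kept cell types bucket under their own name.
    """
    if keep is None:
        keep = DEFAULT_KEEP_CELL_TYPES
    keep = {str(k).strip().casefold() for k in keep}
    if not keep:
        raise ConfigurationError("keep_cell_types must not be empty")
    unknown = keep - KIDNEY_CELL_TYPES
    if unknown:
        raise ConfigurationError(
            f"unknown cell type(s) in keep set: {sorted(unknown)}; "
            f"known: {sorted(KIDNEY_CELL_TYPES)}"
        )
    cell_types = proteins["cell_type"].str.strip().str.casefold()
    n_dropped = int((~cell_types.isin(keep)).sum())
    if n_dropped:
        logger.info("select_cell_types: dropped %d record(s) of other cell types", n_dropped)
    buckets: dict[str, pd.DataFrame] = {}
    for ct in sorted(keep):
        label = COMPARTMENT_LABELS.get(ct, ct)
        buckets[label] = proteins[cell_types == ct].reset_index(drop=True)
    return buckets


@dataclass(frozen=True)
class TertileThresholds:
    """Tertile boundaries of the positive nTPM distribution.

    ``t1`` separates Low from Medium, ``t2`` Medium from High;
    ``n_positive`` is the number of nonzero-nTPM genes the quantiles
    were computed from.
    """

    t1: float
    t2: float
    n_positive: int

    def __post_init__(self) -> None:
        if not (0 < self.t1 <= self.t2):
            raise TableValidationError(
                f"invalid tertile thresholds: t1={self.t1}, t2={self.t2}"
            )
        if self.n_positive < 3:
            raise TableValidationError("tertiles need at least 3 positive values")


def compute_tertiles(transcripts: pd.DataFrame | np.ndarray) -> TertileThresholds:
    """Empirical 1/3 and 2/3 quantiles of the positive nTPM values.

    Quantiles use linear interpolation between order statistics
    (probability ``p`` maps to rank ``1 + (n-1)p``), numpy's default
    convention. Accepts either a transcript frame with an ``ntpm``
    column or a bare array of abundances; zeros are excluded before
    the quantile computation.
    """
    ntpm = np.asarray(
        transcripts["ntpm"] if isinstance(transcripts, pd.DataFrame) else transcripts,
        dtype=float,
    )
    if (ntpm < 0).any():
        raise TableValidationError("negative nTPM value in transcript collection")
    positive = ntpm[ntpm > 0]
    if positive.size < 3:
        raise TableValidationError(
            f"need at least 3 positive nTPM values to form tertiles, got {positive.size}"
        )
    t1, t2 = np.quantile(positive, [1 / 3, 2 / 3], method="linear")
    return TertileThresholds(t1=float(t1), t2=float(t2), n_positive=int(positive.size))


def categorize_transcript(
    ntpm: float | np.ndarray, thresholds: TertileThresholds
) -> ExpressionCategory | np.ndarray:
    """Map nTPM onto the ordinal scale under the zero/tertile rule.

    ``ntpm == 0`` is Not detected; ``(0, t1]`` Low; ``(t1, t2]``
    Medium; ``(t2, inf)`` High — Low and Medium are upper-closed so a
    value sitting exactly on a boundary lands in the lower category.
    Vectorized: an array input returns an integer-code array.
    """
    arr = np.asarray(ntpm, dtype=float)
    if (arr < 0).any():
        raise TableValidationError(f"negative nTPM: {ntpm}")
    codes = np.select(
        [arr == 0, arr <= thresholds.t1, arr <= thresholds.t2],
        [
            int(ExpressionCategory.NOT_DETECTED),
            int(ExpressionCategory.LOW),
            int(ExpressionCategory.MEDIUM),
        ],
        default=int(ExpressionCategory.HIGH),
    )
    if np.isscalar(ntpm) or arr.ndim == 0:
        return ExpressionCategory(int(codes))
    return codes


def categorize_transcripts(
    transcripts: pd.DataFrame, thresholds: TertileThresholds | None = None
) -> tuple[pd.DataFrame, TertileThresholds]:
    """Attach an ordinal ``rna_category`` column to a transcript frame.

    When ``thresholds`` is omitted they are computed from this frame —
    on the full transcript collection, before any pairing with IHC, so
    the tertiles describe the whole kidney transcriptome.
    """
    if thresholds is None:
        thresholds = compute_tertiles(transcripts)
    out = transcripts.copy()
    out["rna_category"] = categorize_transcript(
        out["ntpm"].to_numpy(dtype=float), thresholds
    )
    return out, thresholds
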