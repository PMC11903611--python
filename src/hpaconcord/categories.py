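"""Shared ordinal expression scale and label normalization.

Both discretized bulk RNA-seq abundance and semi-quantitative
immunohistochemistry (IHC) calls live on the same four-level ordinal
scale, which is what makes a per-gene mRNA/protein comparison possible:

    NotDetected < Low < Medium < High

IHC level strings and antibody-reliability grades arrive from
HPA-dialect TSV exports whose casing varies across versions, so all
string matching here is case-folded and whitespace-normalized.
"""

from __future__ import annotations

import enum
import re

from .errors import TableValidationError

__all__ = [
    "ExpressionCategory",
    "RELIABILITY_GRADES",
    "normalize_ihc_level",
    "normalize_reliability",
]


class ExpressionCategory(enum.IntEnum):
    """Ordinal expression level; integer codes give the total order."""

    NOT_DETECTED = 0
    LOW = 1
    MEDIUM = 2
    HIGH = 3

    @property
    def label(self) -> str:
        return _CATEGORY_LABELS[self]

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.label


_CATEGORY_LABELS = {
    ExpressionCategory.NOT_DETECTED: "Not detected",
    ExpressionCategory.LOW: "Low",
    ExpressionCategory.MEDIUM: "Medium",
    ExpressionCategory.HIGH: "High",
}

#: Antibody evidence grades used by the Human Protein Atlas; "Uncertain"
#: entries are excluded from the analysis by :func:`classify.filter_reliability`.
RELIABILITY_GRADES = ("Enhanced", "Supported", "Approved", "Uncertain")

_WS = re.compile(r"\s+")


def _canon(raw: str) -> str:
    """Case-fold and collapse internal whitespace."""
    return _WS.sub(" ", str(raw).strip()).casefold()


_LEVEL_LOOKUP = {_canon(lbl): cat for cat, lbl in _CATEGORY_LABELS.items()}
_RELIABILITY_LOOKUP = {_canon(g): g for g in RELIABILITY_GRADES}


def normalize_ihc_level(raw: str) -> ExpressionCategory:
    """Map a raw IHC level string onto the ordinal scale.

    Matching is case-insensitive with flexible internal whitespace, so
    ``"HIGH"``, ``"not  detected"`` etc. all parse.

    Raises
    ------
    TableValidationError
        If ``raw`` is not one of the four recognized level strings.
    """
    try:
        return _LEVEL_LOOKUP[_canon(raw)]
    except KeyError:
        raise TableValidationError(
            f"unrecognized IHC expression level: {raw!r} "
            f"(expected one of {list(_CATEGORY_LABELS.values())})"
        ) from None


def normalize_reliability(raw: str) -> str:
    """Canonicalize an antibody-reliability grade to its title-case form.

    Raises
    ------
    TableValidationError
        If ``raw`` is not one of the four reliability grades.
    """
    try:
        return _RELIABILITY_LOOKUP[_canon(raw)]
    except KeyError:
        raise TableValidationError(
            f"unrecognized antibody reliability: {raw!r} "
            f"(expected one of {list(RELIABILITY_GRADES)})"
        ) from None
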