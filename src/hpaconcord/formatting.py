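"""Count/percentage formatting and the printed-row consistency check.

Summary tables render every count as ``"N (P%)"`` where P is the count
as a percentage of the compartment total, rounded half-away-from-zero
to two decimals. Exact decimal arithmetic is used so the rendering of a
given (count, total) pair is reproducible and never depends on binary
float rounding at the .xx5 boundary.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

from .errors import InternalConsistencyError

__all__ = ["percentage", "format_count", "check_printed_percentage"]

_TWO_PLACES = Decimal("0.01")


def percentage(count: int | float, total: int | float) -> float:
    """``100*count/total`` rounded half-away-from-zero to 2 decimals."""
    if total == 0:
        raise InternalConsistencyError("percentage undefined for total == 0")
    pct = (Decimal(str(count)) * 100 / Decimal(str(total))).quantize(
        _TWO_PLACES, rounding=ROUND_HALF_UP
    )
    return float(pct)


def format_count(count: int | float, total: int | float) -> str:
    """Render ``"N (P%)"``, e.g. ``format_count(2682, 11157) == "2682 (24.04%)"``."""
    count_str = str(int(count)) if float(count).is_integer() else str(count)
    return f"{count_str} ({percentage(count, total):.2f}%)"


def check_printed_percentage(
    count: int | float, total: int | float, printed_pct: float, *, label: str = ""
) -> None:
    """Verify that a printed percentage matches its printed count.

    Recomputes the percentage from (count, total) under the rounding
    rule above and compares it with the value as printed. A mismatch
    means the published row is internally inconsistent (e.g. a digit
    transposition) and raises :class:`InternalConsistencyError`.
    """
    recomputed = percentage(count, total)
    if abs(recomputed - float(printed_pct)) > 1e-9:
        where = f" in row {label!r}" if label else ""
        raise InternalConsistencyError(
            f"printed percentage {printed_pct}%{where} does not match "
            f"{count}/{total} = {recomputed}%"
        )
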