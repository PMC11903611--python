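"""Readers and writers for the four tabular dialects the pipeline consumes.

Input dialects (all tab-separated, UTF-8, one header row):

``hpa_normal_tissue``
    Human Protein Atlas normal-tissue IHC export: columns
    ``Gene, Gene name, Tissue, Cell type, Level, Reliability``.
``hpa_rna_consensus``
    HPA consensus transcript abundance: ``Gene, Gene name, Tissue, nTPM``.
``compartment_ms``
    Compartment-resolved mass-spectrometry spectral counts (KPMP-style);
    column names configurable via ``column_map``.
``compartment_rna``
    Compartment-resolved external RNA-seq TPM (Levin-et-al.-style);
    column names configurable via ``column_map``.

Every reader returns a typed :class:`pandas.DataFrame` plus a
:class:`ReadReport` satisfying the conservation invariant
``n_ingested + n_dropped + n_errored == n_input``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

from .categories import normalize_ihc_level, normalize_reliability
from .errors import ConfigurationError, SchemaError, TableValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "ReadReport",
    "read_protein_table",
    "read_quant_table",
    "write_summary",
    "read_summary_json",
    "PROTEIN_COLUMNS",
    "RNA_COLUMNS",
]

#: Required columns of the HPA normal-tissue dialect, in export order.
PROTEIN_COLUMNS = {
    "Gene": "gene_id",
    "Gene name": "gene_name",
    "Tissue": "tissue",
    "Cell type": "cell_type",
    "Level": "level",
    "Reliability": "reliability",
}

#: Required columns of the HPA consensus RNA dialect.
RNA_COLUMNS = {
    "Gene": "gene_id",
    "Gene name": "gene_name",
    "Tissue": "tissue",
    "nTPM": "ntpm",
}

_MS_DEFAULT_MAP = {
    "gene": "Gene name",
    "compartment": "Compartment",
    "value": "Mean spectral count",
}
_EXT_DEFAULT_MAP = {
    "gene": "Gene name",
    "compartment": "Compartment",
    "value": "TPM",
}

MS_COMPARTMENTS = frozenset({"glomeruli", "tubulointerstitium"})
EXT_COMPARTMENTS = frozenset({"glomeruli", "tubules"})


@dataclass
class ReadReport:
    """Row accounting for one reader invocation.

    ``n_ingested + n_dropped + n_errored == n_input`` always holds;
    ``n_records`` is the record count after duplicate resolution.
    """

    n_input: int = 0
    n_ingested: int = 0
    n_dropped: int = 0
    n_errored: int = 0
    n_duplicates_collapsed: int = 0
    n_records: int = 0
    errors: list[str] = field(default_factory=list)

    def check_conservation(self) -> None:
        if self.n_ingested + self.n_dropped + self.n_errored != self.n_input:
            raise AssertionError(f"row accounting violated: {self}")


def _read_tsv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)


def _require_columns(df: pd.DataFrame, required, path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")


def read_protein_table(
    path: str | Path,
    dialect: str = "hpa_normal_tissue",
    *,
    tissue: str | None = "kidney",
    strict: bool = False,
) -> tuple[pd.DataFrame, ReadReport]:
    """Read an IHC protein-expression table.

    Rows whose tissue differs from ``tissue`` (case-insensitive) are
    dropped with a logged count; set ``tissue=None`` to keep all rows.
    Level strings are validated but preserved verbatim (normalization
    onto the ordinal scale happens in :mod:`hpaconcord.classify`);
    reliability grades are canonicalized. Duplicate
    ``(gene_id, tissue, cell_type)`` rows keep the highest ordinal
    level, with a warning.

    Returns ``(frame, report)`` where the frame has columns
    ``gene_id, gene_name, tissue, cell_type, level, reliability``.
    """
    if dialect != "hpa_normal_tissue":
        raise ConfigurationError(f"unknown dialect: {dialect!r}")
    raw = _read_tsv(path)
    _require_columns(raw, PROTEIN_COLUMNS, path)
    report = ReadReport(n_input=len(raw))

    df = raw.rename(columns=PROTEIN_COLUMNS)[list(PROTEIN_COLUMNS.values())].copy()

    if tissue is not None:
        keep = df["tissue"].str.strip().str.casefold() == tissue.casefold()
        report.n_dropped = int((~keep).sum())
        if report.n_dropped:
            logger.info(
                "read_protein_table: dropped %d non-%s row(s)", report.n_dropped, tissue
            )
        df = df[keep]

    ok_rows = []
    for idx, row in df.iterrows():
        try:
            normalize_ihc_level(row["level"])  # validate only; keep raw string
            row["reliability"] = normalize_reliability(row["reliability"])
            ok_rows.append(row)
        except TableValidationError as exc:
            msg = f"row {idx + 2}: {exc}"  # +2: header line and 1-based numbering
            report.errors.append(msg)
            if strict:
                raise TableValidationError(f"{path}: {msg}") from None
    report.n_errored = len(report.errors)
    report.n_ingested = len(ok_rows)
    df = pd.DataFrame(ok_rows, columns=list(PROTEIN_COLUMNS.values()))

    # duplicate (gene_id, tissue, cell_type): keep the highest ordinal level
    if len(df):
        order = df["level"].map(lambda s: int(normalize_ihc_level(s)))
        df = (
            df.assign(_ord=order)
            .sort_values("_ord", kind="stable")
            .drop_duplicates(["gene_id", "tissue", "cell_type"], keep="last")
            .drop(columns="_ord")
            .sort_index()
        )
    report.n_duplicates_collapsed = report.n_ingested - len(df)
    if report.n_duplicates_collapsed:
        logger.warning(
            "read_protein_table: collapsed %d duplicate (gene, tissue, cell type) "
            "row(s), keeping the highest level",
            report.n_duplicates_collapsed,
        )
    report.n_records = len(df)
    report.check_conservation()
    return df.reset_index(drop=True), report


def read_quant_table(
    path: str | Path,
    dialect: str,
    *,
    value_column: str | None = None,
    column_map: Mapping[str, str] | None = None,
    tissue: str | None = "kidney",
    strict: bool = False,
) -> tuple[pd.DataFrame, ReadReport]:
    """Read one of the three quantitative dialects into a typed frame.

    Output columns by dialect:

    - ``hpa_rna_consensus`` -> ``gene_id, gene_name, tissue, ntpm``
      (rows restricted to ``tissue`` unless ``tissue=None``)
    - ``compartment_ms``    -> ``gene_name, compartment, mean_spectral_count``
    - ``compartment_rna``   -> ``gene_name, compartment, tpm``

    Negative or non-numeric values raise :class:`TableValidationError`
    naming the offending row. Duplicate keys are averaged in default
    mode (logged); in strict mode they are an error.
    """
    raw = _read_tsv(path)
    report = ReadReport(n_input=len(raw))

    if dialect == "hpa_rna_consensus":
        value_column = value_column or "nTPM"
        required = {**RNA_COLUMNS}
        if value_column != "nTPM":
            required.pop("nTPM")
            required[value_column] = "ntpm"
        _require_columns(raw, required, path)
        df = raw.rename(columns=required)[list(required.values())].copy()
        if tissue is not None:
            keep = df["tissue"].str.strip().str.casefold() == tissue.casefold()
            report.n_dropped = int((~keep).sum())
            df = df[keep]
        value_field, key = "ntpm", ["gene_id", "tissue"]
        allowed_compartments = None
    elif dialect in ("compartment_ms", "compartment_rna"):
        cmap = dict(_MS_DEFAULT_MAP if dialect == "compartment_ms" else _EXT_DEFAULT_MAP)
        if column_map:
            cmap.update(column_map)
        if value_column:
            cmap["value"] = value_column
        value_field = "mean_spectral_count" if dialect == "compartment_ms" else "tpm"
        rename = {
            cmap["gene"]: "gene_name",
            cmap["compartment"]: "compartment",
            cmap["value"]: value_field,
        }
        _require_columns(raw, rename, path)
        df = raw.rename(columns=rename)[list(rename.values())].copy()
        df["compartment"] = df["compartment"].str.strip().str.casefold()
        key = ["gene_name", "compartment"]
        allowed_compartments = (
            MS_COMPARTMENTS if dialect == "compartment_ms" else EXT_COMPARTMENTS
        )
    else:
        raise ConfigurationError(f"unknown dialect: {dialect!r}")

    values = pd.to_numeric(df[value_field], errors="coerce")
    bad = values.isna()
    if bad.any():
        rows = [i + 2 for i in df.index[bad][:5]]
        raise TableValidationError(
            f"{path}: non-numeric {value_field} value(s) at row(s) {rows}"
        )
    if (values < 0).any():
        rows = [i + 2 for i in df.index[values < 0][:5]]
        raise TableValidationError(
            f"{path}: negative {value_field} value(s) at row(s) {rows}"
        )
    df[value_field] = values.astype(float)

    if allowed_compartments is not None:
        bad_comp = ~df["compartment"].isin(allowed_compartments)
        for i in df.index[bad_comp]:
            report.errors.append(
                f"row {i + 2}: unknown compartment {df.at[i, 'compartment']!r} "
                f"(expected one of {sorted(allowed_compartments)})"
            )
        if bad_comp.any() and strict:
            raise TableValidationError(f"{path}: {report.errors[0]}")
        report.n_errored = int(bad_comp.sum())
        df = df[~bad_comp]

    report.n_ingested = len(df)

    n_dup = int(df.duplicated(key).sum())
    if n_dup:
        if strict:
            dups = df[df.duplicated(key, keep=False)][key].drop_duplicates()
            raise TableValidationError(
                f"{path}: duplicate key(s) in strict mode: "
                f"{[tuple(r) for r in dups.itertuples(index=False)][:5]}"
            )
        logger.warning(
            "read_quant_table(%s): averaged %d duplicate key row(s)", dialect, n_dup
        )
        other = [c for c in df.columns if c not in key and c != value_field]
        agg = {value_field: "mean", **{c: "first" for c in other}}
        df = df.groupby(key, as_index=False, sort=False).agg(agg)
    report.n_duplicates_collapsed = n_dup
    report.n_records = len(df)
    report.check_conservation()
    return df.reset_index(drop=True)[_output_order(dialect, value_field)], report


def _output_order(dialect: str, value_field: str) -> list[str]:
    if dialect == "hpa_rna_consensus":
        return ["gene_id", "gene_name", "tissue", "ntpm"]
    return ["gene_name", "compartment", value_field]


def write_summary(summary, path: str | Path, format: str = "tsv") -> None:
    """Serialize a :class:`~hpaconcord.crossval.ConcordanceSummary`.

    ``tsv`` reproduces the published row structure (one row per named
    count, one column per compartment, counts rendered with
    percentages); ``json`` is a lossless machine twin whose
    write-then-read round-trip is the identity.
    """
    from .crossval import ConcordanceSummary  # local import avoids a cycle

    if not isinstance(summary, ConcordanceSummary):
        raise TypeError("write_summary expects a ConcordanceSummary")
    path = Path(path)
    if format == "tsv":
        path.write_text(summary.to_tsv(), encoding="utf-8")
    elif format == "json":
        path.write_text(
            json.dumps(summary.to_dict(), indent=2, sort_keys=True) + "\n",
            encoding="utf-8",
        )
    else:
        raise ConfigurationError(f"unknown summary format: {format!r}")


def read_summary_json(path: str | Path):
    """Inverse of ``write_summary(..., format="json")``."""
    from .crossval import ConcordanceSummary

    with open(path, encoding="utf-8") as fh:
        return ConcordanceSummary.from_dict(json.load(fh))
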