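"""Human-readable Markdown rendering of a concordance summary."""

from __future__ import annotations

from pathlib import Path

from .crossval import ConcordanceSummary

__all__ = ["render_report", "render_report_text"]


def _md_table(frame) -> str:
    header = ["row"] + list(frame.columns)
    lines = ["| " + " | ".join(header) + " |",
             "| " + " | ".join("---" for _ in header) + " |"]
    for idx, row in frame.iterrows():
        lines.append("| " + " | ".join([str(idx)] + [str(v) for v in row]) + " |")
    return "\n".join(lines)


def render_report_text(
    summary: ConcordanceSummary, audit: list[tuple[str, str, object]] | None = None
) -> str:
    """Build the Markdown report: the per-compartment count table,
    chi-square lines, threshold provenance, and the filter audit trail.
    Counts from validation tables that were not supplied render as
    "missing" (never as 0, which would claim a measurement that was
    not made)."""
    parts = [
        "# Kidney mRNA-protein concordance report",
        "",
        "## Count summary",
        "",
        _md_table(summary.to_frame()),
        "",
        "## Chi-square test of independence (mRNA category x IHC category)",
        "",
    ]
    for name, cs in summary.compartments.items():
        if cs.chi_square:
            chi = cs.chi_square
            warn = " [expected count < 5 warning]" if chi.get("validity_warning") else ""
            parts.append(
                f"- {name}: chi2 = {chi['statistic']:.2f}, "
                f"df = {chi['degrees_of_freedom']}, "
                f"p = {chi['p_value']:.3g}{warn}"
            )
        else:
            parts.append(f"- {name}: not computed")
    t = summary.thresholds
    parts += [
        "",
        "## Validation thresholds",
        "",
        f"- mRNA detected: nTPM > {t.ntpm_detect}; strict: nTPM >= {t.ntpm_strict}",
        f"- MS detected: mean spectral count >= {t.spectral_min}",
        f"- external RNA detected: TPM > {t.tpm_detect}; strict: TPM >= {t.tpm_strict}",
    ]
    if audit:
        parts += ["", "## Filter audit trail", "",
                  "| stage | metric | value |", "| --- | --- | --- |"]
        parts += [f"| {s} | {m} | {v} |" for s, m, v in audit]
    return "\n".join(parts) + "\n"


def render_report(
    summary: ConcordanceSummary,
    path: str | Path,
    audit: list[tuple[str, str, object]] | None = None,
) -> None:
    Path(path).write_text(render_report_text(summary, audit), encoding="utf-8")
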