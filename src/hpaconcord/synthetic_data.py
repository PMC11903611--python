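"""Synthetic fixture generator with recorded ground truth.

Emulates the four input tables the pipeline consumes — whole-kidney
transcript abundance, per-compartment IHC protein calls, per-compartment
MS spectral counts, and external per-compartment RNA-seq TPM — from a
single latent bivariate-normal model, so that every downstream summary
count has an independently tally-able ground truth.

Model, per gene and compartment: a latent pair ``(z_r, z_p)`` is
standard bivariate normal with correlation ``rho``. Transcript
abundance is zero-inflated lognormal driven by ``z_r``: genes whose
normal quantile falls below ``p_zero_rna`` get nTPM 0 (latent
thresholding, so non-detection co-occurs across platforms when rho >
0), the rest get ``exp(mu + sigma * z')`` where ``z'`` is the
conditional quantile of ``z_r`` above the zero threshold mapped back
to a standard normal — the positive nTPM marginal is then exactly
lognormal(mu, sigma). The IHC category comes from cutting ``z_p`` at
the cumulative protein marginals; MS spectral counts are negative
binomial with log-mean proportional to ``z_p`` (half of the
IHC-Not-detected genes are forced to zero spectral count, planting
both MS-validated and MS-silent protein nulls); external TPM is nTPM
with lognormal noise, plus a planted subset of RNA-null genes given
positive external TPM.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator
from scipy import stats

from .categories import RELIABILITY_GRADES
from .crossval import ValidationThresholds
from .errors import ConfigurationError

__all__ = [
    "GeneratorConfig",
    "SyntheticDataset",
    "generate",
    "tally_truth",
    "truth_check",
    "analytic_concordance_under_independence",
]

COMPARTMENTS = ("glomeruli", "tubules")
_CELL_TYPE = {"glomeruli": "cells in glomeruli", "tubules": "cells in tubules"}
_MS_LABEL = {"glomeruli": "glomeruli", "tubules": "tubulointerstitium"}
_LEVEL_LABELS = ("Not detected", "Low", "Medium", "High")

# Published per-compartment IHC category frequencies (Not detected, Low,
# Medium, High) and the zero-nTPM fraction of the kidney transcriptome,
# used as the generator's default study conditions.
_GLOM_MARGINALS = (5988 / 11157, 2078 / 11157, 2240 / 11157, 851 / 11157)
_TUB_MARGINALS = (3080 / 10108, 1201 / 10108, 3666 / 10108, 2161 / 10108)
_P_ZERO = 3764 / 20162


def _check_probs(v: Sequence[float], name: str, length: int) -> tuple[float, ...]:
    v = tuple(float(x) for x in v)
    if len(v) != length or any(x < 0 or x > 1 for x in v):
        raise ConfigurationError(f"{name} must be {length} probabilities in [0, 1]")
    if abs(sum(v) - 1.0) > 1e-9:
        raise ConfigurationError(f"{name} must sum to 1, got {sum(v)}")
    return v


class GeneratorConfig(BaseModel):
    """Parameters of the synthetic-data model (defaults emulate the
    marginal structure of the kidney datasets the pipeline targets)."""

    n_genes: int = Field(default=20000, ge=10)
    rho: float = Field(default=0.3, ge=-1.0, le=1.0)
    p_zero_rna: float = Field(default=_P_ZERO, ge=0.0, lt=1.0)
    protein_marginals: dict[str, tuple[float, float, float, float]] = Field(
        default={"glomeruli": _GLOM_MARGINALS, "tubules": _TUB_MARGINALS}
    )
    reliability_probs: tuple[float, float, float, float] = (0.15, 0.25, 0.45, 0.15)
    lognormal_mu: float = 1.84
    lognormal_sigma: float = Field(default=1.73, gt=0)
    ms_mean_link: float = 2.0
    ms_dispersion: float = Field(default=1.0, gt=0)
    ms_missing_frac: float = Field(default=0.05, ge=0.0, le=1.0)
    ext_noise_sd: float = Field(default=0.3, ge=0.0)
    ext_plant_frac: float = Field(default=0.8, ge=0.0, le=1.0)
    ext_plant_mu: float = -1.5
    ext_plant_sigma: float = Field(default=1.0, gt=0)
    overlap_frac: float = Field(default=0.553, ge=0.0, le=1.0)
    n_ihc_only: int = Field(default=0, ge=0)
    seed: int = 0

    @field_validator("reliability_probs")
    @classmethod
    def _valid_reliability(cls, v):
        return _check_probs(v, "reliability_probs", 4)

    @field_validator("protein_marginals")
    @classmethod
    def _valid_marginals(cls, v):
        if set(v) != set(COMPARTMENTS):
            raise ConfigurationError(
                f"protein_marginals must have keys {COMPARTMENTS}"
            )
        return {k: _check_probs(p, f"protein_marginals[{k}]", 4) for k, p in v.items()}


@dataclass
class SyntheticDataset:
    """The four emitted tables (in their input dialects) plus ground truth."""

    rna: pd.DataFrame  # HPA consensus-RNA dialect
    ihc: pd.DataFrame  # HPA normal-tissue dialect
    ms: pd.DataFrame  # compartment-MS dialect
    ext: pd.DataFrame  # compartment-RNA dialect
    truth: pd.DataFrame  # one row per gene x compartment
    config: GeneratorConfig

    # typed views with the internal column names the pipeline operates on
    @property
    def rna_typed(self) -> pd.DataFrame:
        return self.rna.rename(
            columns={"Gene": "gene_id", "Gene name": "gene_name",
                     "Tissue": "tissue", "nTPM": "ntpm"}
        )

    @property
    def ihc_typed(self) -> pd.DataFrame:
        return self.ihc.rename(
            columns={"Gene": "gene_id", "Gene name": "gene_name", "Tissue": "tissue",
                     "Cell type": "cell_type", "Level": "level",
                     "Reliability": "reliability"}
        )

    @property
    def ms_typed(self) -> pd.DataFrame:
        return self.ms.rename(
            columns={"Gene name": "gene_name", "Compartment": "compartment",
                     "Mean spectral count": "mean_spectral_count"}
        )

    @property
    def ext_typed(self) -> pd.DataFrame:
        return self.ext.rename(
            columns={"Gene name": "gene_name", "Compartment": "compartment",
                     "TPM": "tpm"}
        )

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Emit the four dialect TSVs plus ``truth.tsv``; deterministic bytes."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name, df in [("rna", self.rna), ("ihc", self.ihc), ("ms", self.ms),
                         ("external_rna", self.ext), ("truth", self.truth)]:
            paths[name] = outdir / f"{name}.tsv"
            df.to_csv(paths[name], sep="\t", index=False)
        return paths


def generate(config: GeneratorConfig) -> SyntheticDataset:
    """Draw one synthetic dataset; identical config (incl. seed) gives
    byte-identical tables."""
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    gene_id = np.array([f"ENSG{i:011d}" for i in range(n)])
    gene_name = np.array([f"GENE{i:05d}" for i in range(n)])

    z_r = rng.standard_normal(n)
    u_r = stats.norm.cdf(z_r)
    is_zero = u_r < config.p_zero_rna
    ntpm = np.zeros(n)
    if (~is_zero).any():
        # conditional quantile above the zero threshold, re-standardized:
        # positive nTPM is exactly lognormal(mu, sigma) and monotone in z_r
        u_pos = (u_r[~is_zero] - config.p_zero_rna) / (1 - config.p_zero_rna)
        z_pos = stats.norm.ppf(np.clip(u_pos, 1e-12, 1 - 1e-12))
        ntpm[~is_zero] = np.exp(
            config.lognormal_mu + config.lognormal_sigma * z_pos
        )
    ntpm = np.round(ntpm, 6)

    reliability = rng.choice(
        RELIABILITY_GRADES, size=n, p=config.reliability_probs
    )
    n_overlap = int(round(config.overlap_frac * n))
    in_ihc = np.zeros(n, dtype=bool)
    in_ihc[rng.permutation(n)[:n_overlap]] = True

    sqrt_term = np.sqrt(max(0.0, 1 - config.rho**2))
    truth_rows = []
    ihc_rows = []
    ms_rows = []
    ext_rows = []
    for compartment in COMPARTMENTS:
        z_p = config.rho * z_r + sqrt_term * rng.standard_normal(n)
        cuts = stats.norm.ppf(
            np.cumsum(config.protein_marginals[compartment])[:-1]
        )
        protein_cat = np.searchsorted(cuts, z_p, side="left")

        ms_mean = np.exp(config.ms_mean_link * z_p)
        size = config.ms_dispersion
        ms_count = rng.negative_binomial(size, size / (size + ms_mean))
        silence = (protein_cat == 0) & (rng.random(n) < 0.5)
        ms_count = np.where(silence, 0, ms_count).astype(float)
        ms_present = rng.random(n) >= config.ms_missing_frac

        eps = rng.normal(0.0, config.ext_noise_sd, n)
        ext_tpm = np.round(ntpm * np.exp(eps), 6)
        plant = is_zero & (rng.random(n) < config.ext_plant_frac)
        planted_tpm = np.round(
            np.exp(rng.normal(config.ext_plant_mu, config.ext_plant_sigma, n)), 6
        )
        ext_tpm = np.where(plant, planted_tpm, ext_tpm)

        ihc_rows.append(
            pd.DataFrame(
                {
                    "Gene": gene_id[in_ihc],
                    "Gene name": gene_name[in_ihc],
                    "Tissue": "kidney",
                    "Cell type": _CELL_TYPE[compartment],
                    "Level": np.array(_LEVEL_LABELS)[protein_cat[in_ihc]],
                    "Reliability": reliability[in_ihc],
                }
            )
        )
        ms_rows.append(
            pd.DataFrame(
                {
                    "Gene name": gene_name[ms_present],
                    "Compartment": _MS_LABEL[compartment],
                    "Mean spectral count": ms_count[ms_present],
                }
            )
        )
        ext_rows.append(
            pd.DataFrame(
                {"Gene name": gene_name, "Compartment": compartment, "TPM": ext_tpm}
            )
        )
        truth_rows.append(
            pd.DataFrame(
                {
                    "gene_id": gene_id,
                    "gene_name": gene_name,
                    "compartment": compartment,
                    "in_rna": True,
                    "in_ihc": in_ihc,
                    "ntpm": ntpm,
                    "protein_category": protein_cat,
                    "reliability": reliability,
                    "ms_count": np.where(ms_present, ms_count, np.nan),
                    "ext_tpm": ext_tpm,
                }
            )
        )

    if config.n_ihc_only:
        # genes carried only by the IHC table (no transcript row)
        extra_id = np.array(
            [f"ENSG{n + i:011d}" for i in range(config.n_ihc_only)]
        )
        extra_name = np.array([f"GENE{n + i:05d}" for i in range(config.n_ihc_only)])
        for compartment in COMPARTMENTS:
            cat = rng.choice(4, size=config.n_ihc_only,
                             p=config.protein_marginals[compartment])
            ihc_rows.append(
                pd.DataFrame(
                    {
                        "Gene": extra_id,
                        "Gene name": extra_name,
                        "Tissue": "kidney",
                        "Cell type": _CELL_TYPE[compartment],
                        "Level": np.array(_LEVEL_LABELS)[cat],
                        "Reliability": rng.choice(
                            RELIABILITY_GRADES, size=config.n_ihc_only,
                            p=config.reliability_probs
                        ),
                    }
                )
            )

    rna = pd.DataFrame(
        {"Gene": gene_id, "Gene name": gene_name, "Tissue": "kidney", "nTPM": ntpm}
    )
    return SyntheticDataset(
        rna=rna,
        ihc=pd.concat(ihc_rows, ignore_index=True),
        ms=pd.concat(ms_rows, ignore_index=True),
        ext=pd.concat(ext_rows, ignore_index=True),
        truth=pd.concat(truth_rows, ignore_index=True),
        config=config,
    )


def _truth_rna_category(ntpm: np.ndarray, t1: float, t2: float) -> np.ndarray:
    """Zero/tertile rule re-derived inline so the tally is an
    independent oracle for the classification path."""
    return np.where(
        ntpm == 0, 0, np.where(ntpm <= t1, 1, np.where(ntpm <= t2, 2, 3))
    )


def tally_truth(
    truth: pd.DataFrame,
    t1: float,
    t2: float,
    thresholds: ValidationThresholds = ValidationThresholds(),
) -> dict[str, dict[str, int]]:
    """Independently tally every summary count from the ground truth.

    RNA categories are re-derived from the true nTPM values using the
    tertile thresholds the pipeline published (``t1``, ``t2``), by
    direct boolean counting — no pipeline code is reused.
    """
    out: dict[str, dict[str, int]] = {}
    for compartment, grp in truth.groupby("compartment", sort=True):
        paired = grp[grp["in_rna"] & grp["in_ihc"] & (grp["reliability"] != "Uncertain")]
        rna_cat = _truth_rna_category(paired["ntpm"].to_numpy(), t1, t2)
        prot_cat = paired["protein_category"].to_numpy()
        ntpm = paired["ntpm"].to_numpy()
        ms = paired["ms_count"].to_numpy()
        tpm = paired["ext_tpm"].to_numpy()

        protein_null = (prot_cat == 0) & (rna_cat > 0)
        rna_null = (rna_cat == 0) & (prot_cat > 0)
        pn_detect = protein_null & (ntpm > thresholds.ntpm_detect)
        rn_detect = rna_null & ~np.isnan(tpm) & (tpm > thresholds.tpm_detect)
        out[str(compartment)] = {
            "total": len(paired),
            "concordant": int((rna_cat == prot_cat).sum()),
            "discordant": int((rna_cat != prot_cat).sum()),
            "protein_null_rna_detected": int(pn_detect.sum()),
            "protein_null_ntpm_strict": int(
                (pn_detect & (ntpm >= thresholds.ntpm_strict)).sum()
            ),
            "protein_null_ms_validated": int(
                (pn_detect & ~np.isnan(ms) & (ms >= thresholds.spectral_min)).sum()
            ),
            "rna_null_protein_detected": int(rna_null.sum()),
            "rna_null_tpm_detected": int(rn_detect.sum()),
            "rna_null_tpm_strict": int(
                (rn_detect & (tpm >= thresholds.tpm_strict)).sum()
            ),
        }
    return out


def truth_check(summary, truth: pd.DataFrame, t1: float, t2: float) -> list[str]:
    """Compare a pipeline :class:`~hpaconcord.crossval.ConcordanceSummary`
    with the ground-truth tally; returns one message per discrepancy
    (empty list means the pipeline agrees with the truth everywhere)."""
    expected = tally_truth(truth, t1, t2, summary.thresholds)
    discrepancies: list[str] = []
    for compartment, exp in expected.items():
        if compartment not in summary.compartments:
            discrepancies.append(f"missing compartment {compartment!r} in summary")
            continue
        cs = summary.compartments[compartment]
        for fld, want in exp.items():
            got = getattr(cs, fld)
            if got != want:
                discrepancies.append(
                    f"{compartment}.{fld}: pipeline={got} truth={want}"
                )
    return discrepancies


def analytic_concordance_under_independence(
    config: GeneratorConfig, compartment: str
) -> float:
    """Expected concordant fraction when rho = 0: sum of p_i * q_i over
    the four categories, with the RNA marginal (p_zero, equal tertiles)
    and the compartment's configured protein marginal."""
    q = config.protein_marginals[compartment]
    p0 = config.p_zero_rna
    p = (p0, (1 - p0) / 3, (1 - p0) / 3, (1 - p0) / 3)
    return float(sum(pi * qi for pi, qi in zip(p, q)))
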