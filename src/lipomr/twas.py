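"""Summary-based transcriptome-wide association testing.

Given a pre-trained cis-eQTL weight model for a gene (variant weights ``w``,
reference LD ``R``) and per-variant GWAS Z-scores for a trait, the gene's
association Z-score is

    Z_g = sum_l w_l * sigma_l * Z_l / sigma_g,
    sigma_g = sqrt(w' S R S w),  S = diag(sigma_l),

with per-variant genotype SD ``sigma_l = sqrt(2 * eaf_l * (1 - eaf_l))``
under Hardy-Weinberg — the standard summary-form substitute when reference
genotypes are unavailable.

Between-trait comparison uses the differential-effect statistic

    Zdiff = (effect_1 - effect_2) / sqrt(se_1^2 + se_2^2)

in ``signed`` mode, or on absolute effects in ``magnitude`` mode (both are
exposed; reports must name the mode used).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ConfigurationError, DataError, LDMatrix
from .stats_util import bh_fdr


@dataclass
class TwasWeightModel:
    """Cis-eQTL expression prediction weights for one gene."""

    gene: str
    variant_ids: list[str]
    weights: np.ndarray
    eaf: np.ndarray
    ld_ref: LDMatrix

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.eaf = np.asarray(self.eaf, dtype=float)
        m = len(self.variant_ids)
        if self.weights.shape != (m,) or self.eaf.shape != (m,):
            raise DataError(f"{self.gene}: weights/eaf must have length {m}")
        if not np.any(self.weights != 0.0):
            raise DataError(f"{self.gene}: all weights are zero")
        if ((self.eaf <= 0) | (self.eaf >= 1)).any():
            raise DataError(f"{self.gene}: eaf must lie in (0,1)")
        self.ld_ref.index_of(self.variant_ids)  # raises if not covered


@dataclass(frozen=True)
class TwasResult:
    """Gene-level association for one trait."""

    gene: str
    z: float
    pvalue: float
    n_variants_used: int
    coverage: float  # fraction of weighted variants with a trait Z
    flagged_low_coverage: bool
    q_fdr: float | None = None

    @property
    def effect(self) -> float:
        """Z-scaled effect (unit SE) for downstream between-trait comparison."""
        return self.z

    @property
    def se(self) -> float:
        return 1.0


@dataclass(frozen=True)
class DiffResult:
    """Between-trait differential effect for one gene."""

    gene: str
    zdiff: float
    pvalue: float
    direction: str  # which trait has the larger (signed or absolute) effect
    mode: str


def twas_z(model: TwasWeightModel, gwas_z: dict[str, float]) -> TwasResult:
    """Gene-trait association Z from eQTL weights and variant Z-scores.

    Weighted variants missing from ``gwas_z`` are dropped and counted;
    coverage below 50% flags the result.
    """
    have = [i for i, v in enumerate(model.variant_ids) if v in gwas_z]
    weighted = np.flatnonzero(model.weights != 0.0)
    cov_den = len(weighted)
    cov_num = len(set(have) & set(weighted.tolist()))
    coverage = cov_num / cov_den if cov_den else 0.0
    if cov_num == 0:
        raise DataError(f"{model.gene}: no weighted variant has a GWAS Z-score")

    ids = [model.variant_ids[i] for i in have]
    w = model.weights[have]
    eaf = model.eaf[have]
    R = model.ld_ref.subset(ids).r
    sigma = np.sqrt(2.0 * eaf * (1.0 - eaf))
    sw = sigma * w
    var_g = float(sw @ R @ sw)
    if var_g <= 0.0:
        raise DataError(f"{model.gene}: degenerate model (sigma_g = 0)")
    z_vec = np.array([gwas_z[v] for v in ids])
    z_g = float(sw @ z_vec / np.sqrt(var_g))
    return TwasResult(
        gene=model.gene,
        z=z_g,
        pvalue=float(2.0 * stats.norm.sf(abs(z_g))),
        n_variants_used=len(have),
        coverage=coverage,
        flagged_low_coverage=coverage < 0.5,
    )


def run_twas(models: list[TwasWeightModel], gwas_z: dict[str, float]) -> list[TwasResult]:
    """TWAS across genes with per-trait BH q-values attached."""
    raw = [twas_z(m, gwas_z) for m in models]
    q = bh_fdr(np.array([r.pvalue for r in raw]))
    return [
        TwasResult(
            gene=r.gene,
            z=r.z,
            pvalue=r.pvalue,
            n_variants_used=r.n_variants_used,
            coverage=r.coverage,
            flagged_low_coverage=r.flagged_low_coverage,
            q_fdr=float(qi),
        )
        for r, qi in zip(raw, q)
    ]


def zdiff(
    gene: str,
    effect1: float,
    se1: float,
    effect2: float,
    se2: float,
    mode: str = "signed",
) -> DiffResult:
    """Differential-effect Z between two traits for one gene."""
    if se1 <= 0 or se2 <= 0:
        raise DataError("standard errors must be > 0")
    if mode not in ("signed", "magnitude"):
        raise ConfigurationError(f"mode must be signed|magnitude, got {mode!r}")
    e1, e2 = (effect1, effect2) if mode == "signed" else (abs(effect1), abs(effect2))
    z = (e1 - e2) / np.hypot(se1, se2)
    direction = "trait1" if z > 0 else ("trait2" if z < 0 else "equal")
    return DiffResult(
        gene=gene,
        zdiff=float(z),
        pvalue=float(2.0 * stats.norm.sf(abs(z))),
        direction=direction,
        mode=mode,
    )


def zdiff_table(
    results_a: list[TwasResult],
    results_b: list[TwasResult],
    mode: str = "signed",
) -> pd.DataFrame:
    """Per-gene Zdiff over the common gene set of two TWAS runs."""
    b_by_gene = {r.gene: r for r in results_b}
    rows = []
    for ra in results_a:
        rb = b_by_gene.get(ra.gene)
        if rb is None:
            continue
        d = zdiff(ra.gene, ra.effect, ra.se, rb.effect, rb.se, mode=mode)
        rows.append(
            {
                "gene": d.gene,
                "effect_a": ra.effect,
                "effect_b": rb.effect,
                "zdiff": d.zdiff,
                "pvalue": d.pvalue,
                "direction": d.direction,
                "mode": d.mode,
            }
        )
    return pd.DataFrame(rows)


def classify_genes(
    results_a: list[TwasResult],
    results_b: list[TwasResult],
    q_threshold: float = 0.05,
) -> dict[str, set[str]]:
    """Partition significant genes into unique-to-A / unique-to-B / shared.

    Significance is per-trait FDR (q < threshold), computed before
    classification; the three sets are disjoint and their union is exactly
    the genes significant for either trait.
    """
    def sig(results: list[TwasResult]) -> set[str]:
        if any(r.q_fdr is None for r in results):
            q = bh_fdr(np.array([r.pvalue for r in results]))
            return {r.gene for r, qi in zip(results, q) if qi < q_threshold}
        return {r.gene for r in results if r.q_fdr < q_threshold}

    sa, sb = sig(results_a), sig(results_b)
    return {"unique_a": sa - sb, "unique_b": sb - sa, "shared": sa & sb}


def effect_correlation(
    results_a: list[TwasResult], results_b: list[TwasResult]
) -> tuple[float, float]:
    """Pearson correlation of per-gene effects across two traits."""
    b_by_gene = {r.gene: r.effect for r in results_b}
    pairs = [(r.effect, b_by_gene[r.gene]) for r in results_a if r.gene in b_by_gene]
    if len(pairs) < 3:
        raise DataError("effect correlation requires >= 3 paired genes")
    x, y = np.array(pairs).T
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)
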