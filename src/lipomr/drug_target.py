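"""Gene-region (drug-target) MR and between-outcome ratio of effects.

Instruments for a drug-target proxy are exposure-significant variants inside
a flanked gene window (default +/- 200 kb, closed interval), LD-pruned at a
permissive r^2 < 0.1 so deliberately correlated cis variants remain usable;
effect estimation is then LD-aware IVW (GLS with the instrument LD matrix),
with MR-Egger as a sensitivity analysis when more than two variants are
available. Estimates are reported per 1-SD *decrease* in the exposure — the
drug-effect convention — so a protective target has OR < 1.

Outcome comparisons use the ratio of log-odds effects (outcome A over
outcome B) with a percentile bootstrap over instruments: variant indices
are resampled once per replicate and applied to both outcomes' fits
jointly, preserving cross-outcome dependence when the panels share
instruments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import mr_core
from .containers import (
    ConfigurationError,
    DataError,
    GeneRegion,
    HarmonizedPanel,
    LDMatrix,
    MREstimate,
    SummaryStatSet,
)
from .gwas_io import harmonize, ld_prune, select_instruments
from .stats_util import bh_fdr  # re-exported: FDR over per-gene p-values

__all__ = [
    "region_instruments",
    "gene_based_mr",
    "ratio_of_effects",
    "bh_fdr",
    "RatioOfEffects",
    "GeneTargetResult",
    "APOB_TARGET_GENES",
]

# Canonical regulators of ApoB metabolism proxying current or proposed
# lipid-lowering therapeutics.
APOB_TARGET_GENES = [
    "ABCG5", "ABCG8", "ANGPTL3", "ANGPTL4", "ANGPTL8", "APOC3", "APOA5",
    "APOB", "CETP", "DGAT2", "HMGCR", "LDLR", "LPL", "MTTP", "NPC1L1",
    "PCSK9", "PPARA",
]


def load_apob_target_regions(flank_bp: int = 200_000) -> list[GeneRegion]:
    """Bundled annotation for the canonical ApoB-pathway target genes.

    Coordinates are synthetic placeholders laid out on the package's
    synthetic genome (one gene per chromosome, 50 kb body); supply your own
    annotation file via :func:`lipomr.gwas_io.read_gene_regions` for real
    genomes.
    """
    from importlib import resources

    from .gwas_io import read_gene_regions

    path = resources.files("lipomr").joinpath("data/apob_target_genes_synthetic.tsv")
    with resources.as_file(path) as p:
        return read_gene_regions(p, flank_bp=flank_bp)


@dataclass(frozen=True)
class RatioOfEffects:
    """Bootstrap ratio of log-odds effects between two outcomes."""

    ratio: float
    ci_low: float
    ci_high: float
    pvalue: float
    n_boot: int
    n_excluded: int
    seed: int
    degenerate: bool = False


@dataclass
class GeneTargetResult:
    """Per-gene (or polygenic) drug-target MR result."""

    gene: str
    estimates: dict[str, MREstimate]  # outcome -> IVW estimate, per-SD-decrease scale
    egger: dict[str, MREstimate | None]
    ratio: RatioOfEffects | None
    n_variants: int
    q_fdr: float | None = None
    estimable: bool = True
    note: str = ""


def region_instruments(
    exposure: SummaryStatSet,
    outcome: SummaryStatSet,
    region: GeneRegion,
    ld: LDMatrix,
    p_threshold: float = 5e-8,
    r2_threshold: float = 0.1,
    extra_outcomes: list[SummaryStatSet] | None = None,
) -> HarmonizedPanel | None:
    """Select and prune instruments inside a flanked gene window.

    Returns the harmonized, significance-filtered, LD-pruned panel, or
    ``None`` when no variant in the window reaches ``p_threshold`` (a
    reported, non-fatal outcome). Variants lacking chrom/pos are an error.
    """
    in_window = []
    for rec in exposure.records:
        if rec.chrom is None or rec.pos is None:
            raise DataError(f"{rec.variant_id}: chrom/pos required for region selection")
        if region.contains(rec.chrom, rec.pos):
            in_window.append(rec)
    if not in_window:
        return None
    sub = SummaryStatSet(exposure.trait_name, exposure.trait_type, in_window)
    outs = [outcome] + list(extra_outcomes or [])
    shared = set(sub.by_id())
    for o in outs:
        shared &= set(o.by_id())
    if not shared:
        return None
    try:
        panel = harmonize([sub], outcome)
    except DataError:
        return None
    sig = panel.pX is not None and (panel.pX.min(axis=1) < p_threshold).any()
    if not sig:
        return None
    panel = select_instruments(panel, p_threshold=p_threshold, rule="any_exposure")
    return ld_prune(panel, ld, r2_threshold=r2_threshold)


def _per_sd_decrease(est: MREstimate) -> MREstimate:
    """Flip an estimate from per-SD-increase to per-SD-decrease convention."""
    return MREstimate(
        method=est.method,
        exposure=est.exposure,
        theta=-est.theta,
        se=est.se,
        ci_low=-est.ci_high,
        ci_high=-est.ci_low,
        pvalue=est.pvalue,
        n_variants=est.n_variants,
        Q=est.Q,
        egger_intercept=None if est.egger_intercept is None else -est.egger_intercept,
        egger_intercept_se=est.egger_intercept_se,
        egger_intercept_p=est.egger_intercept_p,
        degenerate=est.degenerate,
    )


def gene_based_mr(
    gene: str,
    panels: dict[str, HarmonizedPanel],
    ld: LDMatrix | None,
    effects: str = "random",
    scale: str = "per-SD-decrease",
) -> GeneTargetResult:
    """LD-aware IVW per outcome for one gene region.

    MR-Egger runs as a sensitivity analysis when more than two variants are
    present; with two or fewer it is skipped and flagged. An empty panel is
    reported as not-estimable rather than raising.
    """
    if scale not in ("per-SD-decrease", "per-SD-increase"):
        raise ConfigurationError(f"unknown scale {scale!r}")
    flip = scale == "per-SD-decrease"
    estimates: dict[str, MREstimate] = {}
    egger: dict[str, MREstimate | None] = {}
    note = ""
    n_var = 0
    for outcome, panel in panels.items():
        if panel is None or panel.n_variants == 0:
            return GeneTargetResult(
                gene=gene, estimates={}, egger={}, ratio=None, n_variants=0,
                estimable=False, note="no instruments in region",
            )
        n_var = panel.n_variants
        eff = effects if panel.n_variants >= 2 else "fixed"
        est = mr_core.ivw(panel, ld=ld, effects=eff)
        estimates[outcome] = _per_sd_decrease(est) if flip else est
        if panel.n_variants > 2:
            try:
                eg = mr_core.mr_egger(panel, ld=ld, effects=effects)
                egger[outcome] = _per_sd_decrease(eg) if flip else eg
            except DataError:
                egger[outcome] = None
                note = "degenerate Egger design"
        else:
            egger[outcome] = None
            note = "Egger skipped: <=2 SNPs"
    return GeneTargetResult(
        gene=gene, estimates=estimates, egger=egger, ratio=None,
        n_variants=n_var, note=note,
    )


def ratio_of_effects(
    est_a: MREstimate,
    est_b: MREstimate,
    panel_a: HarmonizedPanel | None = None,
    panel_b: HarmonizedPanel | None = None,
    ld: LDMatrix | None = None,
    n_boot: int = 10_000,
    seed: int = 0,
    min_abs_denominator: float = 1e-4,
    effects: str = "random",
) -> RatioOfEffects:
    """Ratio of log-odds effects (A over B) with bootstrap percentile CI.

    The point estimate is ``theta_A / theta_B``. When both panels are
    supplied, each bootstrap replicate resamples variant indices with
    replacement — jointly across outcomes when the panels share the same
    variant set — refits both IVW estimates, and records the ratio.
    Replicates with ``|theta_B|`` below ``min_abs_denominator`` are excluded
    and counted (more than 5% exclusions is reported via the count). The
    two-sided p-value tests ratio = 1 with the add-one correction.

    Without panels (or with single-variant panels) only the point estimate
    is meaningful and the result is flagged degenerate with a zero-width CI.
    """
    if est_b.theta == 0:
        raise DataError("ratio undefined: denominator effect is zero")
    point = est_a.theta / est_b.theta

    boot_possible = (
        panel_a is not None
        and panel_b is not None
        and panel_a.n_variants > 1
        and panel_b.n_variants > 1
    )
    if not boot_possible:
        return RatioOfEffects(
            ratio=float(point), ci_low=float(point), ci_high=float(point),
            pvalue=1.0, n_boot=0, n_excluded=0, seed=seed, degenerate=True,
        )

    rng = np.random.default_rng(seed)
    shared = panel_a.variant_ids == panel_b.variant_ids
    Ja, Jb = panel_a.n_variants, panel_b.n_variants
    ratios = []
    excluded = 0
    for _ in range(n_boot):
        idx_a = rng.integers(0, Ja, size=Ja)
        idx_b = idx_a if shared else rng.integers(0, Jb, size=Jb)
        try:
            ta = _boot_ivw(panel_a, idx_a, ld, effects)
            tb = _boot_ivw(panel_b, idx_b, ld, effects)
        except (DataError, np.linalg.LinAlgError):
            excluded += 1
            continue
        if abs(tb) < min_abs_denominator:
            excluded += 1
            continue
        ratios.append(ta / tb)
    if not ratios:
        raise DataError("all bootstrap replicates were excluded")
    arr = np.sort(np.asarray(ratios))
    lo, hi = np.percentile(arr, [2.5, 97.5])
    n_ok = len(arr)
    below = int((arr <= 1.0).sum())
    above = int((arr >= 1.0).sum())
    p = 2.0 * min((below + 1) / (n_ok + 1), (above + 1) / (n_ok + 1))
    return RatioOfEffects(
        ratio=float(point), ci_low=float(lo), ci_high=float(hi),
        pvalue=float(min(1.0, p)), n_boot=n_boot, n_excluded=excluded, seed=seed,
    )


def _boot_ivw(panel: HarmonizedPanel, idx: np.ndarray, ld: LDMatrix | None, effects: str) -> float:
    """IVW theta on a bootstrap resample of variants (GLS when LD given)."""
    sub = panel.take(idx)
    if ld is not None:
        pos = ld.index_of(panel.variant_ids)
        R = ld.r[np.ix_(pos[idx], pos[idx])]
        # resampling can duplicate rows -> exactly singular R; ridge to PSD
        sub_ld = LDMatrix([f"b{i}" for i in range(len(idx))], R)
        sub = HarmonizedPanel(
            variant_ids=sub_ld.variant_ids,
            exposure_names=sub.exposure_names,
            bX=sub.bX, seX=sub.seX, bY=sub.bY, seY=sub.seY,
        )
        est = mr_core.ivw(sub, ld=sub_ld, effects=effects)
    else:
        est = mr_core.ivw(sub, ld=None, effects=effects)
    return est.theta


def drug_target_analysis(
    exposure: SummaryStatSet,
    outcomes: dict[str, SummaryStatSet],
    regions: list[GeneRegion],
    ld: LDMatrix,
    ratio_pair: tuple[str, str] | None = None,
    p_threshold: float = 5e-8,
    r2_threshold: float = 0.1,
    n_boot: int = 2000,
    seed: int = 0,
    effects: str = "random",
) -> pd.DataFrame:
    """Per-gene and polygenic drug-target MR across outcomes.

    For every gene region, instruments are selected and pruned once on the
    exposure and re-used for every outcome; the pooled union of all gene
    instruments forms the polygenic row. When ``ratio_pair = (A, B)`` the
    bootstrap ratio of effects of A vs B is added per gene, and per-outcome
    IVW p-values receive BH q-values across genes.
    """
    rng = np.random.default_rng(seed)
    rows = []
    results: list[GeneTargetResult] = []
    pooled_ids: list[str] = []

    for region in regions:
        first_outcome = next(iter(outcomes.values()))
        panel0 = region_instruments(
            exposure, first_outcome, region, ld,
            p_threshold=p_threshold, r2_threshold=r2_threshold,
        )
        if panel0 is None:
            results.append(
                GeneTargetResult(
                    gene=region.gene, estimates={}, egger={}, ratio=None,
                    n_variants=0, estimable=False, note="no instruments in region",
                )
            )
            continue
        ids = panel0.variant_ids
        pooled_ids.extend(v for v in ids if v not in pooled_ids)
        panels = {name: _subset_on(exposure, out, ids) for name, out in outcomes.items()}
        res = gene_based_mr(region.gene, panels, ld=ld, effects=effects)
        if ratio_pair and res.estimable:
            a, b = ratio_pair
            res.ratio = ratio_of_effects(
                res.estimates[a], res.estimates[b],
                panels[a], panels[b], ld=ld, n_boot=n_boot,
                seed=int(rng.integers(0, 2**31 - 1)), effects=effects,
            )
        results.append(res)

    if pooled_ids:
        panels = {
            name: _subset_on(exposure, out, pooled_ids) for name, out in outcomes.items()
        }
        poly = gene_based_mr("Polygenic Targets", panels, ld=ld, effects=effects)
        if ratio_pair and poly.estimable:
            a, b = ratio_pair
            poly.ratio = ratio_of_effects(
                poly.estimates[a], poly.estimates[b],
                panels[a], panels[b], ld=ld, n_boot=n_boot,
                seed=int(rng.integers(0, 2**31 - 1)), effects=effects,
            )
        results.append(poly)

    estimable = [r for r in results if r.estimable]
    for name in outcomes:
        ps = np.array([r.estimates[name].pvalue for r in estimable])
        qs = bh_fdr(np.clip(ps, np.nextafter(0, 1), 1.0)) if len(ps) else []
        for r, q in zip(estimable, qs):
            if name == next(iter(outcomes)):  # record q once, on the first outcome
                r.q_fdr = float(q)

    for r in results:
        row: dict[str, object] = {"gene": r.gene, "J": r.n_variants, "note": r.note}
        for name in outcomes:
            est = r.estimates.get(name)
            if est is None:
                row.update({f"OR_{name}": np.nan, f"CI_low_{name}": np.nan,
                            f"CI_high_{name}": np.nan, f"p_{name}": np.nan})
            else:
                row.update(
                    {
                        f"OR_{name}": est.odds_ratio,
                        f"CI_low_{name}": float(np.exp(est.ci_low)),
                        f"CI_high_{name}": float(np.exp(est.ci_high)),
                        f"p_{name}": est.pvalue,
                    }
                )
        if r.ratio is not None:
            row.update(
                {
                    "ratio": r.ratio.ratio,
                    "ratio_ci_low": r.ratio.ci_low,
                    "ratio_ci_high": r.ratio.ci_high,
                    "ratio_p": r.ratio.pvalue,
                }
            )
        else:
            row.update({"ratio": np.nan, "ratio_ci_low": np.nan,
                        "ratio_ci_high": np.nan, "ratio_p": np.nan})
        row["q_fdr"] = r.q_fdr
        rows.append(row)
    return pd.DataFrame(rows)


def _subset_on(
    exposure: SummaryStatSet, outcome: SummaryStatSet, ids: list[str]
) -> HarmonizedPanel:
    keep = set(ids)
    sub = SummaryStatSet(
        exposure.trait_name,
        exposure.trait_type,
        [r for r in exposure.records if r.variant_id in keep],
    )
    panel = harmonize([sub], outcome)
    order = {v: i for i, v in enumerate(panel.variant_ids)}
    return panel.take([order[v] for v in ids if v in order])
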