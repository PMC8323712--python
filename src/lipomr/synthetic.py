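"""Synthetic GWAS summary statistics with known causal structure.

The generator emulates the statistical setting of a lipoprotein /
atherosclerosis MR study: ~150 genome-wide-significant instruments whose
associations with K correlated lipoprotein exposures follow a sparse latent
factor model (mimicking the shared genetic architecture of ApoB, LDL-C and
triglyceride-related traits), an outcome whose per-variant log-odds are a
linear combination of a sparse causal subset of exposures plus optional
direct (pleiotropic) variant effects, block-diagonal AR(1) LD, and Gaussian
estimation noise with the standard summary-statistic standard errors

    quantitative trait:  se = 1 / sqrt(2 * maf * (1-maf) * n)
    binary outcome:      se = 1 / sqrt(2 * maf * (1-maf) * n_eff),
                         n_eff = 4 / (1/cases + 1/controls)

Summary statistics are simulated directly (no individual-level genotypes).
Noise is independent across variants by default — the regime of LD-pruned
instrument panels — with a correlated-noise mode (noise covariance
proportional to LD) for gene-region analyses where instruments are
deliberately correlated.

Default sample sizes follow the study conditions the package targets:
exposure GWAS n = 361,194; outcome 31,307 cases / 211,753 controls.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from .containers import ConfigurationError, HarmonizedPanel, LDMatrix

MAJOR_LIPIDS = ["LDL-C", "HDL-C", "Triglycerides", "ApoB", "ApoA1"]
SUBFRACTIONS = [
    "XXL.VLDL.P", "XL.VLDL.P", "L.VLDL.P", "M.VLDL.P", "S.VLDL.P",
    "XS.VLDL.P", "IDL.P", "L.LDL.P", "M.LDL.P", "S.LDL.P",
]


@dataclass
class SyntheticConfig:
    """Ground-truth configuration for one simulated study."""

    n_variants: int = 150
    exposures: list[str] = field(default_factory=lambda: list(MAJOR_LIPIDS))
    n_latent_factors: int = 2
    loading_scale: float = 0.03
    unique_frac: float = 0.7  # unique-variance noise sd as a fraction of loading_scale
    causal_set: dict[str, float] = field(default_factory=lambda: {"ApoB": 0.14})
    n_exposure_gwas: float = 361_194
    n_outcome_cases: float = 31_307
    n_outcome_controls: float = 211_753
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_block_size: int = 1
    ld_rho: float = 0.0
    correlated_noise: bool = False
    pleiotropy_frac: float = 0.0
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        K = len(self.exposures)
        if self.n_variants < 1 or K < 1 or self.n_latent_factors < 1:
            raise ConfigurationError("n_variants, exposures and factors must be >= 1")
        unknown = set(self.causal_set) - set(self.exposures)
        if unknown:
            raise ConfigurationError(f"causal_set names unknown exposures: {sorted(unknown)}")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ConfigurationError("maf_range must lie within (0, 0.5]")
        if abs(self.ld_rho) >= 1.0:
            raise ConfigurationError("|ld_rho| must be < 1")
        if self.ld_block_size < 1 or self.ld_block_size > self.n_variants:
            raise ConfigurationError("ld_block_size must be in [1, n_variants]")
        if not (0.0 <= self.pleiotropy_frac <= 1.0):
            raise ConfigurationError("pleiotropy_frac must be in [0, 1]")

    @property
    def n_exposures(self) -> int:
        return len(self.exposures)

    @property
    def theta_true(self) -> np.ndarray:
        return np.array([self.causal_set.get(e, 0.0) for e in self.exposures])

    @property
    def n_eff_outcome(self) -> float:
        return 4.0 / (1.0 / self.n_outcome_cases + 1.0 / self.n_outcome_controls)


@dataclass
class SyntheticTruth:
    """Ground truth of one simulated panel, for recovery testing."""

    exposures: list[str]
    theta_true: np.ndarray  # (K,) causal effect per exposure (log-odds per SD)
    alpha: np.ndarray  # (J,) direct variant->outcome effects (pleiotropy)
    bX_true: np.ndarray  # (J, K) noiseless exposure associations
    bY_true: np.ndarray  # (J,) noiseless outcome associations
    exposure_correlation: np.ndarray  # (K, K) factor-implied correlation of bX columns
    maf: np.ndarray
    seed: int


def _factor_implied_correlation(Gamma: np.ndarray, s2_load: float, s2_unique: float) -> np.ndarray:
    """Correlation across exposure columns implied by one-factor-per-variant loadings."""
    F = Gamma.shape[1]
    cov = (s2_load / F) * (Gamma @ Gamma.T) + s2_unique * np.eye(Gamma.shape[0])
    d = np.sqrt(np.diag(cov))
    return cov / np.outer(d, d)


def _block_ld(J: int, block: int, rho: float) -> np.ndarray:
    """Block-diagonal LD with AR(1) decay r_{ij} = rho^|i-j| inside blocks."""
    R = np.eye(J)
    if block > 1 and rho != 0.0:
        for start in range(0, J, block):
            stop = min(start + block, J)
            idx = np.arange(start, stop)
            R[np.ix_(idx, idx)] = rho ** np.abs(idx[:, None] - idx[None, :])
    return R


def _gamma_matrix(K: int, F: int, rng: np.random.Generator) -> np.ndarray:
    """Exposure-on-factor loading pattern: each exposure loads ~1 on one
    primary factor and 0.3-0.7 on the others, giving lipid-like cross-trait
    genetic correlations in the 0.3-0.8 range."""
    Gamma = 0.3 + 0.4 * rng.random((K, F))
    for k in range(K):
        Gamma[k, k % F] = 1.0
    return Gamma


def simulate_panel(config: SyntheticConfig) -> tuple[HarmonizedPanel, LDMatrix, SyntheticTruth]:
    """Draw one synthetic harmonized panel plus its LD matrix and ground truth."""
    rng = np.random.default_rng(config.seed)
    J, K, F = config.n_variants, config.n_exposures, config.n_latent_factors

    maf = rng.uniform(*config.maf_range, size=J)
    var_g = 2.0 * maf * (1.0 - maf)
    seX_col = 1.0 / np.sqrt(var_g * config.n_exposure_gwas)
    seY = 1.0 / np.sqrt(var_g * config.n_eff_outcome)
    seX = np.repeat(seX_col[:, None], K, axis=1)

    # sparse loadings: each variant drives exactly one latent factor
    Gamma = _gamma_matrix(K, F, rng)
    factor_of = rng.integers(0, F, size=J)
    load = rng.normal(0.0, config.loading_scale, size=J)
    Lambda = np.zeros((J, F))
    Lambda[np.arange(J), factor_of] = load
    s_unique = config.unique_frac * config.loading_scale
    E = rng.normal(0.0, s_unique, size=(J, K))
    bX_true = Lambda @ Gamma.T + E

    theta = config.theta_true
    alpha = np.zeros(J)
    if config.pleiotropy_frac > 0:
        n_pleio = int(round(config.pleiotropy_frac * J))
        which = rng.choice(J, size=n_pleio, replace=False)
        alpha[which] = rng.normal(config.pleiotropy_mean, config.pleiotropy_sd, size=n_pleio)
    bY_true = bX_true @ theta + alpha

    R = _block_ld(J, config.ld_block_size, config.ld_rho)
    ids = [f"rs{i + 1}" for i in range(J)]
    ld = LDMatrix(ids, R)

    if config.correlated_noise and (config.ld_block_size > 1 and config.ld_rho != 0.0):
        chol = np.linalg.cholesky(ld.r)
        noiseX = np.stack([chol @ rng.standard_normal(J) for _ in range(K)], axis=1) * seX
        noiseY = (chol @ rng.standard_normal(J)) * seY
    else:
        noiseX = rng.standard_normal((J, K)) * seX
        noiseY = rng.standard_normal(J) * seY

    bX = bX_true + noiseX
    bY = bY_true + noiseY
    pX = 2.0 * stats.norm.sf(np.abs(bX / seX))

    block = config.ld_block_size
    panel = HarmonizedPanel(
        variant_ids=ids,
        exposure_names=list(config.exposures),
        bX=bX,
        seX=seX,
        bY=bY,
        seY=seY,
        pX=pX,
        chrom=["1"] * J,
        pos=np.arange(1, J + 1) * 10_000,
        outcome_name="outcome",
    )
    truth = SyntheticTruth(
        exposures=list(config.exposures),
        theta_true=theta,
        alpha=alpha,
        bX_true=bX_true,
        bY_true=bY_true,
        exposure_correlation=_factor_implied_correlation(
            Gamma, config.loading_scale**2, s_unique**2
        ),
        maf=maf,
        seed=config.seed,
    )
    return panel, ld, truth


def preset_config(name: str, seed: int = 0, **overrides) -> SyntheticConfig:
    """Named study conditions.

    ``major-lipids``: K=5 lipoprotein traits, 2 latent factors, ApoB causal.
    ``subfractions``: K=10 ApoB-containing particle concentrations, 3
    factors, XS.VLDL.P causal. ``lpa``: 15 locus-concentrated Lp(a)
    instruments plus an ApoB column for multivariable adjustment.
    """
    if name == "major-lipids":
        cfg = SyntheticConfig(seed=seed)
    elif name == "subfractions":
        cfg = SyntheticConfig(
            exposures=list(SUBFRACTIONS),
            n_latent_factors=3,
            causal_set={"XS.VLDL.P": 0.14},
            seed=seed,
        )
    elif name == "lpa":
        cfg = SyntheticConfig(
            n_variants=15,
            exposures=["Lpa", "ApoB"],
            n_latent_factors=2,
            loading_scale=0.25,  # LPA-locus variants explain >40% of Lp(a) variance
            unique_frac=0.3,
            causal_set={"Lpa": 0.12},
            seed=seed,
        )
    else:
        raise ConfigurationError(f"unknown preset {name!r}")
    return replace(cfg, **overrides) if overrides else cfg


# ---------------------------------------------------------------------------
# TWAS fixture
# ---------------------------------------------------------------------------


@dataclass
class TwasTruth:
    """Designed gene-level effects behind a simulated TWAS fixture."""

    genes: list[str]
    effect_a: dict[str, float]  # nonzero designed effects on trait A
    effect_b: dict[str, float]
    seed: int

    @property
    def unique_a(self) -> set[str]:
        return set(self.effect_a) - set(self.effect_b)

    @property
    def unique_b(self) -> set[str]:
        return set(self.effect_b) - set(self.effect_a)

    @property
    def shared(self) -> set[str]:
        return set(self.effect_a) & set(self.effect_b)


def simulate_twas_fixture(
    n_genes: int = 200,
    variants_per_gene: int = 5,
    weight_sparsity: float = 0.6,
    effect_genes_a: dict[str, float] | int = 0,
    effect_genes_b: dict[str, float] | int | None = None,
    effect_size: float = 8.0,
    effect_corr: float | None = None,
    effect_scale: float = 5.0,
    ld_rho: float = 0.3,
    seed: int = 0,
):
    """Simulate per-gene eQTL weight models and trait GWAS Z-scores.

    Each gene has ``variants_per_gene`` cis variants with a sparse weight
    vector and AR(1) LD. Under the null the variant Z-vector for a trait is
    N(0, R), so the gene's TWAS Z is standard normal. A designed effect
    ``mu`` for gene g shifts the variant Z-vector by ``mu * R S w / sigma_g``
    so the gene-level Z has mean exactly ``mu``.

    ``effect_genes_a/b`` may be an int (that many genes given effect
    ``effect_size``; b reuses a's genes when None) or an explicit
    gene->effect mapping. Alternatively ``effect_corr`` draws every gene's
    latent effect pair from a bivariate normal scaled by ``effect_scale``,
    with the latent correlation chosen so the correlation of the resulting
    Z-scores (signal plus unit noise) equals ``effect_corr``.

    Returns ``(models, gwas_a, gwas_b, truth)`` where ``models`` is a list
    of dicts (gene, variant_ids, weights, eaf, ld) and each gwas maps
    variant_id -> Z.
    """
    from .twas import TwasWeightModel  # local import to avoid a cycle

    rng = np.random.default_rng(seed)
    genes = [f"GENE{i + 1:03d}" for i in range(n_genes)]

    if effect_corr is not None:
        s2 = effect_scale**2
        rho_latent = effect_corr * (s2 + 1.0) / s2
        if not (-1.0 <= rho_latent <= 1.0):
            raise ConfigurationError(
                "effect_corr unreachable at this effect_scale; increase effect_scale"
            )
        cov = s2 * np.array([[1.0, rho_latent], [rho_latent, 1.0]])
        eff = rng.multivariate_normal([0.0, 0.0], cov, size=n_genes)
        effect_a = {g: float(eff[i, 0]) for i, g in enumerate(genes)}
        effect_b = {g: float(eff[i, 1]) for i, g in enumerate(genes)}
    else:
        def _as_map(spec, pool):
            if isinstance(spec, dict):
                bad = set(spec) - set(genes)
                if bad:
                    raise ConfigurationError(f"effect genes not in fixture: {sorted(bad)}")
                return dict(spec)
            return {g: effect_size for g in pool[: int(spec)]}

        effect_a = _as_map(effect_genes_a, genes)
        effect_b = _as_map(
            effect_genes_a if effect_genes_b is None else effect_genes_b, genes
        )

    models: list[TwasWeightModel] = []
    gwas_a: dict[str, float] = {}
    gwas_b: dict[str, float] = {}
    m = variants_per_gene
    for gi, gene in enumerate(genes):
        vids = [f"{gene}_v{j + 1}" for j in range(m)]
        w = rng.normal(0.0, 1.0, size=m)
        keep = rng.random(m) < weight_sparsity
        if not keep.any():
            keep[rng.integers(0, m)] = True
        w = np.where(keep, w, 0.0)
        eaf = rng.uniform(0.1, 0.5, size=m)
        idx = np.arange(m)
        R = ld_rho ** np.abs(idx[:, None] - idx[None, :]) if ld_rho else np.eye(m)
        ld = LDMatrix(vids, R)
        model = TwasWeightModel(gene=gene, variant_ids=vids, weights=w, eaf=eaf, ld_ref=ld)

        S = np.diag(np.sqrt(2.0 * eaf * (1.0 - eaf)))
        sw = S @ w
        sigma_g = float(np.sqrt(sw @ ld.r @ sw))
        chol = np.linalg.cholesky(ld.r)
        direction = ld.r @ sw / sigma_g
        for gwas, effects in ((gwas_a, effect_a), (gwas_b, effect_b)):
            z0 = chol @ rng.standard_normal(m)
            mu = effects.get(gene, 0.0)
            z = z0 + mu * direction
            for vid, zv in zip(vids, z):
                gwas[vid] = float(zv)
        models.append(model)

    truth = TwasTruth(
        genes=genes,
        effect_a={g: v for g, v in effect_a.items() if v != 0.0},
        effect_b={g: v for g, v in effect_b.items() if v != 0.0},
        seed=seed,
    )
    return models, gwas_a, gwas_b, truth


# ---------------------------------------------------------------------------
# Gene-region (drug-target) study fixture
# ---------------------------------------------------------------------------


def simulate_gene_region_study(
    genes: list[str] | None = None,
    variants_per_region: int = 10,
    theta: dict[str, float] | None = None,
    n_exposure_gwas: float = 24_925,
    n_cases: float = 31_307,
    n_controls: float = 211_753,
    ld_rho: float = 0.5,
    flank_bp: int = 200_000,
    seed: int = 0,
):
    """Simulate a cis drug-target MR study across gene regions.

    Each gene occupies its own chromosome with a 50 kb body; its cis window
    (body +/- ``flank_bp``) holds ``variants_per_region`` variants with AR(1)
    LD of parameter ``ld_rho``. Joint exposure effects are sparse within the
    region (two causal variants) and marginal effects are ``R @ gamma``, so
    correlated variants show correlated associations as in real cis data.
    Outcome associations are ``theta_outcome * bX`` plus LD-correlated
    estimation noise; exposure sample size defaults to an NMR-metabolite
    GWAS scale, the outcome to a large case-control GWAS.

    Returns ``(exposure_set, outcome_sets, regions, ld, truth)`` where
    ``truth`` maps each outcome to its causal effect per 1-SD exposure
    increase.
    """
    from .containers import GeneRegion, SummaryStatSet, VariantAssociation

    genes = genes if genes is not None else ["APOB", "LDLR", "PCSK9", "HMGCR", "NPC1L1", "CETP"]
    theta = theta if theta is not None else {"PAD": 0.14, "CAD": 0.42}
    rng = np.random.default_rng(seed)

    n_eff = 4.0 / (1.0 / n_cases + 1.0 / n_controls)
    all_ids: list[str] = []
    blocks: list[np.ndarray] = []
    exposure_recs: list[VariantAssociation] = []
    outcome_recs: dict[str, list[VariantAssociation]] = {o: [] for o in theta}
    regions: list[GeneRegion] = []
    alleles = np.array(list("ACGT"))

    for g_idx, gene in enumerate(genes):
        chrom = str(g_idx + 1)
        body_start, body_end = 1_000_000, 1_050_000
        regions.append(GeneRegion(gene, chrom, body_start, body_end, flank_bp))
        m = variants_per_region
        lo, hi = body_start - flank_bp, body_end + flank_bp
        pos = np.sort(rng.integers(lo, hi + 1, size=m))
        ids = [f"{gene}_rs{j + 1}" for j in range(m)]
        idx = np.arange(m)
        R = ld_rho ** np.abs(idx[:, None] - idx[None, :])
        blocks.append(R)
        all_ids.extend(ids)

        maf = rng.uniform(0.1, 0.5, size=m)
        var_g = 2.0 * maf * (1.0 - maf)
        seX = 1.0 / np.sqrt(var_g * n_exposure_gwas)
        seY = 1.0 / np.sqrt(var_g * n_eff)

        gamma = np.zeros(m)
        causal = rng.choice(m, size=2, replace=False)
        gamma[causal] = rng.choice([-1.0, 1.0], size=2) * rng.uniform(0.08, 0.15, size=2)
        bX_true = R @ gamma
        chol = np.linalg.cholesky(R + 1e-10 * np.eye(m))
        bX = bX_true + (chol @ rng.standard_normal(m)) * seX

        ea_idx = rng.integers(0, 4, size=m)
        oa_idx = (ea_idx + rng.integers(1, 4, size=m)) % 4
        pvals = 2.0 * stats.norm.sf(np.abs(bX / seX))
        for j in range(m):
            exposure_recs.append(
                VariantAssociation(
                    variant_id=ids[j], effect_allele=alleles[ea_idx[j]],
                    other_allele=alleles[oa_idx[j]], beta=float(bX[j]),
                    se=float(seX[j]), chrom=chrom, pos=int(pos[j]),
                    eaf=float(maf[j]), pvalue=float(max(pvals[j], 1e-300)),
                    n=n_exposure_gwas,
                )
            )
        for outcome, th in theta.items():
            bY = th * bX_true + (chol @ rng.standard_normal(m)) * seY
            for j in range(m):
                outcome_recs[outcome].append(
                    VariantAssociation(
                        variant_id=ids[j], effect_allele=alleles[ea_idx[j]],
                        other_allele=alleles[oa_idx[j]], beta=float(bY[j]),
                        se=float(seY[j]), chrom=chrom, pos=int(pos[j]),
                        eaf=float(maf[j]),
                        pvalue=float(max(2.0 * stats.norm.sf(abs(bY[j] / seY[j])), 1e-300)),
                        n=n_cases + n_controls,
                    )
                )

    from scipy.linalg import block_diag

    ld = LDMatrix(all_ids, block_diag(*blocks))
    exposure_set = SummaryStatSet("ApoB", "quantitative", exposure_recs)
    outcome_sets = {
        o: SummaryStatSet(o, "binary", recs) for o, recs in outcome_recs.items()
    }
    return exposure_set, outcome_sets, regions, ld, dict(theta)
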