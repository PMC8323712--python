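"""Bayesian model averaging over multivariable MR models (MR-BMA).

Ranks K correlated exposures by marginal inclusion probability (MIP): the
posterior probability, summed over all candidate causal models containing
an exposure, that it belongs to the true causal model. The working model is
the IVW-standardized linear system

    y_j = bY_j / seY_j,   X_jk = bX_jk / seY_j  (columns then unit-norm),
    y = X_S theta_S + eps,  eps ~ N(0, I),  theta_S ~ N(0, sigma_prior^2 I),

whose Gaussian marginal likelihood is available in closed form per exposure
subset S. Model priors are independent-inclusion Bernoulli(prior_inclusion);
the null model is excluded from enumeration (the method ranks causal
candidates; the exclusion rescales all posteriors equally and leaves the
MIP ordering unchanged).

Empirical p-values come from a permutation scheme that permutes the
(bY, seY) pairs jointly across variants — breaking the exposure-outcome
linkage while preserving both the exposure correlation structure and the
outcome SE distribution — and recomputes each exposure's MIP. Multiplicity
is handled either by Benjamini-Hochberg over the permutation p-values or by
the Nyholt effective-tests adjustment for strongly correlated traits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .containers import ConfigurationError, DataError, HarmonizedPanel
from .stats_util import bh_fdr, nyholt_adjust, nyholt_meff


@dataclass
class BMAConfig:
    """Hyperparameters of one MR-BMA run."""

    sigma_prior: float = 0.5
    prior_inclusion: float = 0.1
    max_model_size: int | None = None  # None -> K
    n_permutations: int = 1000
    seed: int = 0
    correction: str = "perm-fdr"  # "perm-fdr" | "nyholt"
    cooks_threshold: float | None = None  # None -> 4/J
    q_outlier_threshold: float = 0.05

    def __post_init__(self) -> None:
        if self.sigma_prior <= 0:
            raise ConfigurationError("sigma_prior must be > 0")
        if not (0.0 < self.prior_inclusion < 1.0):
            raise ConfigurationError("prior_inclusion must lie in (0,1)")
        if self.correction not in ("perm-fdr", "nyholt"):
            raise ConfigurationError("correction must be perm-fdr|nyholt")


@dataclass
class MRBMAResult:
    """Full output of an MR-BMA run."""

    exposures: list[str]
    models: list[tuple[tuple[str, ...], float, float]]  # (subset, log evidence, posterior)
    mip: dict[str, float]
    mace: dict[str, float]
    p_perm: dict[str, float] | None
    q_corrected: dict[str, float] | None
    correction: str | None
    diagnostics: pd.DataFrame | None
    seed: int
    table: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def top_exposure(self) -> str:
        return self.table.iloc[0]["exposure"]

    @property
    def top_model(self) -> tuple[str, ...]:
        best = max(self.models, key=lambda m: m[2])
        return best[0]


def standardize_panel(panel: HarmonizedPanel) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """IVW standardization followed by unit-norm column scaling.

    Returns ``(y, X, scale)`` with ``y_j = bY_j/seY_j``,
    ``X_jk = (bX_jk/seY_j) / scale_k`` and ``scale_k`` the Euclidean norm of
    the IVW-weighted exposure column (kept for back-transforming effects to
    per-SD units).
    """
    y = panel.bY / panel.seY
    X = panel.bX / panel.seY[:, None]
    scale = np.linalg.norm(X, axis=0)
    zero = np.flatnonzero(scale == 0.0)
    if zero.size:
        names = [panel.exposure_names[k] for k in zero]
        raise DataError(f"zero-norm exposure column(s): {names}")
    return y, X / scale, scale


def _enumerate_subsets(K: int, max_size: int) -> list[tuple[int, ...]]:
    return [
        s for size in range(1, max_size + 1) for s in combinations(range(K), size)
    ]


def model_log_evidence(y: np.ndarray, X_S: np.ndarray, sigma_prior: float) -> float:
    """Closed-form log marginal likelihood of one candidate model.

    logML = -J/2 log(2 pi) - 1/2 logdet(I + s^2 X X') - 1/2 y'(I + s^2 X X')^-1 y,
    evaluated via the Woodbury identity on the |S| x |S| Gram matrix.
    """
    X_S = np.atleast_2d(np.asarray(X_S, dtype=float))
    if X_S.ndim == 2 and X_S.shape[0] == 1 and y.shape[0] != 1:
        X_S = X_S.T
    G = X_S.T @ X_S
    b = X_S.T @ y
    val = _log_evidence_from_gram(G, b, float(y @ y), len(y), sigma_prior)[0]
    if not np.isfinite(val):
        raise DataError("non-finite model evidence")
    return val


def _log_evidence_from_gram(
    G: np.ndarray, b: np.ndarray, yy: float, J: int, sigma_prior: float
) -> tuple[float, np.ndarray]:
    """(logML, posterior-mean theta) from the subset Gram matrix and X'y."""
    s2 = sigma_prior**2
    p = G.shape[0]
    A = G + np.eye(p) / s2  # = (X'X + I/s^2)
    chol = np.linalg.cholesky(A)
    u = np.linalg.solve(chol, b)
    theta = np.linalg.solve(chol.T, u)
    # logdet(I_p + s^2 G) = logdet(A) + p log s^2
    logdet = 2.0 * np.log(np.diag(chol)).sum() + p * np.log(s2)
    quad = yy - u @ u
    logml = -0.5 * (J * np.log(2.0 * np.pi) + logdet + quad)
    return float(logml), theta


def _bma_core(
    y: np.ndarray,
    X: np.ndarray,
    sigma_prior: float,
    prior_inclusion: float,
    subsets: list[tuple[int, ...]],
    want_effects: bool = False,
):
    """Enumerate models over a standardized design; returns posterior pieces."""
    J, K = X.shape
    G = X.T @ X
    bXy = X.T @ y
    yy = float(y @ y)
    log_ev = np.empty(len(subsets))
    thetas: list[np.ndarray] = []
    for i, S in enumerate(subsets):
        idx = np.array(S)
        lm, th = _log_evidence_from_gram(
            G[np.ix_(idx, idx)], bXy[idx], yy, J, sigma_prior
        )
        log_ev[i] = lm
        if want_effects:
            thetas.append(th)
    sizes = np.array([len(S) for S in subsets])
    log_prior = sizes * np.log(prior_inclusion) + (K - sizes) * np.log(1.0 - prior_inclusion)
    log_post = log_ev + log_prior
    log_post -= log_post.max()
    post = np.exp(log_post)
    post /= post.sum()
    mip = np.zeros(K)
    mace = np.zeros(K)
    for i, S in enumerate(subsets):
        for pos, k in enumerate(S):
            mip[k] += post[i]
            if want_effects:
                mace[k] += post[i] * thetas[i][pos]
    return log_ev, post, mip, mace


def run_mr_bma(
    panel: HarmonizedPanel,
    config: BMAConfig | None = None,
    with_permutation: bool = False,
) -> MRBMAResult:
    """Exhaustive model averaging over exposure subsets.

    Instruments are assumed approximately independent (LD-pruned panels);
    enumeration is exhaustive and limited to K <= 20 exposures.
    ``with_permutation`` additionally computes permutation p-values and the
    configured multiplicity correction.
    """
    config = config or BMAConfig()
    K = panel.n_exposures
    if K > 20:
        raise ConfigurationError(
            "K > 20: exhaustive enumeration is impractical; reduce exposures "
            "or lower max_model_size"
        )
    max_size = config.max_model_size or K
    if not (1 <= max_size <= K):
        raise ConfigurationError("max_model_size must lie in [1, K]")

    y, X, scale = standardize_panel(panel)
    subsets = _enumerate_subsets(K, max_size)
    log_ev, post, mip, mace_std = _bma_core(
        y, X, config.sigma_prior, config.prior_inclusion, subsets, want_effects=True
    )
    mace = mace_std / scale  # back to per-SD units

    names = panel.exposure_names
    models = [
        (tuple(names[k] for k in S), float(le), float(po))
        for S, le, po in zip(subsets, log_ev, post)
    ]

    p_perm = q_corr = None
    correction = None
    if with_permutation:
        p_arr = _permutation_mips(panel, config, subsets, mip)
        p_perm = dict(zip(names, p_arr))
        if config.correction == "perm-fdr":
            q_arr = bh_fdr(p_arr)
        else:
            meff = nyholt_meff(np.corrcoef(panel.bX, rowvar=False))
            q_arr = nyholt_adjust(p_arr, meff)
        q_corr = dict(zip(names, q_arr))
        correction = config.correction

    table = pd.DataFrame(
        {
            "exposure": names,
            "MIP": mip,
            "MACE": mace,
            "p_uncorrected": [p_perm[n] for n in names] if p_perm else np.nan,
            "p_corrected": [q_corr[n] for n in names] if q_corr else np.nan,
        }
    )
    sort_p = table["p_uncorrected"].fillna(1.0)
    table = (
        table.assign(_p=sort_p)
        .sort_values(["MIP", "_p", "exposure"], ascending=[False, True, True])
        .drop(columns="_p")
        .reset_index(drop=True)
    )

    result = MRBMAResult(
        exposures=list(names),
        models=models,
        mip=dict(zip(names, mip)),
        mace=dict(zip(names, mace)),
        p_perm=p_perm,
        q_corrected=q_corr,
        correction=correction,
        diagnostics=None,
        seed=config.seed,
        table=table,
    )
    result.diagnostics = influence_diagnostics(panel, result.top_model, config)
    return result


def _permutation_mips(
    panel: HarmonizedPanel,
    config: BMAConfig,
    subsets: list[tuple[int, ...]],
    observed_mip: np.ndarray,
) -> np.ndarray:
    """Empirical per-exposure p-values for the observed MIPs."""
    if config.n_permutations < 100:
        raise ConfigurationError("n_permutations must be >= 100")
    rng = np.random.default_rng(config.seed)
    J = panel.n_variants
    count = np.zeros(panel.n_exposures)
    for _ in range(config.n_permutations):
        perm = rng.permutation(J)
        bY, seY = panel.bY[perm], panel.seY[perm]
        y = bY / seY
        X = panel.bX / seY[:, None]
        norms = np.linalg.norm(X, axis=0)
        X = X / norms
        _, _, mip, _ = _bma_core(
            y, X, config.sigma_prior, config.prior_inclusion, subsets
        )
        count += mip >= observed_mip - 1e-12
    return (1.0 + count) / (config.n_permutations + 1.0)


def permutation_pvalues(
    panel: HarmonizedPanel, config: BMAConfig | None = None
) -> tuple[dict[str, float], dict[str, float]]:
    """Permutation p-values and their BH q-values for each exposure's MIP."""
    config = config or BMAConfig()
    max_size = config.max_model_size or panel.n_exposures
    subsets = _enumerate_subsets(panel.n_exposures, max_size)
    y, X, _ = standardize_panel(panel)
    _, _, mip, _ = _bma_core(y, X, config.sigma_prior, config.prior_inclusion, subsets)
    p_arr = _permutation_mips(panel, config, subsets, mip)
    q_arr = bh_fdr(p_arr)
    names = panel.exposure_names
    return dict(zip(names, p_arr)), dict(zip(names, q_arr))


def influence_diagnostics(
    panel: HarmonizedPanel,
    top_model: tuple[str, ...],
    config: BMAConfig | None = None,
) -> pd.DataFrame:
    """Per-variant Cook's distance and heterogeneity contribution.

    Computed from the weighted least-squares fit of the top model on the
    IVW-standardized design; variants exceeding the Cook's threshold
    (default 4/J) are flagged for a refit-without-outliers sensitivity run.
    """
    config = config or BMAConfig()
    y, X, _ = standardize_panel(panel)
    cols = [panel.exposure_index(name) for name in top_model]
    Xs = X[:, cols]
    J, p = Xs.shape
    XtX_inv = np.linalg.pinv(Xs.T @ Xs)
    H = Xs @ XtX_inv @ Xs.T
    h = np.clip(np.diag(H), 0.0, 1.0 - 1e-12)
    resid = y - H @ y
    dof = max(J - p, 1)
    s2 = float(resid @ resid) / dof
    cooks = resid**2 * h / (s2 * p * (1.0 - h) ** 2) if s2 > 0 else np.zeros(J)
    q_contrib = resid**2  # squared standardized residual (unit error variance)
    threshold = config.cooks_threshold if config.cooks_threshold is not None else 4.0 / J
    return pd.DataFrame(
        {
            "variant_id": panel.variant_ids,
            "cooks_distance": cooks,
            "q_contribution": q_contrib,
            "leverage": h,
            "outlier_flag": cooks > threshold,
        }
    )
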