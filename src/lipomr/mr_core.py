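"""Univariable and multivariable MR estimators on summary statistics.

All estimators are generalized weighted least squares of the variant-outcome
associations ``bY`` on the variant-exposure associations ``bX`` with weight
matrix ``inv(Omega)``, ``Omega = D R D`` where ``D = diag(seY)`` and ``R``
is the LD correlation among instruments (identity when instruments are
independent). With identity LD this reduces to the classical
inverse-variance weighted (IVW) estimator.

Random-effects standard errors inflate the fixed-effects SE by
``max(1, sqrt(Q / dof))`` where ``Q`` is the GLS residual chi-square under
the fixed-effects fit — a multiplicative overdispersion model bounded below
at the fixed-effects SE. p-values use the normal distribution, the
summary-data MR convention.
"""

from __future__ import annotations

import numpy as np
from scipy import linalg, stats

from .containers import (
    ConfigurationError,
    DataError,
    HarmonizedPanel,
    LDMatrix,
    MREstimate,
)

_Z95 = stats.norm.ppf(0.975)


def _normal_p(z: float) -> float:
    return float(2.0 * stats.norm.sf(abs(z)))


def _estimate(method, exposure, theta, se, J, Q=None, **kw) -> MREstimate:
    z = theta / se if se > 0 else np.inf * np.sign(theta)
    return MREstimate(
        method=method,
        exposure=exposure,
        theta=float(theta),
        se=float(se),
        ci_low=float(theta - _Z95 * se),
        ci_high=float(theta + _Z95 * se),
        pvalue=_normal_p(z) if np.isfinite(z) else 0.0,
        n_variants=J,
        Q=None if Q is None else float(Q),
        **kw,
    )


def wald_ratio(bx: float, sex: float, by: float, sey: float, exposure: str = "exposure") -> MREstimate:
    """Single-variant causal estimate ``by/bx`` with first-order SE ``|sey/bx|``."""
    if bx == 0:
        raise DataError("Wald ratio undefined: variant-exposure association is zero")
    theta = by / bx
    se = abs(sey / bx)
    return _estimate("wald", exposure, theta, se, J=1)


def _omega_chol(seY: np.ndarray, ld: LDMatrix | None, variant_ids: list[str]):
    """Cholesky factor of Omega = D R D (lower), or None for identity R."""
    if ld is None:
        return None
    R = ld.subset(list(variant_ids)).r
    omega = R * np.outer(seY, seY)
    try:
        return linalg.cholesky(omega, lower=True)
    except linalg.LinAlgError as exc:
        raise DataError(
            "singular weight matrix Omega; regularize the LD matrix"
        ) from exc


def _gls_fit(X: np.ndarray, y: np.ndarray, seY: np.ndarray, chol) -> tuple[np.ndarray, np.ndarray, float]:
    """GLS of y on X with Omega = D R D. Returns (coef, cov_fixed, Q)."""
    if chol is None:
        Xw = X / seY[:, None]
        yw = y / seY
    else:
        Xw = linalg.solve_triangular(chol, X, lower=True)
        yw = linalg.solve_triangular(chol, y, lower=True)
    XtX = Xw.T @ Xw
    Xty = Xw.T @ yw
    try:
        cov = linalg.inv(XtX)
    except linalg.LinAlgError as exc:
        raise DataError("design is singular (collinear exposures?)") from exc
    coef = cov @ Xty
    resid = yw - Xw @ coef
    Q = float(resid @ resid)
    return coef, cov, Q


def ivw(
    panel: HarmonizedPanel,
    ld: LDMatrix | None = None,
    effects: str = "random",
    exposure: str | None = None,
) -> MREstimate:
    """Inverse-variance weighted causal estimate for a single exposure.

    With ``ld`` supplied, instruments may be correlated and the weight
    matrix accounts for their LD (GLS-IVW); with ``ld=None`` instruments
    are treated as independent and the classical IVW formula is recovered.
    """
    if exposure is None:
        if panel.n_exposures != 1:
            raise ConfigurationError("ivw requires K=1 or an explicit exposure name")
        exposure = panel.exposure_names[0]
    k = panel.exposure_index(exposure)
    bx = panel.bX[:, k]
    J = panel.n_variants
    if effects == "random" and J < 2:
        raise ConfigurationError("random-effects IVW requires J >= 2")
    if effects not in ("fixed", "random"):
        raise ConfigurationError(f"effects must be fixed|random, got {effects!r}")
    if J == 1:
        return wald_ratio(bx[0], panel.seX[0, k], panel.bY[0], panel.seY[0], exposure)

    chol = _omega_chol(panel.seY, ld, panel.variant_ids)
    coef, cov, Q = _gls_fit(bx[:, None], panel.bY, panel.seY, chol)
    se = float(np.sqrt(cov[0, 0]))
    if effects == "random":
        se *= max(1.0, np.sqrt(Q / (J - 1)))
    return _estimate(f"ivw_{effects}", exposure, coef[0], se, J, Q=Q)


def mr_egger(
    panel: HarmonizedPanel,
    ld: LDMatrix | None = None,
    effects: str = "random",
    exposure: str | None = None,
) -> MREstimate:
    """MR-Egger regression: slope = causal effect, intercept = average
    directional pleiotropy.

    Each variant is first oriented so its exposure association is
    non-negative (the row's signs flip jointly across bX and bY), the
    standard convention that makes the intercept interpretable.
    """
    if exposure is None:
        if panel.n_exposures != 1:
            raise ConfigurationError("mr_egger requires K=1 or an explicit exposure name")
        exposure = panel.exposure_names[0]
    k = panel.exposure_index(exposure)
    J = panel.n_variants
    if J < 3:
        raise ConfigurationError("MR-Egger requires J >= 3 instruments")

    flip = np.where(panel.bX[:, k] < 0, -1.0, 1.0)
    bx = panel.bX[:, k] * flip
    by = panel.bY * flip
    if np.ptp(bx) < 1e-12 * max(1.0, np.abs(bx).max()):
        raise DataError(
            "degenerate Egger design: all exposure associations equal "
            "(collinear with the intercept)"
        )

    # orientation flips rows of bY; Omega is sign-symmetric: D R' D with
    # R'_ij = f_i f_j R_ij
    if ld is None:
        chol = None
    else:
        R = ld.subset(panel.variant_ids).r * np.outer(flip, flip)
        chol = _omega_chol(panel.seY, LDMatrix(panel.variant_ids, R), panel.variant_ids)

    X = np.column_stack([np.ones(J), bx])
    coef, cov, Q = _gls_fit(X, by, panel.seY, chol)
    infl = max(1.0, np.sqrt(Q / (J - 2))) if effects == "random" else 1.0
    se_slope = float(np.sqrt(cov[1, 1])) * infl
    se_int = float(np.sqrt(cov[0, 0])) * infl
    return _estimate(
        "egger_slope",
        exposure,
        coef[1],
        se_slope,
        J,
        Q=Q,
        egger_intercept=float(coef[0]),
        egger_intercept_se=se_int,
        egger_intercept_p=_normal_p(coef[0] / se_int),
    )


def mvmr(
    panel: HarmonizedPanel,
    ld: LDMatrix | None = None,
    effects: str = "random",
) -> list[MREstimate]:
    """Multivariable MR: direct effect of each exposure conditional on the rest."""
    J, K = panel.n_variants, panel.n_exposures
    if K < 2:
        return [ivw(panel, ld=ld, effects=effects)]
    if J <= K:
        raise ConfigurationError(f"multivariable MR requires J > K (J={J}, K={K})")

    zero_cols = np.flatnonzero((panel.bX == 0).all(axis=0))
    active = [k for k in range(K) if k not in zero_cols]
    X = panel.bX[:, active]
    corr = np.corrcoef(X, rowvar=False) if len(active) > 1 else np.ones((1, 1))
    bad = [
        (panel.exposure_names[active[i]], panel.exposure_names[active[j]])
        for i in range(len(active))
        for j in range(i + 1, len(active))
        if abs(corr[i, j]) > 0.999
    ]
    if bad:
        raise DataError(f"collinear exposures (|r| > 0.999): {bad}")

    chol = _omega_chol(panel.seY, ld, panel.variant_ids)
    coef, cov, Q = _gls_fit(X, panel.bY, panel.seY, chol)
    dof = max(1, J - len(active))
    infl = max(1.0, np.sqrt(Q / dof)) if effects == "random" else 1.0

    out: list[MREstimate] = []
    pos = {k: i for i, k in enumerate(active)}
    for k, name in enumerate(panel.exposure_names):
        if k in pos:
            i = pos[k]
            se = float(np.sqrt(cov[i, i])) * infl
            out.append(_estimate("mvmr", name, coef[i], se, J, Q=Q))
        else:
            out.append(
                MREstimate(
                    method="mvmr",
                    exposure=name,
                    theta=0.0,
                    se=np.inf,
                    ci_low=-np.inf,
                    ci_high=np.inf,
                    pvalue=1.0,
                    n_variants=J,
                    Q=Q,
                    degenerate=True,
                )
            )
    return out
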