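"""Multiplicity corrections shared across analysis stages."""

from __future__ import annotations

import numpy as np
from statsmodels.stats.multitest import multipletests

from .containers import ConfigurationError, DataError


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if ((p <= 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise DataError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def nyholt_meff(trait_correlation) -> float:
    """Effective number of independent tests among correlated traits.

    Eigenvalue-based estimate: Meff = 1 + (K-1) * (1 - Var(lambda)/K) with
    Var the sample variance (ddof=1) of the K eigenvalues of the trait
    correlation matrix. Identity correlation gives Meff = K; a rank-one
    (perfectly correlated) matrix gives Meff = 1.
    """
    C = np.asarray(trait_correlation, dtype=float)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise ConfigurationError("trait correlation must be square")
    if not np.allclose(C, C.T, atol=1e-8):
        raise DataError("trait correlation must be symmetric")
    K = C.shape[0]
    if K == 1:
        return 1.0
    lam = np.linalg.eigvalsh(C)
    meff = 1.0 + (K - 1) * (1.0 - np.var(lam, ddof=1) / K)
    return float(np.clip(meff, 1.0, K))


def nyholt_adjust(pvalues, meff: float) -> np.ndarray:
    """Sidak-free Nyholt adjustment: p_adj = min(1, p * Meff)."""
    p = np.asarray(pvalues, dtype=float)
    return np.minimum(1.0, p * meff)
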