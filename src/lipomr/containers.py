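"""Core data containers shared across the MR / TWAS stack.

Conventions
-----------
* Genomic coordinates are 1-based and intervals are closed on both ends.
* Effect sizes (``beta``) are per effect-allele copy, in SD units for
  quantitative traits and log-odds for binary traits.
* A :class:`HarmonizedPanel` holds the variant-exposure association matrix
  ``bX`` (J x K), the outcome vector ``bY`` (J) and their standard errors,
  all expressed on a common effect allele per variant. Every MR estimator
  in the package consumes this object.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

VALID_ALLELES = frozenset("ACGT")
PALINDROMIC_PAIRS = frozenset({("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")})


class DataError(ValueError):
    """Malformed or inconsistent input data."""


class ConfigurationError(ValueError):
    """Invalid user-supplied configuration."""


@dataclass(frozen=True)
class VariantAssociation:
    """Per-variant association with a single trait."""

    variant_id: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    chrom: str | None = None
    pos: int | None = None
    eaf: float | None = None
    pvalue: float | None = None
    n: float | None = None

    def __post_init__(self) -> None:
        if self.effect_allele == self.other_allele:
            raise DataError(
                f"{self.variant_id}: effect and other allele are identical"
            )
        if self.se <= 0:
            raise DataError(f"{self.variant_id}: se must be > 0")
        if self.eaf is not None and not (0.0 < self.eaf < 1.0):
            raise DataError(f"{self.variant_id}: eaf must lie in (0,1)")

    @property
    def is_palindromic(self) -> bool:
        return (self.effect_allele, self.other_allele) in PALINDROMIC_PAIRS


@dataclass
class SummaryStatSet:
    """GWAS summary statistics for one trait."""

    trait_name: str
    trait_type: str  # "quantitative" | "binary"
    records: list[VariantAssociation]

    def __post_init__(self) -> None:
        if self.trait_type not in ("quantitative", "binary"):
            raise ConfigurationError(
                f"trait_type must be quantitative|binary, got {self.trait_type!r}"
            )
        seen: set[str] = set()
        for rec in self.records:
            if rec.variant_id in seen:
                raise DataError(f"duplicate variant_id {rec.variant_id!r}")
            seen.add(rec.variant_id)

    def __len__(self) -> int:
        return len(self.records)

    def by_id(self) -> dict[str, VariantAssociation]:
        return {r.variant_id: r for r in self.records}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(r) for r in self.records])


@dataclass
class LDMatrix:
    """Symmetric variant-variant correlation matrix.

    Loaded or constructed matrices are validated; if the smallest eigenvalue
    falls below 1e-8 a doubling ridge is added to the diagonal until the
    matrix is numerically positive semi-definite (recorded in
    ``regularization_log``), since sample LD estimates are often indefinite
    and GLS weighting requires invertibility.
    """

    variant_ids: list[str]
    r: np.ndarray
    regularization_log: str = ""

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        J = len(self.variant_ids)
        if self.r.shape != (J, J):
            raise DataError(
                f"LD matrix shape {self.r.shape} does not match {J} variant ids"
            )
        if not np.allclose(self.r, self.r.T, atol=1e-8):
            raise DataError("LD matrix is not symmetric")
        if np.abs(self.r).max() > 1.0 + 1e-8:
            raise DataError("LD correlations must lie in [-1, 1]")
        self.r = (self.r + self.r.T) / 2.0
        self._regularize()

    def _regularize(self) -> None:
        eps = 1e-8
        while np.linalg.eigvalsh(self.r).min() < 1e-8:
            self.r = self.r + eps * np.eye(len(self.variant_ids))
            self.regularization_log += f"ridge +{eps:g}; "
            eps *= 2.0
        if self.regularization_log:
            # keep unit diagonal after ridging
            d = np.sqrt(np.diag(self.r))
            self.r = self.r / np.outer(d, d)

    def index_of(self, ids: list[str]) -> np.ndarray:
        lookup = {v: i for i, v in enumerate(self.variant_ids)}
        missing = [v for v in ids if v not in lookup]
        if missing:
            raise DataError(f"variants absent from LD matrix: {missing[:5]}")
        return np.array([lookup[v] for v in ids], dtype=int)

    def subset(self, ids: list[str]) -> "LDMatrix":
        idx = self.index_of(ids)
        return LDMatrix(list(ids), self.r[np.ix_(idx, idx)])

    @classmethod
    def identity(cls, ids: list[str]) -> "LDMatrix":
        return cls(list(ids), np.eye(len(ids)))


@dataclass
class HarmonizedPanel:
    """Allele-aligned multi-trait association panel (J variants x K exposures)."""

    variant_ids: list[str]
    exposure_names: list[str]
    bX: np.ndarray  # (J, K)
    seX: np.ndarray  # (J, K)
    bY: np.ndarray  # (J,)
    seY: np.ndarray  # (J,)
    pX: np.ndarray | None = None  # (J, K) exposure p-values, optional
    chrom: list[str] | None = None
    pos: np.ndarray | None = None
    outcome_name: str = "outcome"
    alignment_log: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["variant_id", "action", "detail"])
    )

    def __post_init__(self) -> None:
        self.bX = np.atleast_2d(np.asarray(self.bX, dtype=float))
        self.seX = np.atleast_2d(np.asarray(self.seX, dtype=float))
        self.bY = np.asarray(self.bY, dtype=float).ravel()
        self.seY = np.asarray(self.seY, dtype=float).ravel()
        J, K = len(self.variant_ids), len(self.exposure_names)
        if J < 1 or K < 1:
            raise DataError("panel requires J >= 1 variants and K >= 1 exposures")
        if self.bX.shape != (J, K) or self.seX.shape != (J, K):
            raise DataError(f"bX/seX must have shape ({J},{K})")
        if self.bY.shape != (J,) or self.seY.shape != (J,):
            raise DataError(f"bY/seY must have shape ({J},)")
        if (self.seX <= 0).any() or (self.seY <= 0).any():
            raise DataError("all standard errors must be > 0")
        if self.pX is not None:
            self.pX = np.atleast_2d(np.asarray(self.pX, dtype=float))
            if self.pX.shape != (J, K):
                raise DataError(f"pX must have shape ({J},{K})")

    @property
    def n_variants(self) -> int:
        return len(self.variant_ids)

    @property
    def n_exposures(self) -> int:
        return len(self.exposure_names)

    def exposure_index(self, name: str) -> int:
        try:
            return self.exposure_names.index(name)
        except ValueError:
            raise ConfigurationError(f"unknown exposure {name!r}") from None

    def take(self, idx: np.ndarray | list[int]) -> "HarmonizedPanel":
        idx = np.asarray(idx, dtype=int)
        return replace(
            self,
            variant_ids=[self.variant_ids[i] for i in idx],
            bX=self.bX[idx],
            seX=self.seX[idx],
            bY=self.bY[idx],
            seY=self.seY[idx],
            pX=None if self.pX is None else self.pX[idx],
            chrom=None if self.chrom is None else [self.chrom[i] for i in idx],
            pos=None if self.pos is None else np.asarray(self.pos)[idx],
        )

    def select_exposures(self, names: list[str]) -> "HarmonizedPanel":
        cols = [self.exposure_index(n) for n in names]
        return replace(
            self,
            exposure_names=list(names),
            bX=self.bX[:, cols],
            seX=self.seX[:, cols],
            pX=None if self.pX is None else self.pX[:, cols],
        )

    def to_frame(self) -> pd.DataFrame:
        data: dict[str, object] = {"variant_id": self.variant_ids}
        if self.chrom is not None:
            data["chrom"] = self.chrom
        if self.pos is not None:
            data["pos"] = np.asarray(self.pos)
        for k, name in enumerate(self.exposure_names):
            data[f"beta_{name}"] = self.bX[:, k]
            data[f"se_{name}"] = self.seX[:, k]
            if self.pX is not None:
                data[f"p_{name}"] = self.pX[:, k]
        data[f"beta_{self.outcome_name}"] = self.bY
        data[f"se_{self.outcome_name}"] = self.seY
        return pd.DataFrame(data)


@dataclass(frozen=True)
class GeneRegion:
    """Gene locus with a symmetric flank; coordinates 1-based, closed."""

    gene: str
    chrom: str
    start: int
    end: int
    flank_bp: int = 0

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise DataError(f"{self.gene}: start > end")
        if self.flank_bp < 0:
            raise ConfigurationError("flank_bp must be >= 0")

    @property
    def window(self) -> tuple[int, int]:
        return (max(1, self.start - self.flank_bp), self.end + self.flank_bp)

    def contains(self, chrom: str, pos: int) -> bool:
        lo, hi = self.window
        return chrom == self.chrom and lo <= pos <= hi


@dataclass(frozen=True)
class MREstimate:
    """A causal-effect estimate on the log-odds (or SD) scale.

    ``theta`` is the effect of a 1-SD increase in the exposure on the
    outcome; ``exp(theta)`` is the reportable odds ratio for binary
    outcomes.
    """

    method: str
    exposure: str
    theta: float
    se: float
    ci_low: float
    ci_high: float
    pvalue: float
    n_variants: int
    Q: float | None = None
    egger_intercept: float | None = None
    egger_intercept_se: float | None = None
    egger_intercept_p: float | None = None
    degenerate: bool = False

    @property
    def odds_ratio(self) -> float:
        return float(np.exp(self.theta))

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "exposure": self.exposure,
            "theta": self.theta,
            "se": self.se,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "pvalue": self.pvalue,
            "OR": self.odds_ratio,
            "Q": self.Q,
            "n_variants": self.n_variants,
        }
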