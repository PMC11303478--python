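"""Reduced-rank multiplicative model for genotype-by-environment effects.

The covariance Ge is eigendecomposed as Ge = U L U'; the first k
eigenvectors become environmental covariates S_k and the eigenvalues
become term variances L_k. Genotype slopes f_k ~ N(0, L_k (x) G) are then
combined into the v x p matrix of GE effects u = f_k S_k', so that
rows (genotypes) have between-environment covariance S_k L_k S_k' and
columns inherit the genotype relationship G.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .errors import MatrixError, ParameterError, ShapeError
from .rng import as_rng
from .tpe import BetweenEnvCovariance

__all__ = [
    "MultiplicativeTerms",
    "GenotypeRelationship",
    "GenotypeSlopes",
    "GEEffects",
    "decompose",
    "simulate_slopes",
    "construct_ge_effects",
    "genotype_main_effects",
    "psd_sqrt",
]

# Eigenvalues below this fraction of the largest are treated as zero.
RANK_RTOL = 1e-12


@dataclass
class MultiplicativeTerms:
    """Environmental covariates and term variances from the eigendecomposition.

    covariates : p x k matrix S_k with orthonormal columns.
    term_variances : the k leading eigenvalues l_r, non-increasing.
    total_variance : trace of the decomposed Ge (sum of all p eigenvalues).
    """

    covariates: np.ndarray
    term_variances: np.ndarray
    total_variance: float

    def __post_init__(self):
        self.covariates = np.asarray(self.covariates, dtype=float)
        self.term_variances = np.asarray(self.term_variances, dtype=float)
        if self.covariates.ndim != 2 or self.term_variances.ndim != 1:
            raise ShapeError("covariates must be 2-D and term_variances 1-D")
        if self.covariates.shape[1] != self.term_variances.size:
            raise ShapeError("number of covariate columns must match number of term variances")
        if np.any(np.diff(self.term_variances) > 1e-12):
            raise ParameterError("term variances must be sorted non-increasing")

    @property
    def p(self) -> int:
        return self.covariates.shape[0]

    @property
    def k(self) -> int:
        return self.covariates.shape[1]

    @property
    def variance_explained(self) -> np.ndarray:
        """Proportion of total genetic variance captured by each term."""
        return self.term_variances / self.total_variance

    def implied_covariance(self) -> np.ndarray:
        """S_k L_k S_k' — equals Ge exactly when rank(Ge) <= k."""
        s = self.covariates
        return (s * self.term_variances) @ s.T

    def covariate_means(self) -> np.ndarray:
        """Row vector s_bar_k of per-term covariate means across environments."""
        return self.covariates.mean(axis=0)


@dataclass
class GenotypeRelationship:
    """A v x v PSD genotype relationship matrix (identity, pedigree or genomic)."""

    matrix: np.ndarray
    kind: str = "identity"

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        m = self.matrix
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ShapeError(f"relationship matrix must be square, got {m.shape}")
        if np.abs(m - m.T).max() > 1e-8 * max(np.abs(m).max(), 1.0):
            raise MatrixError("relationship matrix is not symmetric")

    @classmethod
    def identity(cls, v: int) -> "GenotypeRelationship":
        return cls(np.eye(v), kind="identity")

    @property
    def v(self) -> int:
        return self.matrix.shape[0]


@dataclass
class GenotypeSlopes:
    """v x k matrix of genotype slopes, one column per multiplicative term."""

    values: np.ndarray
    genotype_ids: list = field(default_factory=list)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ShapeError("slopes must be a v x k matrix")
        if not np.all(np.isfinite(self.values)):
            raise ParameterError("slopes must be finite")
        if not self.genotype_ids:
            self.genotype_ids = [f"G{i + 1}" for i in range(self.values.shape[0])]

    @property
    def v(self) -> int:
        return self.values.shape[0]

    @property
    def k(self) -> int:
        return self.values.shape[1]

    @classmethod
    def from_csv(cls, path) -> "GenotypeSlopes":
        import pandas as pd

        df = pd.read_csv(path, index_col=0)
        return cls(df.to_numpy(dtype=float), genotype_ids=list(df.index.astype(str)))


@dataclass
class GEEffects:
    """The v x p matrix of true genotype-by-environment effects u."""

    values: np.ndarray
    genotype_ids: list = field(default_factory=list)
    environment_ids: list = field(default_factory=list)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ShapeError("GE effects must be a v x p matrix")
        if not np.all(np.isfinite(self.values)):
            raise ParameterError("GE effects must be finite")
        v, p = self.values.shape
        if not self.genotype_ids:
            self.genotype_ids = [f"G{i + 1}" for i in range(v)]
        if not self.environment_ids:
            self.environment_ids = [f"E{j + 1}" for j in range(p)]

    @property
    def v(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]


def psd_sqrt(matrix: np.ndarray, rtol: float = 1e-8) -> np.ndarray:
    """Symmetric PSD square root via eigendecomposition.

    Raises MatrixError when the smallest eigenvalue is below
    -rtol * max(eigenvalue), suggesting bend_to_psd for repair.
    """
    m = np.asarray(matrix, dtype=float)
    w, u = np.linalg.eigh(m)
    if w[0] < -rtol * max(w[-1], 0.0) - 1e-12:
        raise MatrixError(
            f"matrix is not PSD within tolerance (min eigenvalue {w[0]:.3e}); "
            "apply tpe.bend_to_psd first"
        )
    w = np.clip(w, 0.0, None)
    return (u * np.sqrt(w)) @ u.T


def decompose(ge: BetweenEnvCovariance | np.ndarray, k: int | None = None) -> MultiplicativeTerms:
    """Eigendecompose Ge and keep the leading k multiplicative terms.

    Eigenvalues are sorted in decreasing order; each eigenvector's sign
    is fixed so that its largest-magnitude element is positive (ties
    broken by first index), making the covariates reproducible across
    platforms. ``variance_explained`` is relative to trace(Ge).
    """
    matrix = ge.matrix if isinstance(ge, BetweenEnvCovariance) else np.asarray(ge, dtype=float)
    p = matrix.shape[0]
    if k is None:
        k = ge.rank_hint if isinstance(ge, BetweenEnvCovariance) else p
    if not 1 <= k <= p:
        raise ParameterError(f"number of terms k must satisfy 1 <= k <= p={p}, got {k}")
    w, u = scipy.linalg.eigh(matrix)
    order = np.argsort(w)[::-1]
    w, u = w[order], u[:, order]
    w = np.where(w < RANK_RTOL * max(w[0], 0.0), 0.0, w)
    # sign convention: largest-magnitude element of each column positive
    for r in range(p):
        j = int(np.argmax(np.abs(u[:, r])))
        if u[j, r] < 0:
            u[:, r] = -u[:, r]
    return MultiplicativeTerms(
        covariates=u[:, :k],
        term_variances=np.clip(w[:k], 0.0, None),
        total_variance=float(np.trace(matrix)),
    )


def simulate_slopes(
    terms: MultiplicativeTerms,
    v: int,
    relationship: GenotypeRelationship | None = None,
    seed=None,
) -> GenotypeSlopes:
    """Draw genotype slopes f_k ~ N(0, L_k (x) G).

    Term columns are independent; column r has covariance l_r * G,
    realised by scaling standard normal draws with a PSD square root
    of the relationship matrix G (identity by default).
    """
    rng = as_rng(seed)
    k = terms.k
    if relationship is None:
        z = rng.standard_normal((v, k))
    else:
        if relationship.v != v:
            raise ShapeError(f"relationship matrix is {relationship.v} x {relationship.v}, expected v={v}")
        root = psd_sqrt(relationship.matrix)
        z = root @ rng.standard_normal((v, k))
    return GenotypeSlopes(z * np.sqrt(terms.term_variances))


def construct_ge_effects(terms: MultiplicativeTerms, slopes: GenotypeSlopes) -> GEEffects:
    """Combine covariates and slopes into GE effects u = f_k S_k'.

    Rows are genotypes, columns environments; the implied covariance
    across environments is S_k L_k S_k' (for G = I genotypes are i.i.d.).
    """
    if slopes.k != terms.k:
        raise ShapeError(f"slopes have {slopes.k} terms but covariates have {terms.k}")
    return GEEffects(slopes.values @ terms.covariates.T, genotype_ids=list(slopes.genotype_ids))


def genotype_main_effects(u: GEEffects | np.ndarray, environment_subset=None) -> np.ndarray:
    """Genotype main effects: row means of u over the chosen environments."""
    values = u.values if isinstance(u, GEEffects) else np.asarray(u, dtype=float)
    if environment_subset is None:
        return values.mean(axis=1)
    idx = np.asarray(environment_subset, dtype=int)
    if idx.size == 0:
        raise ParameterError("environment subset must be non-empty")
    return values[:, idx].mean(axis=1)
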