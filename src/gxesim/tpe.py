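"""Construction of a between-environment genetic covariance matrix Ge.

A breeder's target population of environments (TPE) is represented by a
p x p genetic covariance matrix Ge = De^{1/2} Ce De^{1/2}, where De holds
heterogeneous per-environment genetic variances (gamma-distributed) and
Ce is a reduced-rank genetic correlation matrix built by adding
unit-length structured noise to a compound-symmetry baseline,

    Ce = rho * J_p + epsilon * Lambda' Lambda,

with Lambda a (k-1) x p matrix of latent environmental covariates whose
columns are drawn elementwise U(-1, 1 + gamma) and scaled to unit length.
The skew parameter gamma in [-1, 0] pushes correlations away from a
symmetric spread around rho, producing the negatively skewed correlation
distributions typical of real multi-environment-trial data. When
epsilon = 1 - rho the diagonal of Ce is exactly one and rank(Ce) = k.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import MatrixError, ParameterError, ShapeError
from .rng import as_rng

__all__ = [
    "VarianceSpec",
    "CorrelationSpec",
    "BetweenEnvCovariance",
    "SCENARIOS",
    "simulate_genetic_variances",
    "simulate_latent_covariates",
    "simulate_correlation_matrix",
    "assemble_covariance",
    "bend_to_psd",
    "simulate_tpe",
    "scenario_covariance",
]

# Relative eigenvalue tolerance below which a symmetric matrix is still
# accepted as positive semi-definite.
PSD_RTOL = 1e-8
SYMMETRY_ATOL = 1e-10


@dataclass(frozen=True)
class VarianceSpec:
    """Gamma law for the per-environment genetic variances.

    Parameters
    ----------
    p : number of environments in the TPE.
    shape : gamma shape alpha (> 0). The product shape * scale is the
        large-p mean genetic variance across environments.
    scale : gamma scale theta (> 0), in variance units of the trait.
    """

    p: int
    shape: float = 1.5
    scale: float = 1.0

    def __post_init__(self):
        if self.p < 1:
            raise ParameterError(f"p must be >= 1, got {self.p}")
        if not self.shape > 0:
            raise ParameterError(f"gamma shape must be > 0, got {self.shape}")
        if not self.scale > 0:
            raise ParameterError(f"gamma scale must be > 0, got {self.scale}")


@dataclass(frozen=True)
class CorrelationSpec:
    """Parameters of the reduced-rank correlation generator.

    rho is the baseline genetic correlation (compound-symmetry part),
    epsilon the magnitude of the structured noise, gamma_skew the skew of
    the latent covariates and k the target rank. With enforce_rank=True,
    epsilon is tied to 1 - rho so that rank(Ce) = k exactly.
    """

    p: int
    rho: float
    epsilon: float | None = None
    gamma_skew: float = 0.0
    k: int = 7
    enforce_rank: bool = True

    def __post_init__(self):
        if self.p < 1:
            raise ParameterError(f"p must be >= 1, got {self.p}")
        if not 0.0 <= self.rho < 1.0:
            raise ParameterError(
                f"baseline correlation rho must satisfy 0 <= rho < 1 (got {self.rho}); "
                "negative rho can produce indefinite matrices that would require bending"
            )
        if not -1.0 <= self.gamma_skew <= 0.0:
            raise ParameterError(f"gamma_skew must lie in [-1, 0], got {self.gamma_skew}")
        if self.k < 2:
            raise ParameterError(f"rank k must be >= 2 (got {self.k}): the structured noise needs k-1 >= 1 rows")
        if self.epsilon is None:
            object.__setattr__(self, "epsilon", 1.0 - self.rho)
        if self.enforce_rank and abs(self.epsilon - (1.0 - self.rho)) > 1e-12:
            raise ParameterError(
                f"enforce_rank requires epsilon = 1 - rho = {1.0 - self.rho}, got {self.epsilon}"
            )
        if self.epsilon < 0 or self.epsilon > 1.0 - self.rho + 1e-12:
            raise ParameterError(
                f"epsilon must satisfy 0 <= epsilon <= 1 - rho = {1.0 - self.rho}, got {self.epsilon}"
            )


@dataclass
class BetweenEnvCovariance:
    """A p x p between-environment genetic covariance matrix.

    ``rank_hint`` is k when the matrix was constructed with the
    reduced-rank generator, else p.
    """

    matrix: np.ndarray
    rank_hint: int | None = None
    environment_ids: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        m = self.matrix
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ShapeError(f"covariance matrix must be square, got shape {m.shape}")
        scale = max(np.abs(m).max(), 1.0)
        if np.abs(m - m.T).max() > SYMMETRY_ATOL * scale:
            raise MatrixError("covariance matrix is not symmetric within tolerance")
        w = np.linalg.eigvalsh(m)
        if w[0] < -PSD_RTOL * max(w[-1], 0.0) - 1e-12:
            raise MatrixError(
                f"covariance matrix is not positive semi-definite "
                f"(min eigenvalue {w[0]:.3e}); consider bend_to_psd()"
            )
        if self.rank_hint is None:
            self.rank_hint = m.shape[0]
        if not self.environment_ids:
            self.environment_ids = [f"E{j + 1}" for j in range(m.shape[0])]

    @property
    def p(self) -> int:
        return self.matrix.shape[0]

    @property
    def variances(self) -> np.ndarray:
        """The p diagonal entries sigma^2_gj."""
        return np.diag(self.matrix).copy()

    @property
    def correlations(self) -> np.ndarray:
        """The implied correlation matrix Ce (unit diagonal)."""
        sd = np.sqrt(self.variances)
        with np.errstate(divide="ignore", invalid="ignore"):
            c = self.matrix / np.outer(sd, sd)
        c[~np.isfinite(c)] = 0.0
        np.fill_diagonal(c, 1.0)
        return c


# Parameter presets used throughout: the low / moderate / high GEI TPEs,
# plus a compound-symmetry TPE with no interaction as a baseline.
SCENARIOS: dict[str, dict] = {
    "none": dict(shape=1.5, scale=1.0, rho=None, epsilon=None, gamma_skew=0.0, k=1),
    "low": dict(shape=1.5, scale=1.0, rho=0.50, epsilon=0.50, gamma_skew=-0.50, k=7),
    "moderate": dict(shape=1.5, scale=1.0, rho=0.20, epsilon=0.80, gamma_skew=-0.50, k=7),
    "high": dict(shape=1.5, scale=1.0, rho=0.00, epsilon=1.00, gamma_skew=-0.35, k=7),
}


def simulate_genetic_variances(spec: VarianceSpec, seed=None) -> np.ndarray:
    """Draw p i.i.d. genetic variances sigma^2_gj ~ Gamma(shape, scale)."""
    rng = as_rng(seed)
    v = rng.gamma(spec.shape, spec.scale, size=spec.p)
    # gamma draws are strictly positive a.s.; guard against underflow to 0
    tiny = np.finfo(float).tiny
    return np.maximum(v, tiny)


def simulate_latent_covariates(p: int, k: int, gamma_skew: float = 0.0, seed=None) -> np.ndarray:
    """Draw the (k-1) x p latent covariate matrix Lambda.

    Each column (one environment) is drawn elementwise U(-1, 1 + gamma_skew)
    and scaled to unit Euclidean length. Columns are generated in
    environment order so that extending p reuses the first draws.
    """
    if k < 2:
        raise ParameterError(f"rank k must be >= 2 (got {k}): the structured noise needs k-1 >= 1 rows")
    if not -1.0 <= gamma_skew <= 0.0:
        raise ParameterError(f"gamma_skew must lie in [-1, 0], got {gamma_skew}")
    rng = as_rng(seed)
    # row-major fill of a (p, k-1) block = column-major in environment order
    lam = rng.uniform(-1.0, 1.0 + gamma_skew, size=(p, k - 1)).T
    norms = np.linalg.norm(lam, axis=0)
    bad = norms == 0.0
    while np.any(bad):  # probability-zero event; redraw defensively
        lam[:, bad] = rng.uniform(-1.0, 1.0 + gamma_skew, size=(k - 1, int(bad.sum())))
        norms = np.linalg.norm(lam, axis=0)
        bad = norms == 0.0
    return lam / norms


def simulate_correlation_matrix(
    spec: CorrelationSpec,
    seed=None,
    latent: np.ndarray | None = None,
    base_matrix: np.ndarray | None = None,
) -> np.ndarray:
    """Simulate the reduced-rank correlation matrix Ce = rho*J + eps*Lambda'Lambda.

    Parameters
    ----------
    latent : optional pre-drawn (k-1) x p covariate matrix (unit columns).
    base_matrix : optional p x p plug-in replacing the compound-symmetry
        base rho * J_p (e.g. a user-supplied empirical structure). Must be
        a valid correlation-scale matrix with entries <= rho on the scale
        implied by the noise budget; it is used as-is.
    """
    p = spec.p
    if latent is None:
        latent = simulate_latent_covariates(p, spec.k, spec.gamma_skew, seed)
    else:
        latent = np.asarray(latent, dtype=float)
        if latent.shape != (spec.k - 1, p):
            raise ShapeError(f"latent covariates must be {(spec.k - 1, p)}, got {latent.shape}")
    if base_matrix is None:
        base = np.full((p, p), spec.rho)
    else:
        base = np.asarray(base_matrix, dtype=float)
        if base.shape != (p, p):
            raise ShapeError(f"base matrix must be {(p, p)}, got {base.shape}")
    ce = base + spec.epsilon * (latent.T @ latent)
    ce = (ce + ce.T) / 2.0
    if not spec.enforce_rank or base_matrix is not None:
        # rank guarantee sacrificed: diagonal must be reset to one
        np.fill_diagonal(ce, 1.0)
    else:
        np.fill_diagonal(ce, 1.0)  # exact up to rounding already
    return ce


def assemble_covariance(variances: np.ndarray, ce: np.ndarray, rank_hint: int | None = None) -> BetweenEnvCovariance:
    """Combine variances and correlations: Ge = De^{1/2} Ce De^{1/2}."""
    variances = np.asarray(variances, dtype=float)
    ce = np.asarray(ce, dtype=float)
    if variances.ndim != 1 or ce.shape != (variances.size, variances.size):
        raise ShapeError(
            f"dimension mismatch: {variances.size} variances vs correlation shape {ce.shape}"
        )
    if np.any(variances <= 0):
        raise ParameterError("all genetic variances must be strictly positive")
    sd = np.sqrt(variances)
    ge = ce * np.outer(sd, sd)
    np.fill_diagonal(ge, variances)  # diagonal equals the inputs exactly
    return BetweenEnvCovariance(ge, rank_hint=rank_hint)


def bend_to_psd(matrix: np.ndarray, tolerance: float = 0.0, correlation: bool = False) -> np.ndarray:
    """Clip eigenvalues below ``tolerance`` and reconstruct.

    Intended for user-supplied matrices; the built-in generator never
    produces indefinite output. For ``correlation=True`` the result is
    re-scaled to unit diagonal after clipping. Already-PSD input is
    returned unchanged (same object).
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ShapeError(f"matrix must be square, got shape {m.shape}")
    scale = max(np.abs(m).max(), 1.0)
    if np.abs(m - m.T).max() > SYMMETRY_ATOL * scale:
        raise ShapeError("matrix must be symmetric")
    w, u = np.linalg.eigh(m)
    if w[0] >= tolerance:
        return matrix
    w = np.maximum(w, tolerance)
    bent = (u * w) @ u.T
    bent = (bent + bent.T) / 2.0
    if correlation:
        d = np.sqrt(np.diag(bent))
        bent = bent / np.outer(d, d)
        np.fill_diagonal(bent, 1.0)
    return bent


def simulate_tpe(
    p: int,
    shape: float = 1.5,
    scale: float = 1.0,
    rho: float = 0.5,
    epsilon: float | None = None,
    gamma_skew: float = 0.0,
    k: int = 7,
    seed=None,
) -> BetweenEnvCovariance:
    """One-call TPE construction: variances, correlations, covariance.

    A single seed controls the whole construction; the variance and
    correlation draws use independent child streams.
    """
    rng = as_rng(seed)
    var_spec = VarianceSpec(p=p, shape=shape, scale=scale)
    corr_spec = CorrelationSpec(
        p=p, rho=rho, epsilon=epsilon, gamma_skew=gamma_skew, k=k,
        enforce_rank=(epsilon is None or abs(epsilon - (1.0 - rho)) <= 1e-12),
    )
    variances = simulate_genetic_variances(var_spec, rng)
    ce = simulate_correlation_matrix(corr_spec, rng)
    return assemble_covariance(variances, ce, rank_hint=k)


def scenario_covariance(name: str, p: int, seed=None) -> BetweenEnvCovariance:
    """Construct the TPE covariance for a named GEI scenario.

    ``"low"``, ``"moderate"`` and ``"high"`` use the reduced-rank
    generator with rank 7; ``"none"`` is the compound-symmetry baseline
    with a common variance (gamma mean) and perfect correlation.
    """
    if name not in SCENARIOS:
        raise ParameterError(f"unknown scenario {name!r}; choose from {sorted(SCENARIOS)}")
    params = SCENARIOS[name]
    if name == "none":
        common = params["shape"] * params["scale"]
        ge = np.full((p, p), common)
        return BetweenEnvCovariance(ge, rank_hint=1)
    return simulate_tpe(
        p=p, shape=params["shape"], scale=params["scale"], rho=params["rho"],
        epsilon=params["epsilon"], gamma_skew=params["gamma_skew"], k=params["k"], seed=seed,
    )
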