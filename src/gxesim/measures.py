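"""Variance-explained and expected-accuracy measures for a simulated TPE.

Two families of summaries are computed from the true simulation
parameters (never estimated from phenotypes):

* a partition of the genetic variance in Ge into genotype main-effect
  variance, interaction variance (further split into heterogeneity of
  genetic variance and lack of genetic correlation) and into
  non-crossover vs crossover variance; and

* expected accuracies of genotype main effects in the TPE and in a MET
  of p_m environments with r replicates, linked by the identity
  r_g = r_m * r_mt with r_mt the expected MET-TPE alignment.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from .errors import DegenerateInputError, ParameterError
from .rng import as_rng
from .tpe import BetweenEnvCovariance, VarianceSpec, simulate_tpe

__all__ = [
    "VarianceDecomposition",
    "AccuracySet",
    "variance_decomposition",
    "heterogeneity_closed_form",
    "expected_accuracies",
    "tune_to_targets",
]


@dataclass
class VarianceDecomposition:
    """Partition of the genetic variance carried by a covariance matrix Ge.

    All sigma2_* fields are in trait-variance units; v_* are proportions
    of the total (mean diagonal) variance. ``env_main_correlations``
    holds the p correlations rho*_gj between the genotype main effects
    and the GE effects of each environment.
    """

    sigma2_g: float
    sigma2_ge: float
    sigma2_ge_h: float
    sigma2_ge_l: float
    sigma2_n: float
    sigma2_c: float
    v_g: float
    v_ge: float
    v_n: float
    v_c: float
    mean_variance: float
    mean_correlation: float
    env_main_correlations: np.ndarray = field(repr=False)

    def as_dict(self) -> dict:
        return {
            "v_g": self.v_g, "v_ge": self.v_ge, "v_n": self.v_n, "v_c": self.v_c,
            "mean_variance": self.mean_variance, "mean_correlation": self.mean_correlation,
            "sigma2_g": self.sigma2_g, "sigma2_ge": self.sigma2_ge,
            "sigma2_ge_h": self.sigma2_ge_h, "sigma2_ge_l": self.sigma2_ge_l,
            "sigma2_n": self.sigma2_n, "sigma2_c": self.sigma2_c,
        }


@dataclass
class AccuracySet:
    """Expected accuracies for a MET of p_m environments with r replicates.

    r_g : expected genotype main-effect accuracy in the TPE
        (square root of the line-mean heritability across environments).
    r_m : expected main-effect accuracy in the MET dataset.
    r_mt : expected MET-TPE alignment (r_g with the plot error removed).
    r_ge : expected accuracy of GE effects within MET environments.
    """

    r_g: float
    r_m: float
    r_mt: float
    r_ge: float
    sigma2_g: float
    sigma2_ge: float
    sigma2_eps: float
    p_m: int
    r: int

    def as_dict(self) -> dict:
        return {"r_g": self.r_g, "r_m": self.r_m, "r_mt": self.r_mt, "r_ge": self.r_ge}


def variance_decomposition(ge: BetweenEnvCovariance | np.ndarray) -> VarianceDecomposition:
    """Compute all variance-explained measures from Ge analytically.

    The main-effect variance sigma2_g is the mean element of Ge (the
    variance of genotype main effects defined as averages across
    environments); the total genetic variance is the mean diagonal
    element; their difference is the interaction variance. The
    non-crossover variance averages rho*_gj^2 * sigma2_gj over
    environments, where rho*_gj = rowmean_j(Ge) / (sigma_gj * sigma_g)
    is the correlation between main effects and environment-j effects.
    """
    matrix = ge.matrix if isinstance(ge, BetweenEnvCovariance) else np.asarray(ge, dtype=float)
    p = matrix.shape[0]
    if p < 2:
        raise ParameterError("variance decomposition needs at least 2 environments")
    variances = np.diag(matrix)
    total = float(variances.mean())
    if total <= 0.0:
        raise DegenerateInputError("total genetic variance is zero")
    sigma2_g = float(matrix.mean())
    sigma2_ge = total - sigma2_g
    sd = np.sqrt(variances)
    sigma2_ge_h = float(variances.mean() - sd.mean() ** 2)
    sigma2_ge_l = sigma2_ge - sigma2_ge_h

    zero = variances == 0.0
    if np.any(zero):
        warnings.warn(
            f"{int(zero.sum())} environment(s) have zero genetic variance; "
            "their rho*_gj is set to 0 and they are excluded from the mean correlation",
            RuntimeWarning,
        )
    row_means = matrix.mean(axis=1)
    rho_star = np.zeros(p)
    nz = ~zero
    rho_star[nz] = row_means[nz] / (sd[nz] * np.sqrt(sigma2_g))
    sigma2_n = float(np.mean(rho_star**2 * variances))
    sigma2_c = total - sigma2_n

    with np.errstate(divide="ignore", invalid="ignore"):
        corr = matrix / np.outer(sd, sd)
    keep = np.outer(nz, nz)
    np.fill_diagonal(keep, False)
    n_off = int(keep.sum())
    mean_corr = float(corr[keep].mean()) if n_off else float("nan")

    return VarianceDecomposition(
        sigma2_g=sigma2_g, sigma2_ge=sigma2_ge,
        sigma2_ge_h=sigma2_ge_h, sigma2_ge_l=sigma2_ge_l,
        sigma2_n=sigma2_n, sigma2_c=sigma2_c,
        v_g=sigma2_g / total, v_ge=sigma2_ge / total,
        v_n=sigma2_n / total, v_c=sigma2_c / total,
        mean_variance=total, mean_correlation=mean_corr,
        env_main_correlations=rho_star,
    )


def heterogeneity_closed_form(spec: VarianceSpec | None = None, shape: float | None = None, scale: float | None = None) -> float:
    """Population value of the heterogeneity-of-genetic-variance component.

    For sigma2_gj ~ Gamma(alpha, theta) the sample statistic
    mean(sigma2_gj) - mean(sigma_gj)^2 converges to

        alpha * theta - theta * (Gamma(alpha + 1/2) / Gamma(alpha))^2,

    using the gamma half-moment E[sqrt(X)] = sqrt(theta) * Gamma(alpha+1/2)/Gamma(alpha).
    """
    if spec is not None:
        shape, scale = spec.shape, spec.scale
    if shape is None or scale is None or shape <= 0 or scale <= 0:
        raise ParameterError("gamma shape and scale must be positive")
    half_moment_sq = np.exp(2.0 * (gammaln(shape + 0.5) - gammaln(shape)))
    return float(shape * scale - scale * half_moment_sq)


def expected_accuracies(sigma2_g: float, sigma2_ge: float, sigma2_eps: float, p_m: int, r: int) -> AccuracySet:
    """Expected accuracy and MET-TPE alignment for a MET sample.

    r_g  = sqrt(sigma2_g / (sigma2_g + sigma2_ge/p_m + sigma2_eps/(p_m r)))
    r_m  = sqrt((sigma2_g + sigma2_ge/p_m) / (same denominator))
    r_mt = sqrt(sigma2_g / (sigma2_g + sigma2_ge/p_m))
    r_ge = sqrt((sigma2_g + sigma2_ge) / (sigma2_g + sigma2_ge + sigma2_eps/r))
    """
    if min(sigma2_g, sigma2_ge, sigma2_eps) < 0:
        raise ParameterError("variance components must be non-negative")
    if p_m < 1 or r < 1:
        raise ParameterError("p_m and r must be >= 1")
    if sigma2_g + sigma2_ge + sigma2_eps == 0.0:
        raise DegenerateInputError("all variance components are zero")
    met_var = sigma2_g + sigma2_ge / p_m
    denom = met_var + sigma2_eps / (p_m * r)
    r_g = np.sqrt(sigma2_g / denom) if denom > 0 else 0.0
    r_m = np.sqrt(met_var / denom) if denom > 0 else 0.0
    r_mt = np.sqrt(sigma2_g / met_var) if met_var > 0 else 0.0
    within = sigma2_g + sigma2_ge
    r_ge = np.sqrt(within / (within + sigma2_eps / r)) if within + sigma2_eps / r > 0 else 0.0
    return AccuracySet(
        r_g=float(r_g), r_m=float(r_m), r_mt=float(r_mt), r_ge=float(r_ge),
        sigma2_g=sigma2_g, sigma2_ge=sigma2_ge, sigma2_eps=sigma2_eps, p_m=p_m, r=r,
    )


def tune_to_targets(
    targets: dict[str, float],
    grid: list[dict],
    p: int = 500,
    n_seeds: int = 3,
    seed=None,
):
    """Rank candidate generator parameters by closeness to target measures.

    ``targets`` maps measure names (e.g. ``"v_n"``, ``"v_g"``) to desired
    values in (0, 1); ``grid`` is a list of parameter dicts accepted by
    :func:`gxesim.tpe.simulate_tpe` (without ``p``/``seed``). For each
    grid point, ``n_seeds`` TPE realisations are simulated and the
    seed-averaged measures attached; rows are sorted by the summed
    squared distance to the targets.
    """
    import pandas as pd

    if not grid:
        raise ParameterError("candidate grid must be non-empty")
    for name, val in targets.items():
        if not 0.0 < val < 1.0:
            raise ParameterError(f"target {name}={val} must lie in (0, 1)")
    rng = as_rng(seed)
    seeds = rng.integers(0, 2**31 - 1, size=n_seeds)
    rows = []
    for params in grid:
        estimates: dict[str, list[float]] = {name: [] for name in targets}
        for s in seeds:
            ge = simulate_tpe(p=p, seed=int(s), **params)
            dec = variance_decomposition(ge).as_dict()
            for name in targets:
                estimates[name].append(dec[name])
        row = dict(params)
        score = 0.0
        for name, val in targets.items():
            est = float(np.mean(estimates[name]))
            row[f"{name}_estimate"] = est
            score += (est - val) ** 2
        row["distance"] = float(np.sqrt(score))
        rows.append(row)
    out = pd.DataFrame(rows).sort_values("distance", kind="stable").reset_index(drop=True)
    return out
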