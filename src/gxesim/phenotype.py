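"""Plot-level phenotype generation for multi-environment trials.

GE effects are embedded in the linear mixed model

    y = 1_n mu + X tau + Z u + eps,

with environmental main effects tau (i.i.d. normal, or a regression on
the environmental covariates), a randomised complete block design
(RCBD) with r blocks per environment, and plot errors that are either
independent or follow a separable AR(1) x AR(1) spatial process on the
trial grid.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ParameterError, ShapeError
from .multiplicative import GEEffects
from .rng import as_rng

__all__ = [
    "TrialDesign",
    "EnvironmentalEffects",
    "PlotErrorSpec",
    "METDataset",
    "simulate_environment_means",
    "per_environment_error_variances",
    "simulate_plot_errors",
    "error_variance_from_heritability",
    "build_met_dataset",
    "summarise_met",
]


@dataclass(frozen=True)
class TrialDesign:
    """An RCBD field-trial layout shared by all environments of a MET.

    n_rows / n_cols give the plot grid per environment for spatial
    errors: blocks occupy contiguous column ranges, plots are ordered
    row-major within each environment.
    """

    n_genotypes: int
    n_envs: int
    n_blocks: int
    design: str = "rcbd"
    n_rows: int | None = None
    n_cols: int | None = None
    trait_mean: float = 0.0

    def __post_init__(self):
        if min(self.n_genotypes, self.n_envs, self.n_blocks) < 1:
            raise ParameterError("genotype, environment and block counts must all be >= 1")
        if self.design != "rcbd":
            raise ParameterError(f"only the RCBD design is generated, got {self.design!r}")
        if (self.n_rows is None) != (self.n_cols is None):
            raise ParameterError("spatial layout needs both n_rows and n_cols")
        if self.n_rows is not None and self.n_rows * self.n_cols != self.plots_per_env:
            raise ParameterError(
                f"grid {self.n_rows} x {self.n_cols} does not hold "
                f"{self.plots_per_env} plots per environment"
            )

    @property
    def plots_per_env(self) -> int:
        return self.n_genotypes * self.n_blocks

    @property
    def n_plots(self) -> int:
        return self.plots_per_env * self.n_envs


@dataclass(frozen=True)
class EnvironmentalEffects:
    """Law of the environmental main effects tau.

    mode "iid": tau ~ N(0, sigma2_e I). mode "covariate_regression":
    tau = S_k tau_s, a deterministic regression on the environmental
    covariates that induces a mean-variance relationship across
    environments (used to track genetic gain in breeding simulations).
    """

    sigma2_e: float = 1.0
    mode: str = "iid"
    tau_s: np.ndarray | None = None

    def __post_init__(self):
        if self.mode not in ("iid", "covariate_regression"):
            raise ParameterError(f"unknown mode {self.mode!r}")
        if self.sigma2_e < 0:
            raise ParameterError("environmental main effect variance must be >= 0")
        if self.mode == "covariate_regression" and self.tau_s is None:
            raise ParameterError("covariate_regression mode requires tau_s")


@dataclass(frozen=True)
class PlotErrorSpec:
    """Law of the plot errors.

    sigma2_eps_mean is the mean error variance across environments.
    With heterogeneous=True (default) the per-environment variances are
    drawn from a gamma distribution rescaled to that mean, mimicking
    the spread of error variances seen in real MET data; otherwise all
    environments share sigma2_eps_mean. Explicit per_env_variances
    override both. correlation "ar1" requests a separable AR(1) x AR(1)
    process on the trial grid with the given row/column parameters.
    """

    sigma2_eps_mean: float
    per_env_variances: tuple | None = None
    heterogeneous: bool = True
    het_shape: float = 10.0
    correlation: str = "independent"
    ar1_row: float = 0.0
    ar1_col: float = 0.0

    def __post_init__(self):
        if self.sigma2_eps_mean < 0:
            raise ParameterError("mean error variance must be >= 0")
        if self.per_env_variances is not None and any(v < 0 for v in self.per_env_variances):
            raise ParameterError("per-environment error variances must be >= 0")
        if self.correlation not in ("independent", "ar1"):
            raise ParameterError(f"unknown error correlation {self.correlation!r}")
        if self.correlation == "ar1" and not (abs(self.ar1_row) < 1 and abs(self.ar1_col) < 1):
            raise ParameterError("AR(1) parameters must lie in (-1, 1)")


@dataclass
class METDataset:
    """A long-format plot table plus the truth needed to audit it.

    ``data`` columns: env_id, block, genotype_id, true_ge_effect,
    phenotype. ``metadata`` records seeds, specs, the sampled TPE
    environment indices and the per-environment truth (tau, error
    variances) so the simulation is fully reconstructable.
    """

    data: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    @property
    def n_plots(self) -> int:
        return len(self.data)


def simulate_environment_means(
    p_m: int,
    effects: EnvironmentalEffects | None = None,
    covariates: np.ndarray | None = None,
    seed=None,
) -> np.ndarray:
    """Simulate the p_m environmental main effects tau.

    In regression mode ``covariates`` must hold the S_k rows of the
    sampled environments (p_m x k); tau = S_k tau_s is deterministic.
    """
    effects = effects or EnvironmentalEffects()
    if effects.mode == "covariate_regression":
        if covariates is None:
            raise ParameterError("covariate_regression mode needs the sampled covariate rows")
        covariates = np.asarray(covariates, dtype=float)
        tau_s = np.asarray(effects.tau_s, dtype=float)
        if covariates.shape != (p_m, tau_s.size):
            raise ShapeError(f"covariates must be {(p_m, tau_s.size)}, got {covariates.shape}")
        return covariates @ tau_s
    rng = as_rng(seed)
    if effects.sigma2_e == 0.0:
        return np.zeros(p_m)
    return rng.normal(0.0, np.sqrt(effects.sigma2_e), size=p_m)


def per_environment_error_variances(spec: PlotErrorSpec, p_m: int, seed=None) -> np.ndarray:
    """Resolve the p_m error variances sigma2_eps_j implied by the spec."""
    if spec.per_env_variances is not None:
        v = np.asarray(spec.per_env_variances, dtype=float)
        if v.size != p_m:
            raise ShapeError(f"expected {p_m} per-environment variances, got {v.size}")
        return v
    if not spec.heterogeneous or spec.sigma2_eps_mean == 0.0:
        return np.full(p_m, spec.sigma2_eps_mean)
    rng = as_rng(seed)
    draws = rng.gamma(spec.het_shape, 1.0, size=p_m)
    return draws * (spec.sigma2_eps_mean / spec.het_shape)


def _ar1_chol(n: int, rho: float) -> np.ndarray:
    idx = np.arange(n)
    corr = rho ** np.abs(idx[:, None] - idx[None, :])
    return np.linalg.cholesky(corr)


def simulate_plot_errors(
    design: TrialDesign,
    spec: PlotErrorSpec,
    seed=None,
    env_variances: np.ndarray | None = None,
) -> np.ndarray:
    """Simulate the n-vector of plot errors in standard plot order.

    Standard order: environments outer, then plots row-major on the
    per-environment grid (for RCBD without a grid: block-major, one
    slot per genotype). Pre-resolved ``env_variances`` may be passed to
    keep them in sync with a dataset's metadata.
    """
    rng = as_rng(seed)
    if env_variances is None:
        env_variances = per_environment_error_variances(spec, design.n_envs, rng)
    env_variances = np.asarray(env_variances, dtype=float)
    m = design.plots_per_env
    if spec.correlation == "independent":
        z = rng.standard_normal((design.n_envs, m))
        return (z * np.sqrt(env_variances)[:, None]).ravel()
    if design.n_rows is None:
        raise ParameterError("AR(1) x AR(1) errors need the n_rows/n_cols trial grid")
    l_row = _ar1_chol(design.n_rows, spec.ar1_row)
    l_col = _ar1_chol(design.n_cols, spec.ar1_col)
    out = np.empty((design.n_envs, m))
    for j in range(design.n_envs):
        z = rng.standard_normal((design.n_rows, design.n_cols))
        grid = l_row @ z @ l_col.T  # correlation AR1_row (x) AR1_col
        out[j] = np.sqrt(env_variances[j]) * grid.ravel()
    return out.ravel()


def error_variance_from_heritability(mean_genetic_variance: float, h2_target: float) -> float:
    """Mean plot-error variance achieving a target plot-level heritability."""
    if not 0.0 < h2_target < 1.0:
        raise ParameterError(f"target heritability must lie in (0, 1), got {h2_target}")
    if mean_genetic_variance < 0:
        raise ParameterError("mean genetic variance must be >= 0")
    return mean_genetic_variance * (1.0 - h2_target) / h2_target


def build_met_dataset(
    u_sampled: GEEffects | np.ndarray,
    tau: np.ndarray,
    errors: np.ndarray,
    design: TrialDesign,
    mu: float | None = None,
    env_ids=None,
    genotype_ids=None,
    randomise: bool = True,
    seed=None,
    metadata: dict | None = None,
) -> METDataset:
    """Assemble the plot table: phenotype = mu + tau_j + u_ij + eps_plot.

    ``errors`` must be in the standard plot order of
    :func:`simulate_plot_errors`. Each (environment, block) cell
    contains every genotype exactly once; with ``randomise`` the
    genotype-to-plot assignment is shuffled per block.
    """
    if isinstance(u_sampled, GEEffects):
        values = u_sampled.values
        genotype_ids = genotype_ids or list(u_sampled.genotype_ids)
        env_ids = env_ids or list(u_sampled.environment_ids)
    else:
        values = np.asarray(u_sampled, dtype=float)
    v, p_m = values.shape
    if (v, p_m) != (design.n_genotypes, design.n_envs):
        raise ShapeError(
            f"GE effects are {v} x {p_m} but the design expects "
            f"{design.n_genotypes} genotypes x {design.n_envs} environments"
        )
    tau = np.asarray(tau, dtype=float)
    errors = np.asarray(errors, dtype=float)
    if tau.size != p_m:
        raise ShapeError(f"expected {p_m} environmental main effects, got {tau.size}")
    if errors.size != design.n_plots:
        raise ShapeError(f"expected {design.n_plots} plot errors, got {errors.size}")
    mu = design.trait_mean if mu is None else mu
    env_ids = env_ids or [f"E{j + 1}" for j in range(p_m)]
    genotype_ids = genotype_ids or [f"G{i + 1}" for i in range(v)]

    rng = as_rng(seed)
    rows_env, rows_block, rows_geno = [], [], []
    for j in range(p_m):
        for b in range(design.n_blocks):
            order = rng.permutation(v) if randomise else np.arange(v)
            rows_env.append(np.full(v, j))
            rows_block.append(np.full(v, b + 1))
            rows_geno.append(order)
    env_idx = np.concatenate(rows_env)
    block = np.concatenate(rows_block)
    geno_idx = np.concatenate(rows_geno)
    true_ge = values[geno_idx, env_idx]
    phenotype = (mu + tau[env_idx] + true_ge) + errors

    data = pd.DataFrame(
        {
            "env_id": np.asarray(env_ids, dtype=object)[env_idx],
            "block": block,
            "genotype_id": np.asarray(genotype_ids, dtype=object)[geno_idx],
            "true_ge_effect": true_ge,
            "plot_error": errors,
            "phenotype": phenotype,
        }
    )
    meta = dict(metadata or {})
    meta.setdefault("mu", mu)
    meta.setdefault("tau", np.asarray(tau))
    meta.setdefault("env_ids", list(env_ids))
    meta.setdefault("design", design)
    return METDataset(data=data, metadata=meta)


def summarise_met(met: METDataset) -> pd.DataFrame:
    """Per-environment summary mirroring a standard MET quality report.

    Columns: genotype/block/plot counts, environment mean, realised
    genetic variance of the true GE effects, true error variance and
    plot-level heritability H2_j = s2_gj / (s2_gj + s2_eps_j). The
    final "Overall" row averages the per-environment columns (counts
    are summed for plots).
    """
    if "error_variances" not in met.metadata:
        raise ParameterError("dataset metadata lacks the true per-environment error variances")
    err_var = np.asarray(met.metadata["error_variances"], dtype=float)
    env_ids = met.metadata.get("env_ids")
    tau = met.metadata.get("tau")
    mu = met.metadata.get("mu", 0.0)
    df = met.data
    order = env_ids if env_ids is not None else list(dict.fromkeys(df["env_id"]))
    rows = []
    for j, env in enumerate(order):
        sub = df[df["env_id"] == env]
        geno_effects = sub.drop_duplicates("genotype_id")["true_ge_effect"].to_numpy()
        s2g = float(np.var(geno_effects, ddof=1))
        s2e = float(err_var[j])
        h2 = s2g / (s2g + s2e) if s2g + s2e > 0 else float("nan")
        mean = float(mu + tau[j]) if tau is not None else float(sub["phenotype"].mean())
        rows.append(
            {
                "env_id": env,
                "n_genotypes": sub["genotype_id"].nunique(),
                "n_blocks": sub["block"].nunique(),
                "n_plots": len(sub),
                "mean": mean,
                "sigma2_g": s2g,
                "sigma2_eps": s2e,
                "H2": h2,
            }
        )
    out = pd.DataFrame(rows)
    overall = {
        "env_id": "Overall",
        "n_genotypes": int(out["n_genotypes"].mean()),
        "n_blocks": int(out["n_blocks"].mean()),
        "n_plots": int(out["n_plots"].sum()),
        "mean": out["mean"].mean(),
        "sigma2_g": out["sigma2_g"].mean(),
        "sigma2_eps": out["sigma2_eps"].mean(),
        "H2": out["H2"].mean(),
    }
    return pd.concat([out, pd.DataFrame([overall])], ignore_index=True)
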