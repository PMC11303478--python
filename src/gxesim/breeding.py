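"""Recurrent breeding-programme simulation under genotype-by-environment
interaction.

The TPE enters the programme through its multiplicative terms: each of
the k terms is a separate additive trait whose founder variance equals
the term variance l_r, so the true GE effects of any genotype in any
environment are recovered as (slopes) @ S_k'. Every year a subset of
environments is sampled from the TPE, each evaluation stage phenotypes
its genotypes in a nested subset of those environments, and superior
genotypes are advanced by truncation on either phenotype means
(phenotypic selection) or genotype main-effect BLUPs from a
compound-symmetry mixed model pooling recent trials (genomic
selection). Genetic progress is tracked in both the TPE and the MET:
the gain is mu*_g = s_bar_k tau*_{s_k} (covariate means times current
slope means) and the variance sigma*2_g = s_bar_k L*_k s_bar_k' with
L*_k the current slope covariance.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import NumericError, ParameterError, ShapeError
from .multiplicative import MultiplicativeTerms
from .rng import as_rng
from .sampling import sample_environments

__all__ = [
    "Genome",
    "Population",
    "StageConfig",
    "ProgrammeConfig",
    "create_founders",
    "make_crosses",
    "genomic_relationship",
    "predict_main_effects_cs",
    "track_progress",
    "run_programme",
]


@dataclass(frozen=True)
class Genome:
    """Marker map: biallelic loci at uniform positions on unit-length chromosomes."""

    chromosome: np.ndarray  # (m,) chromosome index per locus
    position: np.ndarray  # (m,) position in [0, 1], sorted within chromosome

    @property
    def n_loci(self) -> int:
        return self.chromosome.size

    @property
    def n_chromosomes(self) -> int:
        return int(self.chromosome.max()) + 1


@dataclass
class Population:
    """A set of (doubled-haploid) genotypes with marker data and trait model.

    haplotypes : (n, 2, m) allele array in {0, 1}; dosages are the sum
    over the two haplotypes, hence in {0, 1, 2}.
    marker_effects / intercepts : shared additive trait model mapping
    dosages to the k genotype slopes (one trait per multiplicative term).
    """

    genome: Genome
    haplotypes: np.ndarray
    marker_effects: np.ndarray  # (m, k)
    intercepts: np.ndarray  # (k,)
    ids: np.ndarray = None
    generation: str = "founder"

    def __post_init__(self):
        if self.haplotypes.ndim != 3 or self.haplotypes.shape[1] != 2:
            raise ShapeError("haplotypes must have shape (n, 2, n_loci)")
        if self.haplotypes.shape[2] != self.genome.n_loci:
            raise ShapeError("haplotype locus count does not match the genome")
        if self.ids is None:
            self.ids = np.arange(self.n)

    @property
    def n(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def k(self) -> int:
        return self.marker_effects.shape[1]

    @property
    def dosages(self) -> np.ndarray:
        """(n, m) marker dosages in {0, 1, 2}."""
        return self.haplotypes.sum(axis=1)

    @property
    def slopes(self) -> np.ndarray:
        """(n, k) genotype slopes, one column per multiplicative term."""
        return self.dosages @ self.marker_effects + self.intercepts

    def subset(self, index: np.ndarray, generation: str | None = None) -> "Population":
        return replace(
            self,
            haplotypes=self.haplotypes[index],
            ids=self.ids[index],
            generation=generation or self.generation,
        )


def _make_genome(n_loci: int, n_chromosomes: int, rng) -> Genome:
    if n_loci < n_chromosomes:
        raise ParameterError("need at least one locus per chromosome")
    per = np.full(n_chromosomes, n_loci // n_chromosomes)
    per[: n_loci % n_chromosomes] += 1
    chrom = np.repeat(np.arange(n_chromosomes), per)
    position = np.empty(n_loci)
    start = 0
    for c, cnt in enumerate(per):
        position[start : start + cnt] = np.sort(rng.uniform(0.0, 1.0, size=cnt))
        start += cnt
    return Genome(chromosome=chrom, position=position)


def create_founders(
    n: int,
    n_loci: int,
    n_chromosomes: int,
    terms: MultiplicativeTerms,
    seed=None,
) -> Population:
    """Simulate a founder population of doubled-haploid lines.

    Allele frequencies are drawn U(0.1, 0.9) per locus; each founder is
    a doubled gamete (fully homozygous). Raw marker effects are drawn
    standard normal per term and then jointly standardised (centred,
    whitened and rescaled) so the founder slope sample covariance is
    exactly diag(L_k) with zero means — the founder population then has
    mu_g = 0 and sigma2_g = s_bar_k L_k s_bar_k' by construction.
    """
    if n < 1 or n_loci < 1:
        raise ParameterError("founder count and locus count must be >= 1")
    k = terms.k
    if k > n_loci:
        raise ParameterError(f"cannot carry k={k} independent terms on {n_loci} loci")
    if n <= k:
        raise ParameterError(f"need more founders than terms to standardise (n={n}, k={k})")
    rng = as_rng(seed)
    genome = _make_genome(n_loci, n_chromosomes, rng)
    freqs = rng.uniform(0.1, 0.9, size=n_loci)
    gametes = (rng.uniform(size=(n, n_loci)) < freqs).astype(np.int8)
    haplotypes = np.stack([gametes, gametes], axis=1)  # doubled haploids
    dosages = haplotypes.sum(axis=1)

    beta = rng.standard_normal((n_loci, k))
    raw = dosages @ beta
    centred = raw - raw.mean(axis=0)
    cov = np.cov(centred, rowvar=False, ddof=1).reshape(k, k)
    try:
        chol = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as exc:
        raise NumericError("founder slope covariance is singular; increase n or n_loci") from exc
    # transform T maps raw slopes to slopes with sample covariance diag(L_k)
    transform = np.linalg.solve(chol, np.eye(k)).T * np.sqrt(terms.term_variances)
    zero = terms.term_variances == 0.0
    transform[:, zero] = 0.0
    marker_effects = beta @ transform
    intercepts = -raw.mean(axis=0) @ transform
    return Population(
        genome=genome,
        haplotypes=haplotypes,
        marker_effects=marker_effects,
        intercepts=intercepts,
        ids=np.arange(n),
        generation="founder",
    )


def _meiosis(haplotypes: np.ndarray, genome: Genome, rng, crossover_rate: float = 1.0) -> np.ndarray:
    """One recombinant gamete per individual.

    Crossovers form a homogeneous Poisson process along each unit-length
    chromosome (rate = expected crossovers per chromosome), so between
    adjacent loci at map distance d the gamete switches parental strand
    with probability (1 - exp(-2 * rate * d)) / 2 (Haldane), and the
    starting strand is fair. Vectorised over individuals.
    """
    n, _, m = haplotypes.shape
    gamete = np.empty((n, m), dtype=np.int8)
    for c in range(genome.n_chromosomes):
        loci = np.flatnonzero(genome.chromosome == c)
        pos = genome.position[loci]
        d = np.diff(pos)
        switch_p = 0.5 * (1.0 - np.exp(-2.0 * crossover_rate * d))
        start = rng.integers(0, 2, size=(n, 1))
        switches = (rng.uniform(size=(n, d.size)) < switch_p).astype(np.int64)
        strand = (start + np.concatenate([np.zeros((n, 1), dtype=np.int64), np.cumsum(switches, axis=1)], axis=1)) % 2
        h = haplotypes[:, :, loci]
        gamete[:, loci] = np.take_along_axis(h, strand[:, None, :], axis=1)[:, 0, :]
    return gamete


def make_crosses(
    pop: Population,
    n_progeny: int,
    seed=None,
    parent_pairs: np.ndarray | None = None,
    crossover_rate: float = 1.0,
    doubled_haploid: bool = True,
    id_start: int = 0,
    generation: str = "progeny",
) -> Population:
    """Cross random (or given) parent pairs and derive progeny.

    Each progeny takes one recombinant gamete from each parent to form
    an F1; with ``doubled_haploid`` (default) a single recombinant F1
    gamete is then doubled, giving a fully homozygous line. Selfing a
    fully homozygous parent therefore reproduces it exactly.
    """
    rng = as_rng(seed)
    if parent_pairs is None:
        if pop.n < 2:
            raise ParameterError("random crossing needs at least 2 parents")
        a = rng.integers(0, pop.n, size=n_progeny)
        shift = rng.integers(1, pop.n, size=n_progeny)
        b = (a + shift) % pop.n  # distinct from a
        parent_pairs = np.column_stack([a, b])
    else:
        parent_pairs = np.asarray(parent_pairs, dtype=int)
        if parent_pairs.shape != (n_progeny, 2):
            raise ShapeError(f"parent_pairs must be (n_progeny, 2), got {parent_pairs.shape}")
    gam_a = _meiosis(pop.haplotypes[parent_pairs[:, 0]], pop.genome, rng, crossover_rate)
    gam_b = _meiosis(pop.haplotypes[parent_pairs[:, 1]], pop.genome, rng, crossover_rate)
    f1 = np.stack([gam_a, gam_b], axis=1)
    if doubled_haploid:
        doubled = _meiosis(f1, pop.genome, rng, crossover_rate)
        haplotypes = np.stack([doubled, doubled], axis=1)
    else:
        haplotypes = f1
    return replace(
        pop,
        haplotypes=haplotypes,
        ids=np.arange(id_start, id_start + n_progeny),
        generation=generation,
    )


def genomic_relationship(dosages: np.ndarray) -> np.ndarray:
    """VanRaden method-1 genomic relationship from marker dosages.

    K = W W' / sum(2 q (1-q)) with W the dosages centred at twice the
    observed allele frequencies. Falls back to the identity when the
    markers carry no variation.
    """
    w = np.asarray(dosages, dtype=float)
    q = w.mean(axis=0) / 2.0
    denom = float(np.sum(2.0 * q * (1.0 - q)))
    if denom <= 0.0:
        return np.eye(w.shape[0])
    wc = w - 2.0 * q
    return (wc @ wc.T) / denom


def predict_main_effects_cs(
    met,
    sigma2_g: float,
    sigma2_ge: float,
    sigma2_eps: float | None = None,
    relationship: np.ndarray | None = None,
    genotypes: list | None = None,
    ridge: float = 1e-8,
) -> pd.Series:
    """BLUP of genotype main effects under a compound-symmetry model.

    The analysis model is phenotype = environment (fixed) + genotype
    (variance sigma2_g * K) + genotype.environment (variance sigma2_ge)
    + plot error. The variance parameters are plugged in (true
    simulation values), and the interaction and error terms are
    absorbed into genotype-by-environment cell means, which are
    sufficient because blocks do not enter the model. Solved by the
    mixed-model equations on the cell means.

    ``met`` is a METDataset or a DataFrame with columns env_id,
    genotype_id, phenotype and optionally sigma2_eps (per record) when
    ``sigma2_eps`` is not given. Returns a Series indexed by genotype.
    """
    df = met.data if hasattr(met, "data") else met
    cols = {"env_id", "genotype_id", "phenotype"}
    if not cols.issubset(df.columns):
        raise ParameterError(f"MET table needs columns {sorted(cols)}")
    if min(sigma2_g, sigma2_ge) < 0:
        raise ParameterError("variance components must be non-negative")
    work = df.copy()
    if sigma2_eps is not None:
        work["sigma2_eps"] = sigma2_eps
    elif "sigma2_eps" not in work.columns:
        raise ParameterError("supply sigma2_eps or a per-record sigma2_eps column")

    cells = (
        work.groupby(["genotype_id", "env_id"], sort=False)
        .agg(y=("phenotype", "mean"), n=("phenotype", "size"), s2e=("sigma2_eps", "mean"))
        .reset_index()
    )
    if genotypes is None:
        genotypes = sorted(pd.unique(cells["genotype_id"]))
    g_index = pd.Index(genotypes)
    if relationship is not None:
        relationship = np.asarray(relationship, dtype=float)
        if relationship.shape != (len(g_index), len(g_index)):
            raise ShapeError(
                f"relationship matrix is {relationship.shape} but {len(g_index)} genotypes are listed"
            )
    v = len(g_index)
    if sigma2_g == 0.0:
        return pd.Series(np.zeros(v), index=g_index, name="blup_main")

    env_index = pd.Index(pd.unique(cells["env_id"]))
    gi = g_index.get_indexer(cells["genotype_id"])
    ei = env_index.get_indexer(cells["env_id"])
    if np.any(gi < 0):
        raise ParameterError("MET contains genotypes missing from the supplied genotype list")
    d = sigma2_ge + cells["s2e"].to_numpy() / cells["n"].to_numpy()
    if np.any(d <= 0):
        raise ParameterError("cell variances must be positive (sigma2_ge + sigma2_eps/r > 0)")
    w = 1.0 / d
    y = cells["y"].to_numpy()
    p_m = len(env_index)

    gamma = sigma2_g * (relationship if relationship is not None else np.eye(v))
    gamma = gamma + ridge * np.mean(np.diag(gamma)) * np.eye(v)
    try:
        gamma_inv = np.linalg.inv(gamma)
    except np.linalg.LinAlgError as exc:
        raise NumericError("genetic covariance (sigma2_g * K) is singular") from exc

    # mixed-model equations on cell means: [tau; g]
    ncoef = p_m + v
    lhs = np.zeros((ncoef, ncoef))
    rhs = np.zeros(ncoef)
    np.add.at(lhs, (ei, ei), w)
    np.add.at(lhs, (ei, p_m + gi), w)
    np.add.at(lhs, (p_m + gi, ei), w)
    np.add.at(lhs, (p_m + gi, p_m + gi), w)
    lhs[p_m:, p_m:] += gamma_inv
    np.add.at(rhs, ei, w * y)
    np.add.at(rhs, p_m + gi, w * y)
    try:
        sol = np.linalg.solve(lhs, rhs)
    except np.linalg.LinAlgError as exc:
        raise NumericError(
            f"singular mixed-model coefficient matrix ({p_m} environments, {v} genotypes, "
            f"{len(cells)} cells); check for empty environments or zero variances"
        ) from exc
    return pd.Series(sol[p_m:], index=g_index, name="blup_main")


@dataclass(frozen=True)
class StageConfig:
    """One field-evaluation stage: size, testing intensity, error level."""

    name: str
    n_genotypes: int
    n_envs: int
    n_reps: int
    error_variance: float

    def __post_init__(self):
        if min(self.n_genotypes, self.n_envs, self.n_reps) < 1:
            raise ParameterError(f"stage {self.name!r}: counts must be >= 1")
        if self.error_variance < 0:
            raise ParameterError(f"stage {self.name!r}: error variance must be >= 0")


DEFAULT_STAGES = (
    StageConfig("headrow", 200, 1, 1, 4.0),
    StageConfig("pyt", 50, 5, 2, 4.0),
    StageConfig("ayt", 20, 10, 2, 4.0),
    StageConfig("eyt", 10, 20, 2, 4.0),
)


@dataclass(frozen=True)
class ProgrammeConfig:
    """Configuration of the recurrent breeding programme.

    Stage sizes decrease and environments per stage increase through
    the pipeline; each stage's environments are a nested prefix of the
    year's sampled environments. Genomic selection pools all stages
    from the trailing ``met_window_years`` years into one MET.
    """

    years: int = 20
    envs_per_year: int = 20
    stages: tuple = DEFAULT_STAGES
    selection: str = "phenotypic"
    met_window_years: int = 3
    n_parents: int = 20
    n_crosses: int = 40
    progeny_per_cross: int = 5
    n_chromosomes: int = 10
    n_loci: int = 200
    trait_mean: float = 0.0
    sigma2_env: float = 1.0

    def __post_init__(self):
        if self.selection not in ("phenotypic", "genomic"):
            raise ParameterError(f"selection must be 'phenotypic' or 'genomic', got {self.selection!r}")
        if self.years < 1:
            raise ParameterError("years must be >= 1")
        sizes = [s.n_genotypes for s in self.stages]
        if any(b > a for a, b in zip(sizes, sizes[1:])):
            raise ParameterError(f"stage genotype counts must be non-increasing, got {sizes}")
        for s in self.stages:
            if s.n_envs > self.envs_per_year:
                raise ParameterError(
                    f"stage {s.name!r} uses {s.n_envs} environments but only "
                    f"{self.envs_per_year} are sampled per year"
                )
        if self.n_crosses * self.progeny_per_cross != sizes[0]:
            raise ParameterError(
                f"n_crosses * progeny_per_cross = {self.n_crosses * self.progeny_per_cross} "
                f"must equal the entry-stage size {sizes[0]}"
            )
        if self.n_parents < 2:
            raise ParameterError("need at least 2 parents for crossing")

    @property
    def total_genotypes(self) -> int:
        return sum(s.n_genotypes for s in self.stages)


def track_progress(
    slopes: np.ndarray,
    terms: MultiplicativeTerms,
    met_env_indices: np.ndarray | None = None,
    criterion: np.ndarray | None = None,
) -> dict:
    """Genetic-progress summary for one population.

    Gain and variance are computed from the slope means and covariance
    via the covariate means (identical to the mean/variance of the
    directly computed genotype main effects); accuracies are Pearson
    correlations between the selection criterion and the true main
    effects in the TPE / MET.
    """
    slopes = np.asarray(slopes, dtype=float)
    s_bar = terms.covariate_means()
    slope_means = slopes.mean(axis=0)
    slope_cov = np.cov(slopes, rowvar=False, ddof=1).reshape(terms.k, terms.k)
    out = {
        "mu_g_tpe": float(s_bar @ slope_means),
        "var_g_tpe": float(s_bar @ slope_cov @ s_bar),
    }
    mains_tpe = slopes @ s_bar
    mains_met = None
    if met_env_indices is not None:
        s_bar_met = terms.covariates[np.asarray(met_env_indices, dtype=int)].mean(axis=0)
        mains_met = slopes @ s_bar_met
        out["mu_g_met"] = float(s_bar_met @ slope_means)
        out["var_g_met"] = float(s_bar_met @ slope_cov @ s_bar_met)
        out["alignment"] = _safe_corr(mains_met, mains_tpe)
    if criterion is not None:
        out["accuracy_tpe"] = _safe_corr(np.asarray(criterion, dtype=float), mains_tpe)
        if mains_met is not None:
            out["accuracy_met"] = _safe_corr(np.asarray(criterion, dtype=float), mains_met)
    return out


def _safe_corr(a: np.ndarray, b: np.ndarray) -> float:
    if a.size < 3 or np.std(a) == 0.0 or np.std(b) == 0.0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def run_programme(config: ProgrammeConfig, tpe_terms: MultiplicativeTerms, seed=None) -> pd.DataFrame:
    """Run the recurrent programme and return the progress trajectory.

    Per year: sample ``envs_per_year`` environments from the TPE;
    phenotype every stage in its nested environment subset; rank
    genotypes by the configured criterion; advance the top fraction to
    the next stage, cross the best advanced material and enter the new
    doubled-haploid lines at the first stage. One row of progress per
    (year, stage) is recorded before advancement.
    """
    rng = as_rng(seed)
    terms = tpe_terms
    p = terms.p
    stages = list(config.stages)
    n_stages = len(stages)

    founders = create_founders(
        config.total_genotypes, config.n_loci, config.n_chromosomes, terms, rng
    )
    # true variance components of the TPE, plugged into the CS analysis
    implied = terms.implied_covariance()
    sigma2_g_true = float(implied.mean())
    sigma2_ge_true = float(np.diag(implied).mean() - implied.mean())

    # initial pipeline: founders split across stages
    stage_pops: list[Population] = []
    start = 0
    for s in stages:
        stage_pops.append(founders.subset(np.arange(start, start + s.n_genotypes), generation="founder"))
        start += s.n_genotypes
    next_id = founders.n
    dosage_archive: dict[int, np.ndarray] = {int(i): d for i, d in zip(founders.ids, founders.dosages)}

    records: list[pd.DataFrame] = []
    progress_rows: list[dict] = []
    sampled_env_log: list[np.ndarray] = []

    for year in range(1, config.years + 1):
        envs = sample_environments(p, config.envs_per_year, rng)
        sampled_env_log.append(envs)
        tau = rng.normal(0.0, np.sqrt(config.sigma2_env), size=config.envs_per_year)

        # phenotype each stage at genotype-by-environment cell level
        year_frames = []
        for s_i, (s, pop) in enumerate(zip(stages, stage_pops)):
            env_subset = envs[: s.n_envs]
            u = pop.slopes @ terms.covariates[env_subset].T  # (n, n_envs)
            noise = rng.normal(0.0, np.sqrt(s.error_variance / s.n_reps), size=u.shape)
            y = config.trait_mean + tau[: s.n_envs][None, :] + u + noise
            frame = pd.DataFrame(
                {
                    "year": year,
                    "stage": s.name,
                    "env_id": np.tile([f"Y{year}_E{e}" for e in env_subset], pop.n),
                    "env_index": np.tile(env_subset, pop.n),
                    "genotype_id": np.repeat(pop.ids, s.n_envs),
                    "phenotype": y.ravel(),
                    "n_reps": s.n_reps,
                    "sigma2_eps": s.error_variance,
                }
            )
            year_frames.append(frame)
        records.extend(year_frames)

        # selection criterion per stage
        criteria: list[pd.Series] = []
        if config.selection == "phenotypic":
            for frame in year_frames:
                means = frame.groupby("genotype_id", sort=False)["phenotype"].mean()
                criteria.append(means)
        else:
            window = pd.concat(
                [f for f in records if f["year"].iloc[0] > year - config.met_window_years],
                ignore_index=True,
            )
            # records are cell means of n_reps plots: error variance scales accordingly
            window = window.assign(sigma2_eps=window["sigma2_eps"] / window["n_reps"])
            genotype_list = sorted(pd.unique(window["genotype_id"]))
            dosages = np.stack([dosage_archive[int(g)] for g in genotype_list])
            relationship = genomic_relationship(dosages)
            blups = predict_main_effects_cs(
                window,
                sigma2_g=sigma2_g_true,
                sigma2_ge=sigma2_ge_true,
                relationship=relationship,
                genotypes=genotype_list,
            )
            for s, pop in zip(stages, stage_pops):
                criteria.append(blups.loc[list(pop.ids)].set_axis(pop.ids))

        # track progress before advancement
        for s, pop, crit in zip(stages, stage_pops, criteria):
            entry = track_progress(
                pop.slopes, terms,
                met_env_indices=envs[: s.n_envs],
                criterion=crit.loc[list(pop.ids)].to_numpy(),
            )
            entry.update(year=year, stage=s.name, selection=config.selection)
            progress_rows.append(entry)

        # advancement: next year's stage s+1 = top of this year's stage s
        new_pops: list[Population | None] = [None] * n_stages
        for s_i in range(n_stages - 1, 0, -1):
            donor_pop, donor_crit = stage_pops[s_i - 1], criteria[s_i - 1]
            ranked = donor_crit.loc[list(donor_pop.ids)].to_numpy()
            keep = np.argsort(-ranked, kind="stable")[: stages[s_i].n_genotypes]
            new_pops[s_i] = donor_pop.subset(keep, generation=stages[s_i].name)

        # parents: best advanced material (last two stages pooled)
        parent_ids, parent_scores = [], []
        for s_i in range(max(0, n_stages - 2), n_stages):
            parent_ids.extend(stage_pops[s_i].ids)
            parent_scores.extend(criteria[s_i].loc[list(stage_pops[s_i].ids)].to_numpy())
        order = np.argsort(-np.asarray(parent_scores), kind="stable")[: config.n_parents]
        chosen = set(int(parent_ids[i]) for i in order)
        parent_pool_parts = []
        for s_i in range(n_stages):
            mask = np.isin(stage_pops[s_i].ids, list(chosen))
            if mask.any():
                parent_pool_parts.append(stage_pops[s_i].subset(np.flatnonzero(mask)))
        parent_pool = _concat_populations(parent_pool_parts)

        pairs = np.column_stack(
            [
                rng.integers(0, parent_pool.n, size=config.n_crosses),
                rng.integers(0, parent_pool.n, size=config.n_crosses),
            ]
        )
        same = pairs[:, 0] == pairs[:, 1]
        pairs[same, 1] = (pairs[same, 1] + 1) % parent_pool.n
        pairs = np.repeat(pairs, config.progeny_per_cross, axis=0)
        entry_n = stages[0].n_genotypes
        new_entry = make_crosses(
            parent_pool, entry_n, rng, parent_pairs=pairs,
            id_start=next_id, generation=stages[0].name,
        )
        next_id += entry_n
        for i, d in zip(new_entry.ids, new_entry.dosages):
            dosage_archive[int(i)] = d
        new_pops[0] = new_entry
        stage_pops = new_pops

        # drop records that fall out of every future MET window
        horizon = year + 1 - config.met_window_years
        records = [f for f in records if f["year"].iloc[0] > horizon - 1]

    out = pd.DataFrame(progress_rows)
    out.attrs["sampled_environments"] = np.concatenate(sampled_env_log)
    out.attrs["n_environment_samples"] = int(sum(len(e) for e in sampled_env_log))
    return out


def _concat_populations(pops: list[Population]) -> Population:
    if not pops:
        raise ParameterError("no parents selected")
    base = pops[0]
    return replace(
        base,
        haplotypes=np.concatenate([p.haplotypes for p in pops], axis=0),
        ids=np.concatenate([p.ids for p in pops]),
        generation="parents",
    )
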