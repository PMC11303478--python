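"""Sampling MET datasets from a simulated TPE and quantifying alignment.

A MET is a subset of p_m environments drawn uniformly without
replacement from the p TPE environments (full shuffle, prefix take).
The realised MET-TPE alignment is the Pearson correlation between
genotype main effects computed over the sampled environments and over
the whole TPE; its expectation is the r_mt of
:func:`gxesim.measures.expected_accuracies`.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateInputError, ParameterError
from .measures import AccuracySet, expected_accuracies
from .multiplicative import GEEffects, genotype_main_effects
from .rng import as_rng

__all__ = ["TPESample", "sample_environments", "empirical_alignment", "sample_met"]


@dataclass
class TPESample:
    """A sampled MET: environment indices, the GE-effect slice and annotations."""

    environment_indices: np.ndarray
    u_sampled: np.ndarray | None = None
    seed: int | None = None
    expected: AccuracySet | None = None
    realized_alignment: float | None = None

    @property
    def p_m(self) -> int:
        return self.environment_indices.size

    def manifest(self) -> dict:
        """JSON-serialisable record of the sample."""
        out = {
            "environment_indices": [int(i) for i in self.environment_indices],
            "p_m": self.p_m,
            "seed": self.seed,
            "realized_alignment": self.realized_alignment,
        }
        if self.expected is not None:
            out["expected"] = self.expected.as_dict()
        return out


def sample_environments(p: int, p_m: int, seed=None, without_replacement: bool = True) -> np.ndarray:
    """Sample p_m of p environment indices by shuffling the TPE.

    The full index vector is shuffled and the first p_m entries taken,
    so nested samples (growing p_m under the same seed) are prefixes of
    one permutation.
    """
    if not 1 <= p_m <= p:
        raise ParameterError(f"need 1 <= p_m <= p, got p_m={p_m}, p={p}")
    rng = as_rng(seed)
    if not without_replacement:
        return rng.integers(0, p, size=p_m)
    perm = rng.permutation(p)
    return perm[:p_m]


def empirical_alignment(u: GEEffects | np.ndarray, sample: TPESample | np.ndarray) -> float:
    """Pearson correlation of MET vs TPE genotype main effects."""
    values = u.values if isinstance(u, GEEffects) else np.asarray(u, dtype=float)
    idx = sample.environment_indices if isinstance(sample, TPESample) else np.asarray(sample, dtype=int)
    if values.shape[0] < 3:
        raise ParameterError("alignment needs at least 3 genotypes")
    met_means = genotype_main_effects(values, idx)
    tpe_means = genotype_main_effects(values)
    if np.std(met_means) == 0.0 or np.std(tpe_means) == 0.0:
        raise DegenerateInputError("main effects have zero variance; alignment is undefined")
    return float(np.corrcoef(met_means, tpe_means)[0, 1])


def sample_met(
    u: GEEffects | np.ndarray,
    p_m: int,
    seed=None,
    sigma2_g: float | None = None,
    sigma2_ge: float | None = None,
    sigma2_eps: float = 0.0,
    r: int = 1,
) -> TPESample:
    """Draw one MET sample and annotate it.

    Expected accuracies use the TPE-true variance components (pass
    sigma2_g / sigma2_ge from the TPE's variance decomposition), not
    quantities re-estimated from the sample.
    """
    values = u.values if isinstance(u, GEEffects) else np.asarray(u, dtype=float)
    p = values.shape[1]
    seed_int = seed if isinstance(seed, (int, np.integer)) else None
    idx = sample_environments(p, p_m, seed)
    sample = TPESample(environment_indices=idx, u_sampled=values[:, idx], seed=seed_int)
    sample.realized_alignment = empirical_alignment(values, sample)
    if sigma2_g is not None and sigma2_ge is not None:
        sample.expected = expected_accuracies(sigma2_g, sigma2_ge, sigma2_eps, p_m, r)
    return sample
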