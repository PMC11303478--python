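"""Founders, crossing, compound-symmetry BLUP and the programme loop."""
import numpy as np
import pandas as pd
import pytest

import gxesim as g
from gxesim import breeding as br
from gxesim.errors import ParameterError


@pytest.fixture(scope="module")
def none_terms():
    return g.decompose(g.scenario_covariance("none", 200), 1)


@pytest.fixture(scope="module")
def founders(low_terms):
    return g.create_founders(300, 200, 10, low_terms, seed=101)


class TestFounders:
    def test_slope_covariance_is_exactly_term_variances(self, founders, low_terms):
        slopes = founders.slopes
        np.testing.assert_allclose(slopes.mean(axis=0), 0.0, atol=1e-10)
        cov = np.cov(slopes, rowvar=False, ddof=1)
        np.testing.assert_allclose(cov, np.diag(low_terms.term_variances), atol=1e-8)

    def test_zero_variance_term_gives_zero_slopes(self):
        terms = g.MultiplicativeTerms(np.eye(4)[:, :2], np.array([2.0, 0.0]), 2.0)
        pop = g.create_founders(50, 60, 3, terms, seed=5)
        np.testing.assert_allclose(pop.slopes[:, 1], 0.0, atol=1e-12)

    def test_founder_progress_identities(self, founders, low_terms):
        entry = g.track_progress(founders.slopes, low_terms)
        mains = founders.slopes @ low_terms.covariate_means()
        assert entry["mu_g_tpe"] == pytest.approx(float(mains.mean()), abs=1e-10)
        assert entry["var_g_tpe"] == pytest.approx(float(mains.var(ddof=1)), abs=1e-10)
        assert entry["mu_g_tpe"] == pytest.approx(0.0, abs=1e-10)

    def test_dosages_are_biallelic(self, founders):
        assert set(np.unique(founders.dosages)) <= {0, 1, 2}

    def test_too_many_terms_rejected(self, low_terms):
        with pytest.raises(ParameterError):
            g.create_founders(50, 5, 2, low_terms, seed=0)


class TestCrosses:
    def test_selfing_homozygous_parent_reproduces_it(self, founders):
        pairs = np.zeros((5, 2), dtype=int)
        progeny = g.make_crosses(founders, 5, seed=7, parent_pairs=pairs)
        for i in range(5):
            np.testing.assert_array_equal(progeny.haplotypes[i], founders.haplotypes[0])

    def test_zero_crossover_rate_transmits_whole_chromosomes(self, founders):
        # on a heterozygous individual every gamete chromosome equals one strand
        het = founders.haplotypes[:1].copy()
        het[0, 1] = founders.haplotypes[1, 1]
        gamete = br._meiosis(het, founders.genome, np.random.default_rng(3), crossover_rate=0.0)
        for c in range(founders.genome.n_chromosomes):
            loci = founders.genome.chromosome == c
            matches_0 = np.array_equal(gamete[0, loci], het[0, 0, loci])
            matches_1 = np.array_equal(gamete[0, loci], het[0, 1, loci])
            assert matches_0 or matches_1

    def test_progeny_mean_slope_is_mid_parent(self, founders):
        pairs = np.tile([0, 1], (3000, 1))
        progeny = g.make_crosses(founders, 3000, seed=11, parent_pairs=pairs)
        mid = founders.slopes[:2].mean(axis=0)
        got = progeny.slopes.mean(axis=0)
        se = progeny.slopes.std(axis=0, ddof=1) / np.sqrt(3000)
        assert np.all(np.abs(got - mid) < 3 * se + 1e-12)

    def test_progeny_are_doubled_haploids(self, founders):
        progeny = g.make_crosses(founders, 10, seed=13)
        np.testing.assert_array_equal(progeny.haplotypes[:, 0], progeny.haplotypes[:, 1])

    def test_single_parent_random_crossing_rejected(self, founders):
        solo = founders.subset(np.array([0]))
        with pytest.raises(ParameterError):
            g.make_crosses(solo, 5, seed=0)


class TestGenomicRelationship:
    def test_symmetric_with_inbred_diagonal(self, founders):
        k = g.genomic_relationship(founders.dosages[:50])
        np.testing.assert_allclose(k, k.T, atol=1e-12)
        # doubled haploids are fully inbred: mean diagonal near 2
        assert k.diagonal().mean() == pytest.approx(2.0, abs=0.2)

    def test_monomorphic_markers_fall_back_to_identity(self):
        k = g.genomic_relationship(np.full((4, 10), 2.0))
        np.testing.assert_array_equal(k, np.eye(4))


class TestCompoundSymmetryBLUP:
    @staticmethod
    def _plot_data(v, p_m, rng):
        rows = []
        for i in range(v):
            for j in range(p_m):
                rows.append({"env_id": f"E{j}", "genotype_id": f"G{i}", "phenotype": rng.normal()})
        return pd.DataFrame(rows)

    def test_matches_joint_covariance_oracle(self):
        # direct GLS/BLUP on the full plot covariance matrix
        rng = np.random.default_rng(31)
        v, p_m = 5, 2
        df = self._plot_data(v, p_m, rng)
        a = rng.standard_normal((v, v))
        K = a @ a.T / v + 0.5 * np.eye(v)
        s2g, s2ge, s2e = 1.2, 0.4, 0.8
        genotypes = sorted(df["genotype_id"].unique())
        got = g.predict_main_effects_cs(df, s2g, s2ge, s2e, relationship=K,
                                        genotypes=genotypes, ridge=0.0)

        gi = pd.Index(genotypes).get_indexer(df["genotype_id"])
        ei = pd.Index(sorted(df["env_id"].unique())).get_indexer(df["env_id"])
        n = len(df)
        zg = np.zeros((n, v)); zg[np.arange(n), gi] = 1.0
        x = np.zeros((n, p_m)); x[np.arange(n), ei] = 1.0
        gamma = s2g * K
        vmat = zg @ gamma @ zg.T + (s2ge + s2e) * np.eye(n)  # one plot per cell
        vinv = np.linalg.inv(vmat)
        y = df["phenotype"].to_numpy()
        tau = np.linalg.solve(x.T @ vinv @ x, x.T @ vinv @ y)
        blup = gamma @ zg.T @ vinv @ (y - x @ tau)
        np.testing.assert_allclose(got.to_numpy(), blup, atol=1e-8)

    def test_no_genetic_variance_gives_equal_predictions(self):
        df = self._plot_data(4, 2, np.random.default_rng(37))
        got = g.predict_main_effects_cs(df, 0.0, 0.5, 1.0)
        np.testing.assert_array_equal(got.to_numpy(), 0.0)

    def test_high_signal_limit_recovers_ranking(self, low_terms):
        rng = np.random.default_rng(41)
        v, p_m = 40, 6
        slopes = g.simulate_slopes(low_terms, v, seed=43)
        u = g.construct_ge_effects(low_terms, slopes).values[:, :p_m]
        mains = u.mean(axis=1)
        rows = []
        for i in range(v):
            for j in range(p_m):
                rows.append({"env_id": f"E{j}", "genotype_id": f"G{i:02d}",
                             "phenotype": u[i, j] + rng.normal(0, 1e-4)})
        df = pd.DataFrame(rows)
        got = g.predict_main_effects_cs(df, 1.0, 0.7, 1e-8)
        from scipy.stats import spearmanr

        rho = spearmanr(got.loc[[f"G{i:02d}" for i in range(v)]].to_numpy(), mains).statistic
        assert rho > 0.95


class TestProgrammeConfig:
    def test_increasing_stage_sizes_rejected(self):
        stages = (br.StageConfig("a", 10, 1, 1, 4.0), br.StageConfig("b", 20, 1, 1, 4.0))
        with pytest.raises(ParameterError, match="non-increasing"):
            g.ProgrammeConfig(stages=stages, n_crosses=2, progeny_per_cross=5)

    def test_stage_envs_capped_by_yearly_sample(self):
        stages = (br.StageConfig("a", 10, 30, 1, 4.0),)
        with pytest.raises(ParameterError, match="sampled per year"):
            g.ProgrammeConfig(stages=stages, envs_per_year=20, n_crosses=2, progeny_per_cross=5)

    def test_cross_count_must_fill_entry_stage(self):
        with pytest.raises(ParameterError, match="entry-stage"):
            g.ProgrammeConfig(n_crosses=3, progeny_per_cross=5)


SMALL_STAGES = (
    br.StageConfig("headrow", 60, 1, 1, 4.0),
    br.StageConfig("pyt", 25, 4, 2, 4.0),
    br.StageConfig("ayt", 10, 8, 2, 4.0),
)


class TestRunProgramme:
    def test_truncation_on_true_mains_matches_breeders_equation(self, none_terms):
        # one cycle of selection on true main effects at h^2 = 1: the
        # selection differential equals i * sigma_g, with the intensity i
        # obtained from an order-statistics simulation oracle
        pop = g.create_founders(400, 200, 10, none_terms, seed=51)
        mains = pop.slopes @ none_terms.covariate_means()
        n_sel = 80
        top = np.sort(mains)[-n_sel:]
        diff = top.mean() - mains.mean()

        rng = np.random.default_rng(53)
        sims = np.sort(rng.standard_normal((2000, 400)), axis=1)[:, -n_sel:].mean(axis=1)
        assert abs(diff / mains.std(ddof=1) - sims.mean()) < 3 * sims.std(ddof=1)

    def test_selection_reduces_genetic_variance(self, founders, low_terms):
        mains = founders.slopes @ low_terms.covariate_means()
        keep = np.argsort(mains)[-150:]
        before = g.track_progress(founders.slopes, low_terms)["var_g_tpe"]
        after = g.track_progress(founders.subset(keep).slopes, low_terms)["var_g_tpe"]
        assert after < before

    def test_no_heritability_no_gain(self, low_terms):
        # with enormous plot error the selection signal vanishes and the
        # mean gain across replicates is statistically zero
        stages = tuple(br.StageConfig(s.name, s.n_genotypes, s.n_envs, s.n_reps, 1e6)
                       for s in SMALL_STAGES)
        cfg = g.ProgrammeConfig(years=8, stages=stages, n_crosses=12, progeny_per_cross=5,
                                n_parents=10, selection="phenotypic")
        gains = []
        for rep in range(5):
            out = g.run_programme(cfg, low_terms, seed=60 + rep)
            last = out[(out["year"] == 8) & (out["stage"] == "headrow")]
            gains.append(float(last["mu_g_tpe"].iloc[0]))
        gains = np.asarray(gains)
        assert abs(gains.mean()) < 3 * gains.std(ddof=1) / np.sqrt(5) + 0.05

    def test_trajectory_shape_and_env_budget(self, low_terms):
        cfg = g.ProgrammeConfig(years=5, envs_per_year=10, stages=SMALL_STAGES,
                                n_crosses=12, progeny_per_cross=5, n_parents=10)
        out = g.run_programme(cfg, low_terms, seed=71)
        assert len(out) == 5 * len(SMALL_STAGES)
        assert out.attrs["n_environment_samples"] == 50
        assert set(out["stage"]) == {"headrow", "pyt", "ayt"}

    def test_genomic_run_produces_positive_gain(self, low_terms):
        cfg = g.ProgrammeConfig(years=6, envs_per_year=10, stages=SMALL_STAGES,
                                n_crosses=12, progeny_per_cross=5, n_parents=10,
                                selection="genomic")
        out = g.run_programme(cfg, low_terms, seed=73)
        last = out[(out["year"] == 6) & (out["stage"] == "headrow")]
        assert float(last["mu_g_tpe"].iloc[0]) > 0.0
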