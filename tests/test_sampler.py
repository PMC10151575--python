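"""MCMC engines: determinism, recovery, equivalences and degenerate inputs."""

import numpy as np
import pandas as pd
import pytest

from sowpop.genotypes import genomic_relationship
from sowpop.sampler import (
    BayesMarkerThresholdModel,
    BinaryAnimalModel,
    BivariateMarkerModel,
    ChainConfig,
    _sample_liability,
)
from sowpop.synthetic import simulate_binary_trait, simulate_correlated_traits
from sowpop.varcomp import genetic_correlation


class TestChainConfig:
    def test_sample_count(self):
        cfg = ChainConfig(n_iter=1000, burn_in=200, thin=7)
        assert cfg.n_saved == (1000 - 200) // 7

    def test_presets(self):
        assert ChainConfig.gwas_default().n_iter == 50_000
        assert ChainConfig.bivariate_default().n_iter == 120_000

    def test_validation(self):
        with pytest.raises(ValueError):
            ChainConfig(n_iter=100, burn_in=100)
        with pytest.raises(ValueError):
            ChainConfig(thin=0)


class TestLiabilityAugmentation:
    def test_signs_match_phenotype(self):
        rng = np.random.default_rng(0)
        eta = rng.normal(0, 2, size=500)
        y = (rng.random(500) < 0.5).astype(int)
        l = _sample_liability(eta, y, 1.0, rng)
        assert np.all(l[y == 1] > 0)
        assert np.all(l[y == 0] < 0)

    def test_extreme_eta_finite(self):
        rng = np.random.default_rng(1)
        eta = np.array([-40.0, 40.0])
        y = np.array([1, 0])
        l = _sample_liability(eta, y, 1.0, rng)
        assert np.isfinite(l).all()
        assert l[0] > 0 and l[1] < 0


@pytest.fixture(scope="module")
def small_trait():
    return simulate_binary_trait(n=1000, p=400, n_qtl=15, h2=0.4, seed=31, n_chromosomes=4)


class TestThresholdMarkerModel:
    def test_seeded_determinism(self, small_trait):
        geno, y, hyq, _ = small_trait
        runs = [
            BayesMarkerThresholdModel(
                prior="bayes_c", pi="estimate", n_iter=300, burn_in=100, thin=5, seed=42
            ).fit(geno, y, hyq=hyq)
            for _ in range(2)
        ]
        assert np.array_equal(runs[0].chain_.effects, runs[1].chain_.effects)
        assert np.array_equal(runs[0].chain_.var_genetic, runs[1].chain_.var_genetic)
        assert runs[0].pi_mean_ == runs[1].pi_mean_

    def test_null_trait_low_variance(self):
        # pure-noise phenotype with near-total exclusion prior
        geno, y, hyq, _ = simulate_binary_trait(
            n=1000, p=500, n_qtl=10, h2=0.0, seed=33, n_chromosomes=5
        )
        m = BayesMarkerThresholdModel(
            prior="bayes_b", pi=1 - 1e-9, n_iter=600, burn_in=200, thin=5, seed=34
        ).fit(geno, y, hyq=hyq)
        assert m.h2_mean_ < 0.05

    def test_recovery_moderate_scale(self, small_trait):
        geno, y, hyq, truth = small_trait
        m = BayesMarkerThresholdModel(
            prior="bayes_c", pi="estimate", n_iter=1500, burn_in=400, thin=5, seed=35
        ).fit(geno, y, hyq=hyq)
        assert m.h2_mean_ == pytest.approx(truth["h2_realized"], abs=0.12)

    def test_pi_recovery_and_null(self):
        geno, y, hyq, _ = simulate_binary_trait(
            n=1500, p=600, n_qtl=10, h2=0.4, seed=36, n_chromosomes=5
        )
        m = BayesMarkerThresholdModel(
            prior="bayes_c", pi="estimate", n_iter=1200, burn_in=300, thin=5, seed=37
        ).fit(geno, y, hyq=hyq)
        assert 0.9 <= m.pi_mean_ <= 1.0
        geno0, y0, hyq0, _ = simulate_binary_trait(
            n=1000, p=500, n_qtl=10, h2=0.0, seed=38, n_chromosomes=5
        )
        m0 = BayesMarkerThresholdModel(
            prior="bayes_c", pi="estimate", n_iter=800, burn_in=200, thin=5, seed=39
        ).fit(geno0, y0, hyq=hyq0)
        assert m0.pi_mean_ > 0.9

    def test_marker_permutation_invariance(self, small_trait):
        geno, y, hyq, _ = small_trait
        m1 = BayesMarkerThresholdModel(
            prior="bayes_c0", n_iter=800, burn_in=200, thin=5, seed=40
        ).fit(geno.dose_matrix(), y, hyq=hyq)
        rng = np.random.default_rng(41)
        perm = rng.permutation(geno.n_markers)
        m2 = BayesMarkerThresholdModel(
            prior="bayes_c0", n_iter=800, burn_in=200, thin=5, seed=40
        ).fit(geno.dose_matrix()[:, perm], y, hyq=hyq)
        assert m1.h2_mean_ == pytest.approx(m2.h2_mean_, abs=0.05)

    def test_mixture_prior_with_full_inclusion_matches_bayes_c0(self, small_trait):
        # pi -> 0 with a common effect variance forces every marker in: the
        # mixture model collapses onto Bayes-C0 up to Monte-Carlo error
        geno, y, hyq, _ = small_trait
        mb = BayesMarkerThresholdModel(
            prior="bayes_c", pi=1e-9, n_iter=1000, burn_in=300, thin=5, seed=44
        ).fit(geno, y, hyq=hyq)
        mc = BayesMarkerThresholdModel(
            prior="bayes_c0", n_iter=1000, burn_in=300, thin=5, seed=45
        ).fit(geno, y, hyq=hyq)
        assert np.all(mb.chain_.include == 1)
        assert mb.h2_mean_ == pytest.approx(mc.h2_mean_, abs=0.07)
        # posterior-mean genetic values agree closely across the two priors
        corr = np.corrcoef(mb.predict(geno), mc.predict(geno))[0, 1]
        assert corr > 0.95

    def test_constant_phenotype_rejected(self, small_trait):
        geno, y, hyq, _ = small_trait
        with pytest.raises(ValueError, match="threshold"):
            BayesMarkerThresholdModel(n_iter=10, burn_in=1).fit(
                geno, np.ones_like(y), hyq=hyq
            )

    def test_empty_hyq_level_rejected(self, small_trait):
        geno, y, _, _ = small_trait
        labels = pd.Categorical(
            ["a"] * len(y), categories=["a", "ghost"]
        )
        with pytest.raises(ValueError, match="ghost"):
            BayesMarkerThresholdModel(n_iter=10, burn_in=1).fit(geno, y, hyq=labels)

    def test_sample_count_and_pip_range(self, fitted_small_chain):
        _, _, _, _, model = fitted_small_chain
        chain = model.chain_
        assert chain.n_saved == (1200 - 300) // 5
        assert np.all((chain.pip >= 0) & (chain.pip <= 1))
        assert np.all(chain.var_genetic >= 0)


class TestBivariateModel:
    def test_duplicated_trait_high_rg(self):
        geno, Y, hyq, _ = simulate_correlated_traits(
            n=600, p=300, rg=1.0, overlap=1.0, seed=50
        )
        Y[:, 1] = Y[:, 0]
        m = BivariateMarkerModel(n_iter=800, burn_in=200, thin=5, seed=51).fit(
            geno, Y, hyq=hyq
        )
        assert np.mean(m.rg_samples_ > 0.95) > 0.9

    def test_missing_modes(self):
        geno, Y, hyq, _ = simulate_correlated_traits(
            n=500, p=200, rg=0.7, overlap=0.4, seed=52
        )
        m = BivariateMarkerModel(
            n_iter=400, burn_in=100, thin=5, seed=53, missing="complete"
        ).fit(geno, Y, hyq=hyq)
        assert m.chain_.cov_genetic.shape[1:] == (2, 2)
        Y0 = np.column_stack([np.ones(Y.shape[0]), np.full(Y.shape[0], np.nan)])
        Y0[0, 1] = 1.0  # only one sow observed on both traits
        with pytest.raises(ValueError, match="fewer than 2"):
            BivariateMarkerModel(n_iter=50, burn_in=10, missing="complete").fit(
                geno, Y0, hyq=hyq
            )

    def test_covariance_samples_psd(self):
        geno, Y, hyq, _ = simulate_correlated_traits(
            n=500, p=200, rg=0.7, overlap=0.5, seed=54
        )
        m = BivariateMarkerModel(n_iter=400, burn_in=100, thin=5, seed=55).fit(
            geno, Y, hyq=hyq
        )
        for cov in (m.chain_.cov_genetic, m.chain_.cov_residual):
            for s in cov:
                sym = 0.5 * (s + s.T)
                np.linalg.cholesky(sym + 1e-10 * np.eye(2))

    def test_determinism(self):
        geno, Y, hyq, _ = simulate_correlated_traits(
            n=400, p=150, rg=0.7, overlap=0.5, seed=56
        )
        runs = [
            BivariateMarkerModel(n_iter=300, burn_in=100, thin=5, seed=57).fit(
                geno, Y, hyq=hyq
            )
            for _ in range(2)
        ]
        assert np.array_equal(runs[0].chain_.cov_genetic, runs[1].chain_.cov_genetic)


class TestAnimalModel:
    def test_id_mismatch_error(self, small_trait):
        geno, y, hyq, _ = small_trait
        G = genomic_relationship(geno)
        bad_ids = ["nope1", "nope2"] + list(geno.ids[2:])
        with pytest.raises(ValueError, match="nope1"):
            BinaryAnimalModel(n_iter=10, burn_in=1).fit(G, y, hyq=hyq, ids=bad_ids)

    def test_degenerate_groups_rejected(self):
        K = np.eye(40)
        y = np.r_[np.ones(20, dtype=int), np.zeros(20, dtype=int)]
        hyq = ["g1"] * 20 + ["g2"] * 20  # phenotype constant within every group
        with pytest.raises(ValueError, match="constant within"):
            BinaryAnimalModel(n_iter=10, burn_in=1).fit(K, y, hyq=hyq)

    def test_seeded_determinism(self, small_trait):
        geno, y, hyq, _ = small_trait
        G = genomic_relationship(geno)
        runs = [
            BinaryAnimalModel(
                link="PROBIT", n_iter=300, burn_in=100, thin=5, seed=60
            ).fit(G, y, hyq=hyq)
            for _ in range(2)
        ]
        assert np.array_equal(runs[0].chain_.var_genetic, runs[1].chain_.var_genetic)

    def test_logit_scale_larger_variance(self, small_trait):
        # same data: logit-scale genetic variance ~ pi^2/3 times the probit one,
        # so the heritability estimates should roughly agree across links
        geno, y, hyq, _ = small_trait
        G = genomic_relationship(geno)
        h2 = {}
        for link in ("PROBIT", "LOGIT"):
            m = BinaryAnimalModel(
                link=link, n_iter=1200, burn_in=300, thin=5, seed=61
            ).fit(G, y, hyq=hyq)
            h2[link] = m.h2_mean_
        assert h2["PROBIT"] == pytest.approx(h2["LOGIT"], abs=0.08)

    def test_gblup_equivalence_with_bayes_c0(self, small_trait):
        geno, y, hyq, _ = small_trait
        G = genomic_relationship(geno)
        am = BinaryAnimalModel(
            link="PROBIT", n_iter=1500, burn_in=400, thin=5, seed=62
        ).fit(G, y, hyq=hyq)
        mk = BayesMarkerThresholdModel(
            prior="bayes_c0", n_iter=1500, burn_in=400, thin=5, seed=63
        ).fit(geno, y, hyq=hyq)
        assert am.h2_mean_ == pytest.approx(mk.h2_mean_, abs=0.05)


class TestChainPersistence:
    def test_tsv_and_cache_roundtrip(self, fitted_small_chain, tmp_path):
        _, _, _, _, model = fitted_small_chain
        model.chain_.save(tmp_path / "chain")
        assert (tmp_path / "chain.tsv").exists()
        back = type(model.chain_).load(tmp_path / "chain")
        assert np.array_equal(back.var_genetic, model.chain_.var_genetic)
        assert np.array_equal(back.effects, model.chain_.effects)
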