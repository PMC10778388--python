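import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import multivariate_normal

import gselect as gs
from gselect.bayes import DESK_MCMC, MCMCSettings

SMALL = dict(iterations=2100, burn_in=100, thinning=10)


class TestSettings:
    def test_production_retention_arithmetic(self):
        s = MCMCSettings()
        assert (s.iterations, s.burn_in, s.thinning) == (41000, 1000, 100)
        assert s.n_retained == 400

    def test_invalid_settings(self):
        with pytest.raises(ValueError):
            MCMCSettings(iterations=100, burn_in=200)
        with pytest.raises(ValueError):
            MCMCSettings(thinning=0)

    def test_retained_sample_count_honoured(self, qtl_fixture):
        _, Z, yc, _ = qtl_fixture
        st = MCMCSettings(seed=1, **SMALL)
        post, _ = gs.run_bayesb(yc, Z[:, :50], None, st)
        assert post.samples.shape == (st.n_retained, 50)

    def test_degenerate_pi_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            gs.BayesBPrior(pi=1.0)


class TestReproducibility:
    @pytest.mark.parametrize("runner", [gs.run_bayesb, gs.run_bayeslasso, gs.run_bayesr])
    def test_bit_reproducible(self, runner, qtl_fixture):
        _, Z, yc, _ = qtl_fixture
        st = MCMCSettings(seed=42, **SMALL)
        p1, r1 = runner(yc, Z[:, :80], None, st)
        p2, r2 = runner(yc, Z[:, :80], None, st)
        assert (p1.samples == p2.samples).all()
        assert (r1.gebv == r2.gebv).all()


class TestPlantedQTL:
    def test_all_samplers_rank_causal_snp_first(self, qtl_fixture):
        _, Z, yc, q = qtl_fixture
        st = MCMCSettings(seed=3, **SMALL)
        for runner in (gs.run_bayesb, gs.run_bayeslasso, gs.run_bayesr):
            post, _ = runner(yc, Z, None, st)
            rank = int((np.abs(post.effect_mean) >= abs(post.effect_mean[q])).sum())
            assert rank <= 5, runner.__name__

    def test_bayesb_inclusion_peaks_at_qtl(self, qtl_fixture):
        _, Z, yc, q = qtl_fixture
        post, _ = gs.run_bayesb(yc, Z, None, MCMCSettings(seed=4, **SMALL))
        assert post.inclusion[q] == post.inclusion.max()
        assert post.inclusion[q] > 0.9

    def test_permuted_phenotypes_lose_signal(self, qtl_fixture):
        _, Z, yc, _ = qtl_fixture
        rng = np.random.default_rng(5)
        yp = pd.Series(rng.permutation(yc.to_numpy()), index=yc.index)
        st = MCMCSettings(seed=6, **SMALL)
        post_sig, _ = gs.run_bayeslasso(yc, Z, None, st)
        post_nul, _ = gs.run_bayeslasso(yp, Z, None, st)
        assert np.abs(post_nul.effect_mean).mean() < np.abs(post_sig.effect_mean).mean()
        assert abs(post_nul.effect_mean.mean()) < 3 * post_nul.effect_mean.std()


class TestNullCalibration:
    def test_bayesb_null_inclusion_rate(self):
        gm, _ = gs.simulate_genotypes(500, 1000, seed=8)
        Z = gs.centered_dosages(gm)
        rng = np.random.default_rng(9)
        yc = pd.Series(rng.normal(0, 1, 500), index=gm.animal_ids)
        post, _ = gs.run_bayesb(yc, Z, None, MCMCSettings(seed=10, **SMALL))
        assert (post.inclusion > 0.5).mean() <= 0.01

    def test_bayesr_null_vs_signal_genomic_variance(self):
        # a pure-noise phenotype yields a small fraction of the genomic
        # variance fitted to a genuinely heritable one on the same panel
        gm, _ = gs.simulate_genotypes(500, 1000, seed=11)
        Z = gs.centered_dosages(gm)
        rng = np.random.default_rng(12)
        y_null = pd.Series(rng.normal(0, 1, 500), index=gm.animal_ids)
        spec = gs.TraitSpec("gl", mean=50.0, sd=1.0, h2=0.4, min_value=0,
                            max_value=100, fixed_fraction=0.0)
        ds = gs.simulate_trait(gm, None, spec, seed=13)
        y_sig = ds.phenotypes.frame.set_index("animal_id")["gl"]
        y_sig = y_sig - y_sig.mean()
        _, pred_null = gs.run_bayesr(y_null, Z, None, MCMCSettings(seed=13, **SMALL))
        _, pred_sig = gs.run_bayesr(y_sig, Z, None, MCMCSettings(seed=13, **SMALL))
        assert pred_null.sigma_g2_hat < 0.5 * pred_sig.sigma_g2_hat
        # variance conservation: genomic + residual recovers the total
        total = pred_null.sigma_g2_hat + pred_null.sigma_e2_hat
        assert total == pytest.approx(float(y_null.var()), rel=0.10)


class TestShrinkageLimits:
    def test_lasso_infinite_penalty_kills_effects(self, qtl_fixture):
        _, Z, yc, _ = qtl_fixture
        prior = gs.BayesLassoPrior(lambda2=1e10, sample_lambda=False)
        post, _ = gs.run_bayeslasso(yc, Z[:, :100], prior, MCMCSettings(seed=14, **SMALL))
        assert np.abs(post.effect_mean).max() < 1e-3


class TestGenomicVariance:
    def test_zero_effects(self):
        Z = np.random.default_rng(0).normal(size=(20, 5))
        assert gs.genomic_variance_from_samples(np.zeros((10, 5)), Z) == 0.0

    def test_single_snp_unit_effect(self):
        rng = np.random.default_rng(1)
        z = rng.normal(size=(50, 1))
        samples = np.ones((4, 1))
        expected = np.var(z[:, 0], ddof=1)
        assert gs.genomic_variance_from_samples(samples, z) == pytest.approx(expected)

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            gs.genomic_variance_from_samples(np.zeros((1, 3)), np.zeros((5, 3)))

    def test_agrees_with_sum2pq_estimator(self, qtl_fixture):
        gm, Z, yc, _ = qtl_fixture
        post, pred = gs.run_bayesr(yc, Z, None, MCMCSettings(seed=15, **SMALL))
        alt = gs.genomic_variance_sum2pq(post.samples, gm.allele_freq())
        assert pred.sigma_g2_hat == pytest.approx(alt, rel=0.10)


class TestExactPosterior:
    def test_bayesr_components_match_enumerated_posterior(self):
        """Marginal component posteriors on a 2-SNP, 10-animal toy agree with
        brute-force enumeration of all 16 component configurations."""
        rng = np.random.default_rng(4)
        n = 10
        z1, z2 = rng.normal(0, 1, n), rng.normal(0, 1, n)
        y = 0.8 * z1 + rng.normal(0, 0.5, n)
        y = y - y.mean()
        gam = np.array([0.0, 1e-4, 1e-3, 1e-2])
        sigg, sige = 100.0, 0.25
        pi = np.full(4, 0.25)
        logp = {}
        for c1, c2 in itertools.product(range(4), repeat=2):
            V = sige * np.eye(n) + gam[c1] * sigg * np.outer(z1, z1) \
                + gam[c2] * sigg * np.outer(z2, z2)
            logp[(c1, c2)] = np.log(pi[c1] * pi[c2]) + \
                multivariate_normal.logpdf(y, np.zeros(n), V)
        mx = max(logp.values())
        norm = sum(np.exp(v - mx) for v in logp.values())
        post_exact = {k: np.exp(v - mx) / norm for k, v in logp.items()}
        marg = np.array([
            [sum(post_exact[(c1, c2)] for c2 in range(4)) for c1 in range(4)],
            [sum(post_exact[(c1, c2)] for c1 in range(4)) for c2 in range(4)]])

        prior = gs.BayesRPrior(proportions=(0.25,) * 4, genetic_variance=sigg,
                               sample_sigma_g2=False, sample_proportions=False,
                               sample_mu=False, sample_sigma_e2=False, sigma_e2=sige)
        post, _ = gs.run_bayesr(pd.Series(y), np.column_stack([z1, z2]), prior,
                                MCMCSettings(iterations=42000, burn_in=2000,
                                             thinning=2, seed=9))
        for j in range(2):
            tv = 0.5 * np.abs(marg[j] - post.component_probs[j]).sum()
            assert tv < 0.05

    def test_multipliers_echoed(self, qtl_fixture):
        _, Z, yc, _ = qtl_fixture
        post, _ = gs.run_bayesr(yc, Z[:, :40], None, MCMCSettings(seed=16, **SMALL))
        assert post.extras["multipliers"] == (0.0, 1e-4, 1e-3, 1e-2)
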