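import numpy as np
import pytest
from scipy.special import digamma

from mirbayes import (
    DirichletParams,
    NIGParams,
    PriorBundle,
    VBEMConfig,
    VerifiedExpressionSet,
    elbo,
    nig_posterior_update,
    vbe_step,
    vbem_fit,
    vbm_step,
)

from oracles import mixture_log_evidence


def _flat_bundle(mu_pos=-2.0, mu_neg=2.0, eps=1e-8):
    """Nearly improper NIG priors (location only breaks init symmetry)."""
    return PriorBundle(
        positive=NIGParams(mu_pos, eps, eps, eps),
        negative=NIGParams(mu_neg, eps, eps, eps),
        weights=DirichletParams(1.0, 1.0),
    )


class TestVBEStep:
    def test_symmetric_state_gives_half(self):
        r = vbe_step(np.array([0.0]), NIGParams(-1.0, 10, 5, 5), NIGParams(1.0, 10, 5, 5),
                     DirichletParams(7.0, 7.0))
        assert r[0] == pytest.approx(0.5, abs=1e-12)

    def test_identical_components_reduce_to_weight_softmax(self):
        q = NIGParams(0.0, 10.0, 5.0, 5.0)
        w = DirichletParams(200.0, 20000.0)
        r = vbe_step(np.array([-1.0, 0.0, 2.0]), q, q, w)
        expected = 1.0 / (1.0 + np.exp(digamma(20000.0) - digamma(200.0)))
        assert r == pytest.approx(expected, abs=1e-12)

    def test_dominance_limit(self):
        # e at the positive mean with tiny variance, far from the negative
        q_pos = NIGParams(-3.0, 1e4, 1e4, 1.0)  # var concentrated near 1e-4
        q_neg = NIGParams(10.0, 1e4, 1e4, 1e4)
        r = vbe_step(np.array([-3.0]), q_pos, q_neg, DirichletParams(1.0, 1.0))
        assert r[0] > 1.0 - 1e-12

    def test_responsibilities_in_unit_interval(self, study_fit):
        r = study_fit.responsibilities
        assert np.all(r >= 0.0) and np.all(r <= 1.0)
        assert np.all(np.isfinite(r))


class TestVBMStep:
    def test_zero_responsibilities_leave_positive_prior_unchanged(self, default_priors):
        e = np.array([-0.5, 0.2, 0.3])
        q_pos, q_neg, _ = vbm_step(e, np.zeros(3), default_priors)
        assert q_pos == default_priors.positive
        assert q_neg != default_priors.negative

    def test_hard_assignment_reduces_to_conjugate_update(self, default_priors):
        rng = np.random.default_rng(8)
        e = rng.normal(0, 1, 30)
        r = (e < 0).astype(float)
        q_pos, q_neg, _ = vbm_step(e, r, default_priors)
        ref_pos = nig_posterior_update(default_priors.positive, VerifiedExpressionSet(e[e < 0]))
        ref_neg = nig_posterior_update(default_priors.negative, VerifiedExpressionSet(e[e >= 0]))
        for got, ref in ((q_pos, ref_pos), (q_neg, ref_neg)):
            for f in ("mu", "kappa", "alpha", "beta"):
                assert getattr(got, f) == pytest.approx(getattr(ref, f), rel=1e-10)

    def test_dirichlet_mass_conserved(self, default_priors):
        rng = np.random.default_rng(9)
        e = rng.normal(0, 1, 100)
        r = rng.random(100)
        _, _, q_w = vbm_step(e, r, default_priors)
        total = default_priors.weights.gamma_pos + default_priors.weights.gamma_neg + 100
        assert q_w.gamma_pos + q_w.gamma_neg == pytest.approx(total, rel=1e-12)
        assert q_w.gamma_pos == pytest.approx(200.0 + r.sum(), rel=1e-12)


class TestVBEMFit:
    def test_elbo_trace_non_decreasing(self, study_fit):
        trace = np.asarray(study_fit.elbo_trace)
        diffs = np.diff(trace)
        assert np.all(diffs >= -1e-8 * np.abs(trace[:-1]))
        assert study_fit.converged

    def test_degenerate_state_has_lower_elbo_than_optimum(self, study_fit, default_priors):
        e = np.asarray([-0.5, 0.0, 0.4, -1.2, 0.8, 0.1])
        fit = vbem_fit(e, default_priors)
        bad_pos = NIGParams(40.0, 1e5, 1e5, 1e5)  # point mass far from the data
        bad = elbo(e, fit.responsibilities, bad_pos, fit.negative, fit.weights, default_priors)
        good = elbo(e, fit.responsibilities, fit.positive, fit.negative, fit.weights, default_priors)
        assert bad < good

    def test_well_separated_components_recovered(self):
        rng = np.random.default_rng(21)
        n = 1000
        e = np.concatenate([rng.normal(-10, np.sqrt(0.1), n), rng.normal(10, np.sqrt(0.1), n)])
        fit = vbem_fit(e, _flat_bundle(mu_pos=-10.0, mu_neg=10.0))
        th = fit.theta_hat
        # responsibilities match a nearest-mean classifier
        assert np.all(fit.responsibilities[:n] > 0.999)
        assert np.all(fit.responsibilities[n:] < 0.001)
        # point estimates within 2% of per-cluster sample moments
        assert th.mu_pos == pytest.approx(e[:n].mean(), rel=0.02)
        assert th.mu_neg == pytest.approx(e[n:].mean(), rel=0.02)
        assert th.var_pos == pytest.approx(e[:n].var(), rel=0.02)
        assert th.var_neg == pytest.approx(e[n:].var(), rel=0.02)
        assert th.pi_pos == pytest.approx(0.5, abs=0.01)

    def test_vanishing_priors_match_classical_em(self):
        sklearn = pytest.importorskip("sklearn.mixture")
        rng = np.random.default_rng(4)
        e = np.concatenate(
            [rng.normal(-2, 1.0, 2500), rng.normal(2, 1.2, 2500)]
        )
        fit = vbem_fit(e, _flat_bundle(), VBEMConfig(elbo_rel_tol=1e-12, max_iter=2000))
        gm = sklearn.GaussianMixture(
            n_components=2, covariance_type="full", tol=1e-10, max_iter=2000,
            means_init=[[-2.0], [2.0]], reg_covar=0.0,
        ).fit(e.reshape(-1, 1))
        th = fit.theta_hat
        assert th.mu_pos == pytest.approx(gm.means_[0, 0], rel=0.01)
        assert th.mu_neg == pytest.approx(gm.means_[1, 0], rel=0.01)
        assert th.var_pos == pytest.approx(gm.covariances_[0, 0, 0], rel=0.01)
        assert th.var_neg == pytest.approx(gm.covariances_[1, 0, 0], rel=0.01)
        assert th.pi_pos == pytest.approx(gm.weights_[0], rel=0.01)

    def test_single_population_weight_stays_near_prior_mean(self):
        # all data from the negative population: the Dirichlet prior
        # (200, 20000) should pin the positive weight near its prior mean
        prior_mean = 200.0 / 20200.0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            e = rng.normal(0.0, np.sqrt(0.4), 20_000)
            fit = vbem_fit(e, PriorBundle(
                positive=NIGParams(-0.5, 209.2, 104.7, 50.0),
                negative=NIGParams(0.0, 0.2, 0.2, 0.2),
                weights=DirichletParams(200.0, 20000.0),
            ))
            assert fit.theta_hat.pi_pos <= prior_mean * 1.5

    def test_elbo_below_log_evidence_quadrature(self):
        rng = np.random.default_rng(13)
        e = np.concatenate([rng.normal(-1, np.sqrt(0.3), 10), rng.normal(1, np.sqrt(0.3), 10)])
        prior_pos = (-1.0, 2.0, 3.0, 2.0)
        prior_neg = (1.0, 2.0, 3.0, 2.0)
        dirichlet = (2.0, 2.0)
        priors = PriorBundle(
            positive=NIGParams(*prior_pos),
            negative=NIGParams(*prior_neg),
            weights=DirichletParams(*dirichlet),
        )
        fit = vbem_fit(e, priors)
        log_z = mixture_log_evidence(e, prior_pos, prior_neg, dirichlet,
                                     n_mu=30, n_v=30, n_pi=41)
        assert fit.elbo_trace[-1] <= log_z + 0.1  # margin covers grid error

    @pytest.mark.parametrize("bad", [np.array([1.0]), np.array([0.0, np.nan])])
    def test_invalid_input_rejected(self, bad, default_priors):
        with pytest.raises(ValueError):
            vbem_fit(bad, default_priors)
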