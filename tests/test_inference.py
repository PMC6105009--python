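import math

import numpy as np
import pytest
from scipy import stats as sps
from scipy.integrate import quad

from relsal.inference import (
    MODEL_SPACE,
    FitOptions,
    ModelSpec,
    ParamPrior,
    default_priors,
    fit_cohort,
    laplace_evidence,
    log_joint,
    map_fit,
    model_by_id,
    neg_free_energy,
)
from relsal.response import RespParams
from relsal.stats import preprocess_rts
from relsal.task import simulate_subject


def fixed(prior: ParamPrior, native_value: float) -> ParamPrior:
    return ParamPrior(prior.transform, prior.from_native(native_value), 0.0)


def beta0_only_priors(zeta=0.04, omega=-2.0, sigma2_0=0.05, m0=6.0, v0=4.0):
    """Priors pinning everything except the intercept: a conjugate 1-D model."""
    pri = default_priors()
    pri["omega"] = fixed(pri["omega"], omega)
    pri["sigma2_0"] = fixed(pri["sigma2_0"], sigma2_0)
    pri["zeta"] = fixed(pri["zeta"], zeta)
    for b in ("beta1", "beta2", "beta3", "beta4", "beta5", "beta6"):
        pri[b] = ParamPrior("identity", 0.0, 0.0)
    pri["beta0"] = ParamPrior("identity", m0, v0)
    return pri


class TestModelSpace:
    def test_sixteen_models(self):
        assert len(MODEL_SPACE) == 16
        assert MODEL_SPACE[0].id == "2HGF-BL"
        assert model_by_id("3HGFprecfb-RelPE+IrrelBias") == MODEL_SPACE[-1]
        with pytest.raises(KeyError):
            model_by_id("4HGF-BL")


class TestLogJoint:
    def test_matches_independent_density_sum(self, default_task, sim_behavior, full_model):
        """Brute-force oracle: likelihood + prior terms recomposed from
        scipy densities and an independent trajectory/prediction pass."""
        from relsal.hgf import LearnParams, run_two_branch
        from relsal.response import predict_logrt

        pri = default_priors()
        est = {
            "omega": -2.3, "sigma2_0": math.log(0.04), "zeta": math.log(0.05),
            "beta0": 6.1, "beta1": 0.15, "beta2": 0.02, "beta3": -0.01,
            "beta4": 0.0, "beta5": 0.03, "beta6": 0.06,
        }
        got = log_joint(est, sim_behavior, default_task, full_model, pri)
        traj = run_two_branch(
            default_task, LearnParams(omega=-2.3, sigma2_0=0.04, variant="2HGF")
        )
        resp = RespParams(
            beta0=6.1, beta1=0.15, beta2=0.02, beta3=-0.01, beta4=0.0, beta5=0.03,
            beta6=0.06, zeta=0.05, variant="RelPE+IrrelBias",
        )
        pred = predict_logrt(traj, default_task, resp)
        v = sim_behavior["valid"].to_numpy()
        oracle = sps.norm.logpdf(
            sim_behavior["log_rt"].to_numpy()[v], pred[v], math.sqrt(0.05)
        ).sum()
        oracle += sum(
            sps.norm.logpdf(est[n], pri[n].mean, math.sqrt(pri[n].var)) for n in est
        )
        assert got == pytest.approx(float(oracle), rel=1e-10)

    def test_flat_priors_leave_likelihood_differences(
        self, default_task, sim_behavior, full_model
    ):
        """With huge prior variances, log-joint differences equal response
        log-likelihood differences (the prior is locally constant)."""
        from relsal.hgf import LearnParams, run_two_branch
        from relsal.response import predict_logrt, response_loglik

        pri = default_priors()
        for n in pri:
            pri[n] = ParamPrior(pri[n].transform, pri[n].mean, 1e10)
        base = {n: pri[n].mean for n in pri}
        alt = dict(base, beta0=base["beta0"] + 0.05, omega=base["omega"] + 0.5)
        d_joint = log_joint(alt, sim_behavior, default_task, full_model, pri) - log_joint(
            base, sim_behavior, default_task, full_model, pri
        )

        def loglik(est):
            traj = run_two_branch(
                default_task,
                LearnParams(
                    omega=est["omega"], sigma2_0=math.exp(est["sigma2_0"]), variant="2HGF"
                ),
            )
            resp = RespParams(
                **{k: est[k] for k in (
                    "beta0", "beta1", "beta2", "beta3", "beta4", "beta5", "beta6")},
                zeta=math.exp(est["zeta"]), variant="RelPE+IrrelBias",
            )
            pred = predict_logrt(traj, default_task, resp)
            return response_loglik(
                sim_behavior["log_rt"].to_numpy(), pred, math.exp(est["zeta"]),
                valid=sim_behavior["valid"].to_numpy(),
            )

        assert d_joint == pytest.approx(loglik(alt) - loglik(base), abs=1e-6)

    def test_parameter_mismatch_rejected(self, default_task, sim_behavior, full_model):
        with pytest.raises(ValueError):
            log_joint({"omega": -2.0}, sim_behavior, default_task, full_model)


class TestMapFit:
    def test_noiseless_recovery(self, default_task, full_model):
        from relsal.hgf import LearnParams

        learn = LearnParams(omega=-2.0, sigma2_0=0.05, variant="2HGF")
        resp = RespParams(
            beta0=6.25, beta1=0.2, beta2=0.05, beta3=0.0, beta4=0.03, beta5=0.01,
            beta6=0.07, zeta=1e-8, variant="RelPE+IrrelBias",
        )
        beh = preprocess_rts(simulate_subject(default_task, full_model, learn, resp, seed=3))
        fit = map_fit(beh, default_task, full_model, options=FitOptions(n_starts=3, seed=0))
        assert fit.map_params["omega"] == pytest.approx(-2.0, abs=0.05)
        assert fit.map_params["beta1"] == pytest.approx(0.2, abs=0.01)
        assert fit.map_params["beta6"] == pytest.approx(0.07, abs=0.005)
        # within-feature differences are the identified quantities
        assert fit.map_params["beta2"] - fit.map_params["beta3"] == pytest.approx(
            0.05, abs=0.01
        )

    def test_intercept_only_fit_is_precision_weighted_mean(
        self, default_task, sim_behavior, full_model
    ):
        """Conjugate closed form: with only beta0 free the MAP is the
        precision-weighted combination of prior mean and data mean."""
        zeta, m0, v0 = 0.04, 6.0, 4.0
        pri = beta0_only_priors(zeta=zeta, m0=m0, v0=v0)
        fit = map_fit(sim_behavior, default_task, full_model, priors=pri)
        y = sim_behavior.loc[sim_behavior["valid"], "log_rt"].to_numpy()
        n = y.size
        expected = (y.sum() / zeta + m0 / v0) / (n / zeta + 1 / v0)
        assert fit.free_names == ("beta0",)
        assert fit.map_params["beta0"] == pytest.approx(expected, rel=1e-9)

    def test_seeded_determinism(self, default_task, sim_behavior, full_model):
        opts = FitOptions(n_starts=3, seed=9)
        a = map_fit(sim_behavior, default_task, full_model, options=opts)
        b = map_fit(sim_behavior, default_task, full_model, options=opts)
        np.testing.assert_array_equal(a.map_est, b.map_est)
        assert a.neg_free_energy == b.neg_free_energy


class TestLaplaceEvidence:
    def test_conjugate_1d_closed_form(self, default_task, sim_behavior, full_model):
        """For the intercept-only model the marginal likelihood is Gaussian
        and the Laplace approximation must be exact to <= 1e-6."""
        zeta, m0, v0 = 0.04, 6.0, 4.0
        pri = beta0_only_priors(zeta=zeta, m0=m0, v0=v0)
        fit = map_fit(sim_behavior, default_task, full_model, priors=pri)
        y = sim_behavior.loc[sim_behavior["valid"], "log_rt"].to_numpy()
        n = y.size
        cov = zeta * np.eye(n) + v0 * np.ones((n, n))
        oracle = sps.multivariate_normal.logpdf(y, mean=np.full(n, m0), cov=cov)
        assert fit.neg_free_energy == pytest.approx(float(oracle), abs=1e-6)
        assert neg_free_energy(fit) == pytest.approx(fit.neg_free_energy)

    def test_shift_additivity(self):
        H = np.array([[3.0, 0.2], [0.2, 2.0]])
        base, _ = laplace_evidence(10.0, H)
        shifted, _ = laplace_evidence(10.0 + 2.5, H)
        assert shifted - base == pytest.approx(2.5)

    def test_nonpositive_hessian_flags_warning(self):
        H = np.array([[1.0, 0.0], [0.0, -0.5]])
        _, warned = laplace_evidence(0.0, H)
        assert warned

    def test_prior_width_effect_matches_quadrature(
        self, default_task, sim_behavior, full_model
    ):
        """1-D quadrature oracle: narrowing the intercept prior away from the
        likelihood peak lowers the evidence, and Laplace tracks the exact
        value under both widths."""
        y = sim_behavior.loc[sim_behavior["valid"], "log_rt"].to_numpy()
        zeta = 0.04
        # prior centered away from the data mean so the width matters
        m0 = float(y.mean()) - 1.0
        results = []
        for v0 in (1.0, 0.5):
            pri = beta0_only_priors(zeta=zeta, m0=m0, v0=v0)
            fit = map_fit(sim_behavior, default_task, full_model, priors=pri)

            def integrand(b0):
                ll = sps.norm.logpdf(y, b0, math.sqrt(zeta)).sum()
                lp = sps.norm.logpdf(b0, m0, math.sqrt(v0))
                return math.exp(ll + lp - fit.log_joint)

            b_map = fit.map_params["beta0"]
            val, _ = quad(integrand, b_map - 0.5, b_map + 0.5, limit=200)
            exact = math.log(val) + fit.log_joint
            assert fit.neg_free_energy == pytest.approx(exact, abs=1e-5)
            results.append(exact)
        assert results[1] < results[0]


class TestFitCohort:
    def test_matrix_bookkeeping_and_row_permutation(
        self, default_task, full_model, gen_params
    ):
        learn, resp = gen_params
        behs = [
            preprocess_rts(simulate_subject(default_task, full_model, learn, resp, seed=s))
            for s in (1, 2)
        ]
        space = (ModelSpec("2HGF", "BL"), ModelSpec("2HGF", "RelPE+IrrelBias"))
        opts = FitOptions(n_starts=1, seed=0)
        cohort = fit_cohort(behs, default_task, model_space=space, options=opts)
        assert cohort.evidence.shape == (2, 2)
        assert not cohort.failures
        assert len(cohort.fits) == 4
        flipped = fit_cohort(behs[::-1], default_task, model_space=space, options=opts)
        np.testing.assert_allclose(
            flipped.evidence.to_numpy(), cohort.evidence.to_numpy()[::-1]
        )
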