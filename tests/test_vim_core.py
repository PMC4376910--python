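import numpy as np
import pytest
from scipy import integrate, stats
from scipy.special import expit

from shiftvim.simulate import (
    generate_worked_example,
    worked_example_nuisances,
    true_psi,
)
from shiftvim.vim import (
    ExactConditionalDensity,
    NuisanceSet,
    PositivityBoundError,
    ShiftSpec,
    TrueBinaryExposure,
    TrueOutcomeRegression,
    clever_covariate,
    eif_values,
    plug_in_psi_b,
    plug_in_psi_c,
    positivity_check,
)


def _uniform_nuisances(qfn=None):
    """phi = 1, g uniform on [0,1], optional outcome regression."""
    return NuisanceSet(
        qbar=TrueOutcomeRegression(qfn or (lambda a, W: expit(a))),
        g=ExactConditionalDensity(lambda a, W: np.ones(len(W))),
        phi=lambda W: np.ones(len(W)),
    )


class TestPlugIn:
    def test_null_shift_is_zero_at_true_nuisances(self):
        cs = generate_worked_example(50_000, "worked_logistic", seed=0,
                                     exposure="continuous")
        nuis = worked_example_nuisances("worked_logistic", "continuous")
        psi = plug_in_psi_c(nuis, cs, ShiftSpec(0.0, "continuous"), n_grid=300)
        assert abs(psi) < 4 * 0.5 / np.sqrt(cs.n)

    @pytest.mark.parametrize("delta", [0.01, 0.05, 0.09])
    def test_linear_outcome_recovers_delta_exactly(self, delta):
        cs = generate_worked_example(150_000, "worked_linear", seed=1,
                                     exposure="continuous")
        nuis = worked_example_nuisances("worked_linear", "continuous")
        psi = plug_in_psi_c(nuis, cs, ShiftSpec(delta, "continuous"), n_grid=200)
        assert psi == pytest.approx(delta, abs=1.5e-3)
        csb = generate_worked_example(600_000, "worked_linear", seed=1,
                                      exposure="binary")
        nb = worked_example_nuisances("worked_linear", "binary")
        psib = plug_in_psi_b(nb, csb, ShiftSpec(delta, "binary"))
        assert psib == pytest.approx(delta, abs=1.5e-3)

    def test_logistic_example_matches_independent_quadrature(self):
        cs = generate_worked_example(400_000, "worked_logistic", seed=2,
                                     exposure="continuous")
        nuis = worked_example_nuisances("worked_logistic", "continuous")
        psi = plug_in_psi_c(nuis, cs, ShiftSpec(0.01, "continuous"), n_grid=300)
        truth = true_psi("worked_logistic", "psi_c", 0.01)
        assert psi == pytest.approx(truth, abs=4 * 0.5 / np.sqrt(cs.n))

    def test_binary_bound_is_enforced(self):
        cs = generate_worked_example(500, "worked_logistic", seed=3,
                                     exposure="binary")
        nuis = worked_example_nuisances("worked_logistic", "binary")
        with pytest.raises(PositivityBoundError):
            plug_in_psi_b(nuis, cs, ShiftSpec(0.2, "binary"))


class TestCleverCovariate:
    def test_null_intervention_with_full_observation_is_one(self):
        nuis = _uniform_nuisances()
        W = np.zeros((5, 1))
        H = clever_covariate(nuis, ShiftSpec(0.0, "continuous"),
                             np.full(5, 0.3), np.ones(5), W)
        assert np.allclose(H, 1.0)

    def test_unobserved_rows_get_zero(self):
        nuis = _uniform_nuisances()
        W = np.zeros((4, 1))
        H = clever_covariate(nuis, ShiftSpec(0.05, "continuous"),
                             np.full(4, np.nan), np.zeros(4), W)
        assert np.allclose(H, 0.0)

    def test_uniform_density_ratio_in_the_interior(self):
        nuis = _uniform_nuisances()
        W = np.zeros((1, 1))
        H = clever_covariate(nuis, ShiftSpec(0.1, "continuous"),
                             np.array([0.5]), np.ones(1), W)
        assert H[0] == pytest.approx(1.0)

    def test_ratio_vanishes_below_the_support(self):
        nuis = _uniform_nuisances()
        H = clever_covariate(nuis, ShiftSpec(0.1, "continuous"),
                             np.array([0.05]), np.ones(1), np.zeros((1, 1)))
        assert H[0] == 0.0


class TestEIF:
    def test_mean_zero_at_ee_solution(self):
        from shiftvim.estimators import ee_estimator

        cs = generate_worked_example(3000, "worked_logistic", seed=4,
                                     exposure="binary")
        nuis = worked_example_nuisances("worked_logistic", "binary")
        spec = ShiftSpec(0.01, "binary")
        est = ee_estimator(cs, nuis, spec)
        eif = eif_values(nuis, cs, spec, est.psi)
        assert abs(eif.mean) < 1e-10

    def test_mean_zero_at_truth_with_true_nuisances(self):
        cs = generate_worked_example(100_000, "worked_logistic", seed=5,
                                     exposure="binary")
        nuis = worked_example_nuisances("worked_logistic", "binary")
        spec = ShiftSpec(0.01, "binary")
        truth = true_psi("worked_logistic", "psi_b", 0.01)
        eif = eif_values(nuis, cs, spec, truth)
        assert abs(eif.mean) < 3 * np.std(eif.d) / np.sqrt(cs.n)

    def test_asymptotic_linearity_variance_matches_replication(self):
        """Var(D)/n predicts the sampling variance of the EE estimator."""
        from shiftvim.estimators import ee_estimator

        nuis = worked_example_nuisances("worked_logistic", "binary")
        spec = ShiftSpec(0.01, "binary")
        psis, var_preds = [], []
        for s in range(200):
            cs = generate_worked_example(500, "worked_logistic", seed=100 + s,
                                         exposure="binary")
            est = ee_estimator(cs, nuis, spec)
            psis.append(est.psi)
            var_preds.append(est.se**2)
        emp = np.var(psis, ddof=1)
        pred = np.mean(var_preds)
        assert emp == pytest.approx(pred, rel=0.35)  # 200-replicate tolerance


class TestComparability:
    def test_small_delta_slope_matches_analytic_derivative(self):
        """(Psi_c(d) - Psi_c(0)) / d converges to E[Qbar'] as d -> 0."""
        d = 1e-4
        slope = true_psi("worked_logistic", "psi_c", d) / d
        beta = stats.beta(2, 2)

        def integrand(b):
            a1 = 0.1 + 0.8 * b
            dq = a1 * expit(a1 + 1) * (1 - expit(a1 + 1)) \
                + (1 - a1) * expit(a1) * (1 - expit(a1))
            return dq * beta.pdf(b)

        deriv, _ = integrate.quad(integrand, 0, 1)
        assert slope == pytest.approx(deriv, rel=5e-4)

    def test_continuous_and_binary_vims_agree_to_first_order(self):
        pc = true_psi("worked_logistic", "psi_c", 0.01)
        pb = true_psi("worked_logistic", "psi_b", 0.01)
        assert pc == pytest.approx(pb, rel=0.05)


class TestPositivityCheck:
    def test_clean_nuisances_produce_no_flags(self):
        cs = generate_worked_example(1000, "worked_logistic", seed=6,
                                     exposure="continuous")
        nuis = _uniform_nuisances()
        rep = positivity_check(nuis, cs, ShiftSpec(0.01, "continuous"))
        assert rep.n_flagged == 0
        assert rep.phi_quantiles["min"] == 1.0

    def test_small_phi_is_flagged(self):
        cs = generate_worked_example(100, "worked_logistic", seed=7,
                                     exposure="binary")
        nuis = NuisanceSet(
            qbar=TrueOutcomeRegression(lambda a, W: expit(a + W[:, 0])),
            g=TrueBinaryExposure(lambda W: W[:, 0]),
            phi=lambda W: np.full(len(W), 5e-4),
        )
        rep = positivity_check(nuis, cs, ShiftSpec(0.01, "binary"), floor=1e-3)
        assert rep.n_flagged == cs.n
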