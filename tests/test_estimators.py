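import numpy as np
import pandas as pd
import pytest
from scipy.special import expit
from scipy.stats import norm

from shiftvim.data import CrossSection
from shiftvim.estimators import (
    ee_estimator,
    gcomp_ipmw,
    tmle,
    unadjusted,
    wald_inference,
)
from shiftvim.simulate import (
    confounded_cross_section,
    confounded_nuisances,
    generate_worked_example,
    true_psi,
    worked_example_nuisances,
)
from shiftvim.vim import (
    EIFValue,
    NuisanceSet,
    ShiftSpec,
    TrueBinaryExposure,
    TrueOutcomeRegression,
    eif_values,
)


def _table_nuisances(qtable, g1=0.5, phi=1.0):
    """Qbar from a lookup on (a, w) pairs; scalar g and phi."""

    def qfn(a, W):
        return np.array([qtable[(float(ai), float(wi))]
                         for ai, wi in zip(a, W[:, 0])])

    return NuisanceSet(
        qbar=TrueOutcomeRegression(qfn),
        g=TrueBinaryExposure(lambda W: np.full(len(W), g1)),
        phi=lambda W: np.full(len(W), phi),
    )


class TestWaldInference:
    def test_normal_arithmetic(self):
        d = np.zeros(100)
        d[:50] = 1.0
        d[50:] = -1.0
        d *= 1.0 / np.std(d, ddof=1)  # sample sd exactly 1
        se, ci, p = wald_inference(0.196, d)
        assert se == pytest.approx(0.1)
        assert p == pytest.approx(2 * norm.sf(1.96), rel=1e-6)
        assert ci[0] == pytest.approx(0.196 - 1.959964 * 0.1, abs=1e-5)

    def test_null_estimate_has_p_one(self):
        se, ci, p = wald_inference(0.0, np.array([1.0, -1.0, 0.5, -0.5]))
        assert p == 1.0

    def test_zero_variance_warns(self):
        with pytest.warns(UserWarning, match="degenerate"):
            se, ci, p = wald_inference(0.1, np.zeros(10))
        assert np.isnan(p)


class TestEEPencilOracle:
    def test_two_row_binary_instance_matches_hand_sum(self):
        # n = 2, phi = 1, C = 1, g(1|w) = 0.5, delta = 0.1, tabulated Qbar
        qtable = {(1.0, 0.0): 0.8, (0.0, 0.0): 0.4,
                  (1.0, 1.0): 0.6, (0.0, 1.0): 0.2}
        cs = CrossSection(
            W=pd.DataFrame({"w": [0.0, 1.0]}),
            C=np.array([1, 1]), A=np.array([1.0, 0.0]),
            Y=np.array([1, 0]), exposure_kind="binary",
        )
        nuis = _table_nuisances(qtable)
        delta = 0.1
        est = ee_estimator(cs, nuis, ShiftSpec(delta, "binary"))
        # hand evaluation: D_i + psi with r = g*/g
        by_hand = []
        for (a, w, y) in [(1.0, 0.0, 1.0), (0.0, 1.0, 0.0)]:
            q1, q0 = qtable[(1.0, w)], qtable[(0.0, w)]
            qa = q1 if a == 1 else q0
            gstar = 0.5 + delta if a == 1 else 0.5 - delta
            r = gstar / 0.5
            m0 = 0.5 * q1 + 0.5 * q0
            mb = m0 + delta * (q1 - q0)
            by_hand.append(r * (y - qa) + qa - m0 + mb - y)
        assert est.psi == pytest.approx(np.mean(by_hand), abs=1e-12)

    def test_zero_residuals_make_ee_equal_plug_in(self):
        qtable = {(1.0, 0.0): 1.0, (0.0, 0.0): 0.0,
                  (1.0, 1.0): 1.0, (0.0, 1.0): 0.0}
        cs = CrossSection(
            W=pd.DataFrame({"w": [0.0, 1.0, 0.0, 1.0]}),
            C=np.ones(4, int), A=np.array([1.0, 0.0, 0.0, 1.0]),
            Y=np.array([1, 0, 0, 1]), exposure_kind="binary",
        )
        nuis = _table_nuisances(qtable)
        spec = ShiftSpec(0.1, "binary")
        est = ee_estimator(cs, nuis, spec)
        from shiftvim.vim import plug_in_psi_b

        assert est.psi == pytest.approx(plug_in_psi_b(nuis, cs, spec), abs=1e-12)


class TestGcompIPMW:
    def test_four_row_instance_matches_hand_sum(self):
        qtable = {(1.0, 0.0): 0.7, (0.0, 0.0): 0.3,
                  (1.0, 1.0): 0.9, (0.0, 1.0): 0.5}
        cs = CrossSection(
            W=pd.DataFrame({"w": [0.0, 0.0, 1.0, 1.0]}),
            C=np.array([1, 1, 1, 0]),
            A=np.array([1.0, 0.0, 1.0, np.nan]),
            Y=np.array([1, 0, 1, 0]), exposure_kind="binary",
        )
        nuis = _table_nuisances(qtable, phi=0.8)
        delta = 0.1
        est = gcomp_ipmw(cs, ShiftSpec(delta, "binary"), nuisances=nuis)
        rows = [(1.0, 0.0, 1.0, 1), (0.0, 0.0, 0.0, 1), (1.0, 1.0, 1.0, 1),
                (0.0, 1.0, 0.0, 0)]
        total = 0.0
        for a, w, y, c in rows:
            q1, q0 = qtable[(1.0, w)], qtable[(0.0, w)]
            qa = q1 if a == 1 else q0
            total += (c / 0.8) * (qa + delta * (q1 - q0)) - y
        assert est.psi == pytest.approx(total / 4, abs=1e-12)

    def test_perfect_fit_and_null_shift_give_zero(self):
        qtable = {(1.0, 0.0): 1.0, (0.0, 0.0): 0.0,
                  (1.0, 1.0): 0.0, (0.0, 1.0): 1.0}
        cs = CrossSection(
            W=pd.DataFrame({"w": [0.0, 0.0, 1.0, 1.0]}),
            C=np.ones(4, int), A=np.array([1.0, 0.0, 1.0, 0.0]),
            Y=np.array([1, 0, 0, 1]), exposure_kind="binary",
        )
        nuis = _table_nuisances(qtable)
        est = gcomp_ipmw(cs, ShiftSpec(0.0, "binary"), nuisances=nuis)
        assert est.psi == pytest.approx(0.0, abs=1e-12)

    def test_unadjusted_reduces_to_stratum_mean_contrast(self):
        rng = np.random.default_rng(8)
        n = 2000
        a = rng.binomial(1, 0.4, n).astype(float)
        y = rng.binomial(1, expit(-0.5 + a)).astype(float)
        cs = CrossSection(
            W=pd.DataFrame({"w": rng.normal(size=n)}),
            C=np.ones(n, int), A=a, Y=y, exposure_kind="binary",
        )
        delta = 0.05
        est = unadjusted(cs, ShiftSpec(delta, "binary"))
        ybar1, ybar0 = y[a == 1].mean(), y[a == 0].mean()
        # logistic in A alone is saturated: psi = delta * (ybar1 - ybar0)
        # (tolerance reflects the numerical optimizer, not sampling noise)
        assert est.psi == pytest.approx(delta * (ybar1 - ybar0), abs=1e-4)


class TestTMLE:
    def test_null_shift_with_true_nuisances_is_near_zero(self):
        cs = generate_worked_example(5000, "worked_logistic", seed=9,
                                     exposure="binary")
        nuis = worked_example_nuisances("worked_logistic", "binary")
        est = tmle(cs, nuis, ShiftSpec(0.0, "binary"))
        # at delta = 0 the parameter and its influence function both vanish
        assert abs(est.psi) < 1e-8

    def test_solves_the_eif_estimating_equation(self):
        cs = generate_worked_example(2000, "worked_logistic", seed=10,
                                     exposure="binary")
        nuis = worked_example_nuisances("worked_logistic", "binary")
        est = tmle(cs, nuis, ShiftSpec(0.01, "binary"))
        n = cs.n
        assert est.diagnostics["converged"]
        assert abs(est.diagnostics["mean_eif"]) < est.se / np.log(n)

    def test_plug_in_bounds_respected_even_with_poor_nuisances(self):
        # wildly wrong nuisances: the intervened-mean estimate stays in [0,1]
        for s in range(5):
            cs = confounded_cross_section(300, seed=20 + s)
            nuis = confounded_nuisances(cs, q_right=False, gphi_right=False)
            est = tmle(cs, nuis, ShiftSpec(0.05, "binary"))
            assert 0.0 <= est.diagnostics["intervened_mean"] <= 1.0

    def test_agrees_with_ee_when_both_consistent(self):
        psis_t, psis_e = [], []
        nuis = worked_example_nuisances("worked_logistic", "binary")
        spec = ShiftSpec(0.01, "binary")
        for s in range(30):
            cs = generate_worked_example(1000, "worked_logistic", seed=300 + s,
                                         exposure="binary")
            psis_t.append(tmle(cs, nuis, spec).psi)
            psis_e.append(ee_estimator(cs, nuis, spec).psi)
        diff = np.array(psis_t) - np.array(psis_e)
        joint_se = np.std(diff) / np.sqrt(len(diff)) + 1e-12
        assert abs(diff.mean()) < max(2 * joint_se, 1e-4)

    def test_continuous_estimate_solves_equation_with_fitted_nuisances(self):
        import warnings

        from shiftvim.vim import fit_nuisances

        cs = generate_worked_example(800, "worked_logistic", seed=11,
                                     exposure="continuous")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            nuis = fit_nuisances(
                cs, library=("GLM", "MEAN"), V=4, seed=11,
                density_grid=((5, "equal_width"), (10, "equal_width")),
            )
        est = tmle(cs, nuis, ShiftSpec(0.01, "continuous"), n_grid=100)
        assert est.diagnostics["converged"]
        assert abs(est.diagnostics["mean_eif"]) < est.se / np.log(cs.n)
        assert -1.0 <= est.psi <= 1.0


class TestDoubleRobustnessContrast:
    def test_gcomp_biased_under_misspecified_outcome_model(self):
        """With a wrong Qbar but right (g, phi), TMLE stays centered while
        the Gcomp/IPMW drifts."""
        truth = true_psi("confounded", "psi_b", 0.01)
        spec = ShiftSpec(0.01, "binary")
        t_psis, g_psis = [], []
        for s in range(40):
            cs = confounded_cross_section(2000, seed=600 + s)
            nuis = confounded_nuisances(cs, q_right=False, gphi_right=True)
            t_psis.append(tmle(cs, nuis, spec).psi)
            g_psis.append(gcomp_ipmw(cs, spec, nuisances=nuis).psi)
        t_bias = np.mean(t_psis) - truth
        g_bias = np.mean(g_psis) - truth
        mcse = np.std(t_psis) / np.sqrt(len(t_psis))
        assert abs(t_bias) < 3 * mcse
        assert abs(g_bias) > 5 * mcse

    def test_no_confounding_makes_unadjusted_agree_with_tmle(self):
        rng = np.random.default_rng(13)
        n = 4000
        w = rng.normal(size=(n, 1))
        a = rng.binomial(1, 0.5, n).astype(float)  # independent of W
        y = rng.binomial(1, expit(-1 + a)).astype(float)  # independent of W
        cs = CrossSection(W=pd.DataFrame({"w": w[:, 0]}), C=np.ones(n, int),
                          A=a, Y=y, exposure_kind="binary")
        nuis = NuisanceSet(
            qbar=TrueOutcomeRegression(lambda av, W: expit(-1 + av)),
            g=TrueBinaryExposure(lambda W: np.full(len(W), 0.5)),
            phi=lambda W: np.ones(len(W)),
        )
        spec = ShiftSpec(0.05, "binary")
        t = tmle(cs, nuis, spec)
        u = unadjusted(cs, spec)
        assert abs(t.psi - u.psi) < 3 * max(t.se, u.se)

    def test_strong_confounding_separates_unadjusted_from_tmle(self):
        truth = true_psi("confounded", "psi_b", 0.01)
        spec = ShiftSpec(0.01, "binary")
        cs = confounded_cross_section(20_000, seed=700)
        nuis = confounded_nuisances(cs, q_right=True, gphi_right=True)
        t = tmle(cs, nuis, spec)
        u = unadjusted(cs, spec)
        joint_se = np.hypot(t.se, u.se)
        assert abs(t.psi - u.psi) > 3 * joint_se


class TestEIFContractAcrossEstimators:
    def test_ee_influence_mean_is_numerically_zero(self):
        cs = generate_worked_example(1500, "worked_logistic", seed=14,
                                     exposure="binary")
        nuis = worked_example_nuisances("worked_logistic", "binary")
        spec = ShiftSpec(0.01, "binary")
        est = ee_estimator(cs, nuis, spec)
        eif = eif_values(nuis, cs, spec, est.psi)
        assert isinstance(eif, EIFValue)
        assert abs(eif.mean) < 1e-10
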