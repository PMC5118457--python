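"""Variable-J mesophyll conductance, Cc conversion, and FvCB fitting."""

import numpy as np
import pytest
from scipy import stats

from acifit.c3 import (
    GM_PA_TO_BAR,
    cc_from_ci,
    c3_forward,
    fit_c3_curve,
    fit_vcmax_jmax,
    fvcb_finite_gm,
    gm_ethier,
    gm_variable_j,
    rl_from_rdark,
)
from acifit.synthetic import default_true_parameters, simulate_c3_curve


class TestRLFromRdark:
    @pytest.mark.parametrize("rdark,expected", [(2.0, 1.0), (0.0, 0.0), (1.7, 0.85)])
    def test_halving(self, rdark, expected):
        assert rl_from_rdark(rdark) == expected

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            rl_from_rdark(-0.1)


class TestVariableJ:
    def test_hand_arithmetic(self):
        # AN=20, Ci=30 Pa, ETR=160, RL=1, Gamma*=4.19 Pa:
        # Cc_implied = 4.19*328/76, gm = 0.1 * 20/(30 - 18.083) mol m-2 s-1 bar-1
        gm, mask = gm_variable_j(
            np.array([20.0]), np.array([30.0]), np.array([160.0]), 1.0, 4.19
        )
        assert mask[0]
        assert gm[0] == pytest.approx(0.16783, abs=2e-4)

    def test_zero_flux_gives_zero_gm(self):
        gm, mask = gm_variable_j(
            np.array([0.0]), np.array([30.0]), np.array([60.0]), 1.0, 4.19
        )
        assert mask[0] and gm[0] == 0.0

    def test_etr_deficit_flagged_not_fatal(self):
        an = np.array([20.0, 20.0])
        gm, mask = gm_variable_j(an, np.array([30.0, 30.0]),
                                 np.array([160.0, 80.0]), 1.0, 4.19)
        assert mask.tolist() == [True, False]
        assert np.isnan(gm[1])

    def test_forward_inverse_recovers_generating_gm(self, noiseless_c3_curve, rice25, rice_params):
        c = noiseless_c3_curve
        gm, mask = gm_variable_j(
            c.AN, c.Ci_Pa, c.ETR, rl_from_rdark(c.Rdark), rice25.gamma_star_Pa
        )
        assert mask.all()
        assert np.max(np.abs(gm / rice_params.gm - 1)) < 1e-6


class TestCcFromCi:
    def test_arithmetic(self):
        assert cc_from_ci(300.0, 20.0, 0.2) == pytest.approx(200.0)

    def test_zero_flux_identity(self):
        assert cc_from_ci(123.0, 0.0, 0.1) == 123.0

    def test_infinite_conductance_limit(self):
        assert cc_from_ci(300.0, 20.0, 1e12) == pytest.approx(300.0)

    def test_nonpositive_gm_rejected(self):
        with pytest.raises(ValueError):
            cc_from_ci(300.0, 20.0, 0.0)


class TestC3Forward:
    def test_compensation_point_exact(self, rice25):
        for rl in (0.0, 0.5, 2.0):
            a = c3_forward(rice25.gamma_star_Pa, 120.0, 200.0, rl, rice25)
            assert a == -rl

    def test_rubisco_limited_hand_value(self, rice25):
        # Vcmax=100, Cc=20 Pa, rice 25 degC constants, RL=0
        a = c3_forward(20.0, 100.0, 1e6, 0.0, rice25)
        assert a == pytest.approx(25.31, abs=0.01)

    def test_rubp_asymptote(self, rice25):
        a = c3_forward(1e7, 1e9, 180.0, 1.0, rice25)
        assert a == pytest.approx(180.0 / 4.0 - 1.0, rel=1e-4)

    def test_min_of_branches_and_monotone(self, rice25):
        cc = np.linspace(rice25.gamma_star_Pa + 0.01, 200.0, 400)
        a = c3_forward(cc, 100.0, 180.0, 1.0, rice25)
        ac = 100.0 * (cc - rice25.gamma_star_Pa) / (cc + rice25.kc_app_Pa()) - 1.0
        aj = 180.0 * (cc - rice25.gamma_star_Pa) / (4 * cc + 8 * rice25.gamma_star_Pa) - 1.0
        assert np.all(a <= ac + 1e-12) and np.all(a <= aj + 1e-12)
        assert np.all(np.diff(a) > 0)


class TestFitVcmaxJmax:
    def test_noiseless_recovery(self, rice25):
        cc = np.array([2, 4, 6, 8, 10, 12, 16, 20, 26, 34, 44, 60], dtype=float)
        a = c3_forward(cc, 100.0, 180.0, 1.0, rice25)
        res = fit_vcmax_jmax(cc, a, rice25, 1.0)
        assert res.Vcmax == pytest.approx(100.0, rel=5e-3)
        assert res.Jmax == pytest.approx(180.0, rel=5e-3)
        assert set(res.limitation) == {"rubisco", "rubp"}

    def test_all_rubisco_limited_flags_jmax(self, rice25):
        cc = np.linspace(5.0, 9.0, 8)
        a = c3_forward(cc, 100.0, 1e5, 1.0, rice25)
        with pytest.warns(UserWarning):
            res = fit_vcmax_jmax(cc, a, rice25, 1.0)
        assert not res.jmax_identifiable
        assert res.Vcmax == pytest.approx(100.0, rel=0.01)

    def test_too_few_points_rejected(self, rice25):
        from acifit.c3 import FitError

        with pytest.raises(FitError):
            fit_vcmax_jmax(np.array([10.0, 20.0]), np.array([5.0, 10.0]), rice25, 1.0)


class TestEthier:
    def test_noiseless_gm_recovery(self, noiseless_c3_curve, rice25, rice_params):
        c = noiseless_c3_curve
        gm, res = gm_ethier(c.Ci_Pa, c.AN, rice25, rl_from_rdark(c.Rdark))
        assert gm == pytest.approx(rice_params.gm, rel=0.02)
        assert res.Vcmax == pytest.approx(rice_params.Vcmax, rel=0.02)

    def test_large_gm_matches_infinite_gm_fit(self, rice25):
        ci = np.array([5, 8, 12, 16, 22, 30, 40, 55, 80, 120], dtype=float)
        a = c3_forward(ci, 110.0, 190.0, 1.0, rice25)  # infinite gm: Cc == Ci
        gm, res = gm_ethier(ci, a, rice25, 1.0)
        inf_fit = fit_vcmax_jmax(ci, a, rice25, 1.0)
        assert res.Vcmax == pytest.approx(inf_fit.Vcmax, rel=0.02)

    def test_correlates_with_variable_j_on_noisy_ensemble(self, rice25, rice_params):
        # both estimators track the same underlying conductance across
        # replicate noisy curves: positive correlation, P < 0.01
        harley, ethier = [], []
        for i, seq in enumerate(np.random.SeedSequence(99).spawn(16)):
            rng = np.random.default_rng(seq)
            gm_true = 0.15 + 0.02 * i  # spread of true conductances
            p = default_true_parameters("rice", 25.0, "WW", 25.0)
            p = type(p)(species=p.species, Vcmax=p.Vcmax, Jmax=p.Jmax,
                        gs=p.gs, gm=gm_true, Rdark=p.Rdark)
            c = simulate_c3_curve(p, 25.0, "WW", 25.0, noise_sd=0.3, rng=rng)
            rl = rl_from_rdark(c.Rdark)
            gm_pts, mask = gm_variable_j(c.AN, c.Ci_Pa, c.ETR, rl, rice25.gamma_star_Pa)
            harley.append(float(np.nanmean(gm_pts[mask])))
            ethier.append(gm_ethier(c.Ci_Pa, c.AN, rice25, rl)[0])
        r, p_val = stats.pearsonr(harley, ethier)
        assert r > 0 and p_val < 0.01


class TestPipeline:
    def test_tobacco_kinetics_overestimate_vcmax(self, noiseless_c3_curve):
        # tobacco Kc(1+O/Ko) exceeds the rice value at 25 degC, so refitting
        # with the standard constants inflates Vcmax
        own = fit_c3_curve(noiseless_c3_curve, kinetics_source="own")
        std = fit_c3_curve(noiseless_c3_curve, kinetics_source="bernacchi")
        assert std.Vcmax > own.Vcmax

    def test_finite_gm_steady_state_consistency(self, rice25):
        # closed-form quadratic equals the fixed-point solution of A = FvCB(Ci - A/gm)
        ci = np.array([10.0, 20.0, 40.0, 80.0])
        gm_bar = 0.3
        a = fvcb_finite_gm(ci, 100.0, 180.0, gm_bar, 1.0, rice25)
        cc = ci - a / (gm_bar / GM_PA_TO_BAR)
        assert np.allclose(a, c3_forward(cc, 100.0, 180.0, 1.0, rice25), atol=1e-8)

    def test_per_point_gm_mode(self, noiseless_c3_curve, rice_params):
        res = fit_c3_curve(noiseless_c3_curve, gm_mode="per-point")
        assert res.Vcmax == pytest.approx(rice_params.Vcmax, rel=5e-3)
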