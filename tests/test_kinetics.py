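"""Steady-state and transient kinetic fitting."""

import numpy as np
import pytest
from scipy import optimize

from nqogate import kinetics as kin
from nqogate import synthetic as syn


def _rates(noise_cv=0.0, replicates=1, seed=0, **kwargs):
    return syn.simulate_rates(syn.KineticsSimSpec(
        noise_cv=noise_cv, replicates=replicates, rng_seed=seed, **kwargs))


class TestRateLawIdentities:
    def test_inhibition_model_reduces_to_plain_at_huge_kis(self):
        A = np.array([10.0, 50.0, 200.0])
        B = np.array([5.0, 20.0, 80.0])
        plain = syn.pingpong_rate(A, B, 11.0, 0.4, 35.0)
        limit = syn.pingpong_rate(A, B, 11.0, 0.4, 35.0, Kis=0.4e9)
        np.testing.assert_allclose(limit, plain, rtol=1e-6)

    def test_fixed_coq0_slice_is_michaelis_menten(self):
        """At fixed B the ping-pong law is hyperbolic in A with apparent
        Vmax = kcat*B/(Kb+B) and apparent Km = Ka*B/(Kb+B)."""
        kcat, Ka, Kb, B = 5.4, 130.0, 10.0, 6.0
        A = np.geomspace(1.0, 500.0, 30)
        v = syn.pingpong_rate(A, B, kcat, Ka, Kb)
        vmax_app = kcat * B / (Kb + B)
        km_app = Ka * B / (Kb + B)
        np.testing.assert_allclose(v, vmax_app * A / (km_app + A), rtol=1e-12)


class TestSteadyStateFits:
    def test_noiseless_recovery_plain(self):
        fit = kin.fit_pingpong(_rates())
        spec = syn.KineticsSimSpec()
        assert fit.kcat == pytest.approx(spec.true_kcat, rel=1e-3)
        assert fit.Ka == pytest.approx(spec.true_Ka, rel=1e-3)
        assert fit.Kb == pytest.approx(spec.true_Kb, rel=1e-3)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_noiseless_recovery_with_inhibition(self):
        data = _rates(true_kcat=11.0, true_Ka=0.4, true_Kb=35.0, true_Kis=1.1,
                      nadh_grid=(30., 40., 50., 60., 80., 100.),
                      coq0_grid=(30., 50., 70., 100., 150.))
        fit = kin.fit_pingpong_substrate_inhibition(data)
        for got, want in ((fit.kcat, 11.0), (fit.Ka, 0.4), (fit.Kb, 35.0),
                          (fit.Kis, 1.1)):
            assert got == pytest.approx(want, rel=1e-3)

    def test_matches_grid_search_oracle(self):
        """Independent coarse grid search + simplex polish lands on the same
        optimum (4 significant figures) on a small noisy dataset."""
        data = _rates(noise_cv=0.05, replicates=1, seed=3,
                      nadh_grid=(10., 50., 100.), coq0_grid=(2., 5., 10.))
        fit = kin.fit_pingpong(data)
        A, B, v = data.A, data.B, data.v

        def sse(log_p):
            kcat, Ka, Kb = np.exp(log_p)
            return np.sum((syn.pingpong_rate(A, B, kcat, Ka, Kb) - v) ** 2)

        grid = [np.log(np.geomspace(lo, hi, 12)) for lo, hi in
                ((0.5, 50), (5, 2000), (0.5, 200))]
        best = min(((a, b, c) for a in grid[0] for b in grid[1]
                    for c in grid[2]), key=lambda p: sse(np.array(p)))
        polished = optimize.minimize(sse, np.array(best),
                                     method="Nelder-Mead",
                                     options={"xatol": 1e-12, "fatol": 1e-14,
                                              "maxiter": 20000})
        oracle = np.exp(polished.x)
        assert fit.kcat == pytest.approx(oracle[0], rel=1e-4)
        assert fit.Ka == pytest.approx(oracle[1], rel=1e-4)
        assert fit.Kb == pytest.approx(oracle[2], rel=1e-4)

    def test_rank_deficient_design_rejected(self):
        import pandas as pd
        table = pd.DataFrame({
            "NADH_uM": [50.0, 50.0], "CoQ0_uM": [5.0, 5.0],
            "replicate": [1, 2], "v0_over_e_per_s": [1.0, 1.1]})
        with pytest.raises(kin.FitError, match="distinct"):
            kin.fit_pingpong(syn.RateDataset(table=table))

    def test_parameter_bias_below_se_under_noise(self):
        """Across seeded replicates at n >= 30 points, the mean deviation of
        each recovered parameter stays within its typical standard error."""
        truths = dict(true_kcat=5.4, true_Ka=130.0, true_Kb=10.0)
        est, ses = [], []
        for seed in range(25):
            fit = kin.fit_pingpong(_rates(noise_cv=0.05, replicates=1,
                                          seed=seed, **truths), n_starts=3)
            est.append([fit.kcat, fit.Ka, fit.Kb])
            ses.append([fit.se["kcat"], fit.se["Ka"], fit.se["Kb"]])
        bias = np.mean(est, axis=0) - [5.4, 130.0, 10.0]
        assert np.all(np.abs(bias) < np.mean(ses, axis=0))


class TestModelSelection:
    def test_identical_residuals_prefer_simpler_model(self):
        data = _rates()
        f1 = kin.fit_pingpong(data)
        f2 = kin.fit_pingpong_substrate_inhibition(data)
        # noiseless no-inhibition data: both fit essentially perfectly
        sel = kin.select_model(f1, f2, data)
        assert sel.choice == "pingpong"

    def test_strong_inhibition_detected(self):
        data = _rates(noise_cv=0.05, replicates=3, seed=1,
                      true_kcat=11.0, true_Ka=0.4, true_Kb=35.0, true_Kis=0.4,
                      nadh_grid=(30., 40., 50., 60., 80., 100.),
                      coq0_grid=(30., 50., 70., 100., 150.))
        f1 = kin.fit_pingpong(data)
        f2 = kin.fit_pingpong_substrate_inhibition(data)
        sel = kin.select_model(f1, f2, data)
        assert sel.choice == "pingpong_si"
        assert sel.p_value < 0.05


class TestBiexponentialFit:
    def test_noiseless_recovery_of_stated_truth(self):
        t = np.geomspace(1e-3, 60.0, 300)
        a = syn.biexponential(t, 0.09, 0.008, 3.2, 0.1, 0.02)
        fit = kin.fit_biexponential(syn.StoppedFlowTrace(
            times=t, absorbance=a, substrate_concentration=100.0))
        assert fit.B1 == pytest.approx(0.09, rel=5e-3)
        assert fit.B2 == pytest.approx(0.008, rel=5e-3)
        assert fit.kobs1 == pytest.approx(3.2, rel=5e-3)
        assert fit.kobs2 == pytest.approx(0.1, rel=5e-3)
        assert fit.C == pytest.approx(0.02, rel=5e-3)
        assert fit.amplitude_fraction_fast > 0.9
        assert fit.rates_distinguishable

    def test_single_exponential_recovered_as_nested_case(self):
        rng = np.random.default_rng(0)
        t = np.geomspace(1e-3, 5.0, 200)
        a = 0.1 * np.exp(-2.0 * t) + 0.02 + rng.normal(0, 2e-4, t.shape)
        fit = kin.fit_biexponential(syn.StoppedFlowTrace(
            times=t, absorbance=a, substrate_concentration=100.0))
        # one phase should carry essentially the whole amplitude at rate ~2
        dominant_rate = fit.kobs1 if fit.B1 >= fit.B2 else fit.kobs2
        assert dominant_rate == pytest.approx(2.0, rel=0.05)
        assert min(fit.B1, fit.B2) < 0.05 * max(fit.B1, fit.B2)

    def test_phase_relabeling_convention(self):
        """kobs1 >= kobs2 regardless of which phase converged first."""
        t = np.geomspace(1e-3, 80.0, 250)
        a = syn.biexponential(t, 0.01, 0.09, 0.08, 4.0, 0.02)  # slow listed first
        fit = kin.fit_biexponential(syn.StoppedFlowTrace(
            times=t, absorbance=a, substrate_concentration=50.0))
        assert fit.kobs1 >= fit.kobs2
        assert fit.kobs1 == pytest.approx(4.0, rel=1e-2)
        assert fit.B1 == pytest.approx(0.09, rel=1e-2)

    def test_short_or_rising_traces_rejected(self):
        t = np.linspace(0.1, 1.0, 5)
        with pytest.raises(kin.FitError, match="10 time points"):
            kin.fit_biexponential(syn.StoppedFlowTrace(
                times=t, absorbance=np.linspace(1, 0.5, 5),
                substrate_concentration=1.0))
        t = np.linspace(0.1, 1.0, 20)
        with pytest.raises(kin.FitError, match="decay"):
            kin.fit_biexponential(syn.StoppedFlowTrace(
                times=t, absorbance=np.linspace(0.1, 0.9, 20),
                substrate_concentration=1.0))


class TestSaturationFit:
    def test_noiseless_recovery_over_stopped_flow_range(self):
        S = np.array([90.0, 150.0, 250.0, 350.0, 500.0])
        kobs = syn.saturation_kobs(S, 4.8, 450.0)
        fit = kin.fit_saturation(list(zip(S, kobs)))
        assert fit.kred == pytest.approx(4.8, rel=5e-3)
        assert fit.Kd == pytest.approx(450.0, rel=5e-3)
        assert not fit.kd_unconstrained

    def test_midpoint_identity(self):
        fit = kin.fit_saturation(
            [(s, syn.saturation_kobs(s, 4.8, 450.0)) for s in
             (90, 200, 450, 500)])
        assert fit.predict(fit.Kd) == pytest.approx(fit.kred / 2)

    def test_saturated_regime_flags_kd_unconstrained(self):
        rng = np.random.default_rng(1)
        S = np.array([90.0, 150.0, 250.0, 350.0, 500.0])
        kobs = syn.saturation_kobs(S, 12.9, 1.0) + rng.normal(0, 0.05, S.shape)
        fit = kin.fit_saturation(list(zip(S, kobs)))
        assert fit.kd_unconstrained
        assert fit.kred == pytest.approx(np.mean(kobs), rel=0.02)

    def test_too_few_points_rejected(self):
        with pytest.raises(kin.FitError):
            kin.fit_saturation([(90.0, 1.0), (500.0, 4.0)])


class TestDerivedQuantities:
    def test_beer_lambert_arithmetic(self):
        # -0.00622 AU/s at eps 6220 and 1 cm is 1 uM/s; over 0.1 uM enzyme
        v = kin.absorbance_to_rate(-0.00622, 6220.0, 1.0, 0.1)
        assert v == pytest.approx(10.0, rel=1e-12)

    def test_zero_slope_gives_zero(self):
        assert kin.absorbance_to_rate(0.0, 6220.0, 1.0, 0.1) == 0.0

    def test_default_extinction_coefficient(self):
        assert kin.EPSILON_340_NADH == 6220.0

    def test_efficiency_value_and_units(self):
        value, se = kin.efficiency(5.4, 10.0)
        assert value == pytest.approx(5.4e5)
        assert se == 0.0

    def test_efficiency_error_propagation(self):
        value, se = kin.efficiency(11.0, 35.0, 1.0, 6.0)
        assert value == pytest.approx(11.0 / 35.0e-6)
        expected = value * np.sqrt((1 / 11) ** 2 + (6 / 35) ** 2)
        assert se == pytest.approx(expected, rel=1e-12)
        # consistent with the ~5.7e4 scale of the wild-type efficiency SE
        assert 5.0e4 < se < 7.0e4

    def test_fold_change_decrease(self):
        fc = kin.fold_change(35.0, 10.0, "WT", "mutant")
        assert fc.ratio == pytest.approx(3.5)
        assert fc.direction == "decrease"

    def test_fold_change_identity(self):
        assert kin.fold_change(4.2, 4.2).ratio == pytest.approx(1.0)

    def test_fold_change_increase(self):
        fc = kin.fold_change(3.2e5, 5.6e5, "WT", "mutant")
        assert fc.ratio == pytest.approx(1.75)
        assert round(fc.ratio, 1) == 1.8
        assert fc.direction == "increase"
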