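"""Per-compound dual binding-potential fitting and TED classification."""

import numpy as np
import pytest
import scipy.optimize

from hydroted import (
    CompoundSeries,
    CompoundTruth,
    DEFAULT_CONSTANTS,
    DomainError,
    DualBindingModel,
    InsufficientDataError,
    SingularFitError,
    ThermoConstants,
    binding_potential,
    classify_ted,
    generate_compound,
    iceberg_residual,
)
from conftest import make_series

R = DEFAULT_CONSTANTS.gas_constant_R
CPW = DEFAULT_CONSTANTS.water_heat_capacity_Cpw


class TestDualFit:
    def test_constant_lnk_forces_zero_temperature_dependence(self):
        T = np.arange(273.0, 374.0, 10.0)
        res = DualBindingModel(T, np.full(T.size, 2.0)).fit()
        assert res.dH_mot == pytest.approx(0.0, abs=1e-6)
        assert res.dCp_hydr == pytest.approx(0.0, abs=1e-8)
        assert res.dS_mot == pytest.approx(R * 2.0, abs=1e-8)
        assert res.r_squared == 1.0

    def test_noiseless_recovery_to_1e8_relative(self, spec_truth, noiseless_series):
        res = DualBindingModel.from_series(noiseless_series).fit()
        assert res.dH_mot == pytest.approx(spec_truth.dH_mot, rel=1e-8)
        assert res.dS_mot == pytest.approx(spec_truth.dS_mot, rel=1e-8)
        assert res.dCp_hydr == pytest.approx(spec_truth.n_w * CPW, rel=1e-8)
        assert res.hydration_class == "A"
        assert res.xi_w == pytest.approx(4.0, rel=1e-8)

    def test_noisy_estimates_within_three_standard_errors(self, spec_truth):
        """Over 100 seeded replicates at sigma = 0.02, each parameter should
        fall within 3 reported SE of truth in at least 95 replicates."""
        truth_vals = {
            "dH_mot": spec_truth.dH_mot,
            "dS_mot": spec_truth.dS_mot,
            "dCp_hydr": spec_truth.n_w * CPW,
        }
        hits = {k: 0 for k in truth_vals}
        for seed in range(100):
            truth = CompoundTruth(
                spec_truth.dH_mot, spec_truth.dS_mot, spec_truth.n_w,
                noise_sd_lnK=0.02, T_grid=spec_truth.T_grid,
            )
            res = DualBindingModel.from_series(generate_compound(truth, seed)).fit()
            for k, v in truth_vals.items():
                if abs(res.params[k] - v) <= 3 * res.bse[k]:
                    hits[k] += 1
        for k, n_ok in hits.items():
            assert n_ok >= 95, f"{k}: only {n_ok}/100 within 3 SE"

    def test_fewer_than_four_points_rejected(self):
        with pytest.raises(InsufficientDataError):
            DualBindingModel([273.0, 298.0, 323.0], [1.0, 1.1, 1.2]).fit()

    def test_non_positive_temperature_rejected(self):
        with pytest.raises(DomainError):
            DualBindingModel([-1.0, 298.0, 323.0, 350.0], [1, 1, 1, 1])

    def test_pathological_grid_raises_singular_fit(self):
        T = 300.0 + np.array([0.0, 1e-10, 2e-10, 3e-10])
        with pytest.raises(SingularFitError):
            DualBindingModel(T, [1.0, 1.0, 1.0, 1.0]).fit()

    def test_exactly_four_points_flags_low_df(self):
        _, s = make_series(-5e4, -400.0, 2.0, T_grid=[273.0, 303.0, 333.0, 363.0])
        res = DualBindingModel.from_series(s).fit()
        assert res.low_df
        assert np.all(np.isfinite(res.bse))

    def test_weighted_fit_accepts_per_point_weights(self, noiseless_series):
        w = np.linspace(0.5, 2.0, len(noiseless_series))
        res = DualBindingModel(
            noiseless_series.temperatures, noiseless_series.ln_k, weights=w
        ).fit()
        assert res.dCp_hydr == pytest.approx(4.0 * CPW, rel=1e-8)

    def test_closed_form_matches_brute_force_minimizer(self):
        """Independent oracle: direct numerical minimisation of the residual
        sum of squares agrees with the linear-algebra solution."""
        truth, s = make_series(-3.0e4, -250.0, 1.5, T_grid=[275.0, 300.0, 325.0, 350.0, 375.0])
        res = DualBindingModel.from_series(s).fit()

        T, y = s.temperatures, R * s.ln_k

        def rss(p):
            dH, dS, dCp = p
            pred = -dH / T + (dS - dCp) + dCp * np.log(T)
            return np.sum((y - pred) ** 2)

        x0 = np.array([truth.dH_mot, truth.dS_mot, truth.n_w * CPW]) * 1.2 + 1.0
        opt = scipy.optimize.minimize(rss, x0, method="Nelder-Mead",
                                      options={"xatol": 1e-10, "fatol": 1e-14,
                                               "maxiter": 20000})
        assert res.dH_mot == pytest.approx(opt.x[0], rel=1e-4)
        assert res.dS_mot == pytest.approx(opt.x[1], rel=1e-4)
        assert res.dCp_hydr == pytest.approx(opt.x[2], rel=1e-4)

    def test_diagnostic_plot_returns_axes(self, noiseless_series):
        import matplotlib
        matplotlib.use("Agg")
        res = DualBindingModel.from_series(noiseless_series).fit()
        ax = res.plot()
        assert ax.get_xlabel().startswith("1/T")

    def test_summary_mentions_class_and_parameters(self, noiseless_series):
        res = DualBindingModel.from_series(noiseless_series).fit()
        text = res.summary()
        assert "dCp_hydr" in text and "class A" in text


class TestClassifyTed:
    @pytest.mark.parametrize(
        "dcp,se,n_w_expected,cls_expected",
        [
            (0.0, 0.0, 0.0, "indeterminate"),
            (150.6, 1.0, 2.0, "A"),
            (-1129.5, 10.0, -15.0, "B"),
            (100.0, 80.0, 100.0 / 75.3, "indeterminate"),  # < 2 SE
        ],
    )
    def test_water_count_and_class(self, dcp, se, n_w_expected, cls_expected):
        n_w, xi_w, cls = classify_ted(dcp, se)
        assert n_w == pytest.approx(n_w_expected)
        assert xi_w == pytest.approx(abs(n_w_expected))
        assert cls == cls_expected

    def test_xi_w_never_rounded(self):
        n_w, xi_w, _ = classify_ted(100.0, 0.1)
        assert xi_w == pytest.approx(100.0 / 75.3)
        assert xi_w != round(xi_w)


class TestBindingPotential:
    def test_alpha_round_trip_against_generator(self, spec_truth, noiseless_series):
        res = DualBindingModel.from_series(noiseless_series).fit()
        T = spec_truth.T_grid
        assert np.allclose(
            res.predict(T, "alpha"), R * noiseless_series.ln_k, rtol=1e-10
        )

    def test_beta_is_temperature_times_alpha(self, noiseless_series):
        res = DualBindingModel.from_series(noiseless_series).fit()
        T = np.array([280.0, 310.0, 340.0])
        assert np.allclose(res.predict(T, "beta"), T * res.predict(T, "alpha"))

    def test_zero_dcp_gives_linear_vant_hoff(self):
        u = 1.0 / np.linspace(270.0, 370.0, 9)
        alpha = binding_potential(-5e4, -300.0, 0.0, 1.0 / u)
        slope, intercept = np.polyfit(u, alpha, 1)
        assert np.allclose(alpha, slope * u + intercept,
                           rtol=0, atol=1e-9 * np.abs(alpha).max())

    def test_class_a_curvature_is_convex_in_reciprocal_temperature(self):
        u = np.linspace(1 / 373.0, 1 / 273.0, 21)
        alpha = binding_potential(-104100.0, -1868.0, 301.2, 1.0 / u)
        # unequal u spacing handled by divided differences
        dd = np.diff(np.diff(alpha) / np.diff(u)) / np.diff(u[:-1])
        assert np.all(dd > 0)

    def test_negative_temperature_rejected(self):
        with pytest.raises(DomainError):
            binding_potential(0.0, 0.0, 0.0, -3.0)


class TestDecomposition:
    def test_thermal_enthalpy_direct_arithmetic(self):
        _, s = make_series(-1e4, -100.0, 2.0)
        res = DualBindingModel.from_series(s).fit()
        d = res.decompose(298.0)
        assert d.dH_th == pytest.approx(2 * 75.3 * 298, rel=1e-9)

    def test_one_kelvin_anchor(self):
        _, s = make_series(-1e4, -100.0, 2.0)
        res = DualBindingModel.from_series(s).fit()
        d = res.decompose(1.0)
        assert d.dS_th == 0.0
        assert d.dH_th == pytest.approx(res.n_w * 75.3, rel=1e-9)

    @pytest.mark.parametrize("T", [250.0, 298.0, 400.0])
    def test_conservation_identities_machine_precision(self, T):
        _, s = make_series(-7e4, -900.0, -3.0, noise_sd=0.05, seed=7)
        res = DualBindingModel.from_series(s).fit()
        d = res.decompose(T)
        # identities hold to floating-point rounding of the additions
        assert abs(d.dH_dual - d.dH_mot - d.dH_th) <= 1e-12 * max(1.0, abs(d.dH_dual))
        assert abs(d.dS_dual - d.dS_mot - d.dS_th) <= 1e-12 * max(1.0, abs(d.dS_dual))
        assert d.dG_mot == pytest.approx(d.dH_mot - T * d.dS_mot)

    def test_thermal_sign_follows_n_w(self):
        _, sA = make_series(-1e4, -100.0, 2.0)
        _, sB = make_series(1e4, 100.0, -2.0)
        dA = DualBindingModel.from_series(sA).fit().decompose(298.0)
        dB = DualBindingModel.from_series(sB).fit().decompose(298.0)
        assert dA.dH_th > 0 and dA.dS_th > 0
        assert dB.dH_th < 0 and dB.dS_th < 0


class TestIcebergResidual:
    def test_exact_unitary_subtraction_linearizes(self):
        """Subtracting the true iceberg terms leaves a perfect van't Hoff line."""
        xi, h, s0 = 3.0, -22.0e3, -445.0
        H0, S0 = -17.7e3, -86.4
        dcp = 3.0 * 75.3
        truth, series = make_series(H0 + xi * h, S0 + xi * s0, 3.0)
        res = iceberg_residual(series, xi, h, s0, dcp)
        assert res.r_squared == pytest.approx(1.0, abs=1e-10)
        # slope of lnK_x vs 1/T is -dH_x/R with dH_x the null-iceberg enthalpy
        assert res.slope == pytest.approx(-H0 / 8.3145, rel=1e-8)

    def test_zero_iceberg_is_identity(self, noiseless_series):
        res = iceberg_residual(noiseless_series, 0.0, -22e3, -445.0, 0.0)
        assert np.array_equal(res.ln_K_x, noiseless_series.ln_k)

    def test_noisy_series_still_linearizes_well(self):
        truth, series = make_series(-50e3, -300.0, 0.0, noise_sd=0.02, seed=11)
        res = iceberg_residual(series, 0.0, 0.0, 0.0, 0.0)
        assert res.r_squared > 0.99

    def test_negative_xi_rejected(self, noiseless_series):
        with pytest.raises(DomainError):
            iceberg_residual(noiseless_series, -1.0, 0.0, 0.0, 0.0)
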