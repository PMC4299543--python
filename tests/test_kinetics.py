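"""Cascade simulation, rate estimation and Michaelis-Menten fitting."""

import numpy as np
import pytest

from zymocharge.kinetics import (
    CascadeParams,
    EnzymeSpec,
    MMDataset,
    NoQualifyingWindowError,
    TimeCourse,
    UNIT_CONC,
    activity_to_concentration,
    concentration_to_activity,
    estimate_activation_rate,
    fit_cascade,
    fit_mm,
    fold_difference,
    molar_mass_from_sequence,
    read_mm_csv,
    read_timecourse_csv,
    simulate_cascade,
    write_mm_csv,
    write_timecourse_csv,
)
from zymocharge.synthetic_data import NoiseSpec, gen_mm_data, gen_timecourse

# wild-type-like autoactivation: 2 umol/L zymogen + 10 nmol/L active enzyme,
# bimolecular constant chosen so the initial slope is 30.9 nmol/L/min
WT_LIKE = CascadeParams(k_auto=1.545, tg0_umol=2.0, tr0_nmol=10.0)


class TestSimulateCascade:
    def test_no_rates_means_constant_course(self):
        p = CascadeParams(k_auto=0.0, tg0_umol=2.0, tr0_nmol=10.0)
        tc = simulate_cascade(p, np.linspace(0, 100, 11))
        assert np.allclose(tc.values, 10.0, atol=1e-9)

    def test_long_time_limit_is_complete_activation(self):
        tc = simulate_cascade(WT_LIKE, np.linspace(0, 500, 11))
        assert tc.values[-1] == pytest.approx(2010.0, rel=1e-6)

    def test_initial_secant_matches_closed_form_rate(self):
        dt = 1e-3
        tc = simulate_cascade(WT_LIKE, [0.0, dt])
        secant = (tc.values[1] - tc.values[0]) / dt
        assert secant == pytest.approx(WT_LIKE.initial_rate_nmol_per_min, rel=0.01)
        assert WT_LIKE.initial_rate_nmol_per_min == pytest.approx(30.9)

    @pytest.mark.parametrize("seed", range(8))
    def test_mass_conservation_and_monotonicity(self, seed):
        rng = np.random.default_rng(seed)
        p = CascadeParams(
            k_auto=float(rng.uniform(0.001, 5.0)),
            k_ep=float(rng.uniform(0.0, 50.0)),
            tg0_umol=float(rng.uniform(0.5, 5.0)),
            tr0_nmol=float(rng.uniform(0.0, 100.0)),
            ep0_nmol=float(rng.uniform(0.0, 5.0)),
        )
        t = np.linspace(0, 200, 81)
        tc = simulate_cascade(p, t)
        total = p.tg0_umol * 1000.0 + p.tr0_nmol
        # [Tg] + [Tr] constant: [Tr] never exceeds the total pool
        assert np.all(tc.values <= total + total * 1e-6)
        assert np.all(np.diff(tc.values) >= -total * 1e-9)

    def test_activator_only_course_matches_closed_form(self):
        p = CascadeParams(k_auto=0.0, k_ep=20.0, tg0_umol=2.0,
                          tr0_nmol=5.0, ep0_nmol=1.0)
        t = np.linspace(0, 120, 61)
        tc = simulate_cascade(p, t)
        closed = 2000.0 * (1.0 - np.exp(-p.k_ep * 1e-3 * t)) + 5.0
        assert np.allclose(tc.values, closed, rtol=1e-6, atol=1e-3)

    def test_autocatalytic_course_is_sigmoidal(self):
        tc = simulate_cascade(WT_LIKE, np.linspace(0, 6, 301))
        d2 = np.diff(tc.values, 2)
        inflection = np.where(np.sign(d2[:-1]) > np.sign(d2[1:]))[0]
        assert len(inflection) >= 1  # accelerating then decelerating

    def test_grid_must_start_at_zero(self):
        with pytest.raises(ValueError):
            simulate_cascade(WT_LIKE, [1.0, 2.0])


class TestActivityConversion:
    def test_unit_arithmetic(self):
        spec = EnzymeSpec("toy", molar_mass=20_000.0, specific_activity=50.0)
        assert activity_to_concentration(1.0, spec) == pytest.approx(1.0)  # umol/L
        assert activity_to_concentration(0.0, spec) == 0.0

    def test_roundtrip(self):
        spec = EnzymeSpec("toy", molar_mass=23_456.0, specific_activity=69.0)
        c = activity_to_concentration(3.3, spec)
        assert concentration_to_activity(c, spec) == pytest.approx(3.3)

    def test_molar_mass_from_sequence_is_reasonable(self):
        # ~110 g/mol per residue on average
        mass = molar_mass_from_sequence("ACDEFGHIKLMNPQRSTVWY")
        assert 2000 < mass < 3000


class TestEstimateActivationRate:
    def test_exact_linear_course(self):
        t = np.arange(0, 10.0, 1.0)
        tc = TimeCourse(times=t, values=5.0 * t, unit=UNIT_CONC)
        est = estimate_activation_rate(tc, total_zymogen_nmol=1e6)
        assert est.rate_nmol_per_min == pytest.approx(5.0)
        assert est.r_squared == pytest.approx(1.0)

    def test_constant_course_has_zero_slope(self):
        tc = TimeCourse(times=np.arange(5.0), values=np.full(5, 7.0),
                        unit=UNIT_CONC)
        est = estimate_activation_rate(tc)
        assert est.rate_nmol_per_min == pytest.approx(0.0)
        assert est.r_squared == 1.0

    def test_recovers_simulated_initial_rate(self):
        """On a grid that resolves the linear regime (window short relative
        to the autocatalytic e-folding time) the slope estimate matches the
        generating initial rate."""
        k_fold = WT_LIKE.k_auto * (WT_LIKE.tg0_umol + WT_LIKE.tr0_nmol / 1000.0)
        t = np.linspace(0.0, 0.03 / k_fold, 8)
        tc = simulate_cascade(WT_LIKE, t)
        est = estimate_activation_rate(tc, total_zymogen_nmol=2010.0)
        assert est.rate_nmol_per_min == pytest.approx(30.9, rel=0.02)

    def test_activity_course_converted_before_fitting(self):
        spec = EnzymeSpec("toy", molar_mass=20_000.0, specific_activity=50.0)
        t = np.arange(0, 6.0)
        conc_nmol = 3.0 * t  # nmol/L
        activity = np.array(
            [concentration_to_activity(v / 1000.0, spec) for v in conc_nmol]
        )
        tc = TimeCourse(times=t, values=activity, unit="U_per_mL")
        est = estimate_activation_rate(tc, spec=spec, total_zymogen_nmol=1e6)
        assert est.rate_nmol_per_min == pytest.approx(3.0)

    def test_activity_course_without_spec_rejected(self):
        tc = TimeCourse(times=np.arange(4.0), values=np.arange(4.0),
                        unit="U_per_mL")
        with pytest.raises(ValueError, match="EnzymeSpec"):
            estimate_activation_rate(tc)

    def test_degenerate_course_has_no_window(self):
        # third point already exceeds the allowed conversion
        tc = TimeCourse(times=np.array([0.0, 1.0, 2.0, 3.0]),
                        values=np.array([0.0, 1.0, 900.0, 1000.0]),
                        unit=UNIT_CONC)
        with pytest.raises(NoQualifyingWindowError):
            estimate_activation_rate(tc, total_zymogen_nmol=1000.0)


class TestFitCascade:
    def test_noiseless_recovery_within_one_percent(self):
        t = np.linspace(0, 5, 40)
        tc = simulate_cascade(WT_LIKE, t)
        fit = fit_cascade(tc, tg0_umol=2.0, tr0_nmol=10.0)
        assert fit.k_auto == pytest.approx(1.545, rel=0.01)

    def test_joint_recovery_with_activator(self):
        p = CascadeParams(k_auto=0.8, k_ep=40.0, tg0_umol=2.0,
                          tr0_nmol=2.0, ep0_nmol=1.0)
        tc = simulate_cascade(p, np.linspace(0, 40, 60))
        fit = fit_cascade(tc, tg0_umol=2.0, tr0_nmol=2.0, ep0_nmol=1.0,
                          fit_k_ep=True)
        assert fit.k_auto == pytest.approx(0.8, rel=0.02)
        assert fit.k_ep == pytest.approx(40.0, rel=0.02)

    def test_noisy_recovery_median_within_ten_percent(self):
        t = np.linspace(0, 5, 40)
        clean = simulate_cascade(WT_LIKE, t)
        errors = []
        for seed in range(25):
            noisy = NoiseSpec(kind="multiplicative", sigma=0.05, seed=seed)
            tc = TimeCourse(times=t, values=noisy.apply(clean.values),
                            unit=UNIT_CONC)
            fit = fit_cascade(tc, tg0_umol=2.0, tr0_nmol=10.0)
            errors.append(abs(fit.k_auto - 1.545) / 1.545)
        assert np.median(errors) < 0.10


class TestFitMM:
    def test_roundtrip_noiseless(self):
        data = gen_mm_data(78.0, 324.1, 1.0, [12.5, 25, 50, 100, 200, 400])
        params = fit_mm(data)
        assert params.km_umol == pytest.approx(78.0, rel=1e-3)
        assert params.kcat_per_s == pytest.approx(324.1, rel=1e-3)

    def test_half_saturation_identity(self):
        data = gen_mm_data(50.0, 100.0, 2.0, [10, 25, 50, 100, 300])
        params = fit_mm(data)
        vmax = params.kcat_per_s * 2.0 / 1000.0
        v_at_km = vmax * 50.0 / (params.km_umol + 50.0)
        assert v_at_km == pytest.approx(vmax / 2.0, rel=1e-6)

    @pytest.mark.parametrize("km", [0.5, 5.0, 50.0, 500.0])
    @pytest.mark.parametrize("kcat", [1.0, 100.0])
    def test_bias_below_one_percent_across_magnitudes(self, km, kcat):
        levels = km * np.array([0.2, 0.5, 1.0, 2.0, 5.0, 10.0])
        data = gen_mm_data(km, kcat, 1.0, levels)
        params = fit_mm(data)
        assert params.km_umol == pytest.approx(km, rel=0.01)
        assert params.kcat_per_s == pytest.approx(kcat, rel=0.01)

    def test_efficiency_is_kcat_over_km(self):
        params = fit_mm(gen_mm_data(100.0, 200.0, 1.0, [20, 50, 100, 200, 500]))
        assert params.efficiency == pytest.approx(params.kcat_per_s / params.km_umol)

    def test_too_few_substrate_levels_rejected(self):
        with pytest.raises(ValueError, match="4 distinct"):
            fit_mm(MMDataset(np.array([10.0, 20.0, 30.0]),
                             np.array([1.0, 1.5, 1.8]), 1.0))


class TestFoldDifference:
    def test_identity(self):
        assert fold_difference(3.3, 3.3) == 1.0

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            fold_difference(1.0, 0.0)


class TestCsvIO:
    def test_timecourse_roundtrip(self, tmp_path):
        tc = gen_timecourse(WT_LIKE, np.linspace(0, 2, 9))
        path = tmp_path / "tc.csv"
        write_timecourse_csv(tc, path)
        back = read_timecourse_csv(path)
        assert back.unit == UNIT_CONC
        assert np.allclose(back.values, tc.values)

    def test_mm_roundtrip(self, tmp_path):
        data = gen_mm_data(78.0, 324.1, 1.0, [25, 50, 100, 200])
        path = tmp_path / "mm.csv"
        write_mm_csv(data, path)
        back = read_mm_csv(path, e0_nmol=1.0)
        assert np.allclose(back.velocity_umol_per_s, data.velocity_umol_per_s)
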