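import math
from dataclasses import replace

import numpy as np
import pytest

from znpp.core_io import Session, Site, Spectrum, default_grid
from znpp.quantify import (
    BloodIndexResult,
    QuantifyConfig,
    accept_site,
    blood_absorption_index,
    difference_spectrum,
    fit_difference_spectrum,
    quantify_subject,
    repeatability_split,
    second_derivative,
)
from znpp.synthetic import (
    SpectrumGenSpec,
    generate_difference_fixture,
    generate_session,
    generate_spectrum_pair,
)


class TestDifferenceSpectrum:
    def test_identical_spectra_cancel(self, make_spectrum):
        f = make_spectrum(np.linspace(50, 10, 251), calibrated=True)
        f407 = replace(f, excitation_nm=407)
        d = difference_spectrum(f, f407)
        assert d.norm_k == pytest.approx(1.0)
        np.testing.assert_allclose(d.values, 0.0, atol=1e-12)

    def test_invariant_to_common_rescaling(self, refs):
        cyc = generate_spectrum_pair(SpectrumGenSpec(seed=3), refs).calibrated()
        d1 = difference_spectrum(cyc.f425, cyc.f407)
        d2 = difference_spectrum(cyc.f425.scaled(7.5), cyc.f407.scaled(7.5))
        np.testing.assert_allclose(d2.values, 7.5 * d1.values, rtol=1e-9)

    def test_norm_window_mean_is_zero(self, refs):
        cyc = generate_spectrum_pair(SpectrumGenSpec(seed=4), refs).calibrated()
        d = difference_spectrum(cyc.f425, cyc.f407)
        mask = d.grid.band_mask(520.0, 525.0)
        scale = np.abs(cyc.f425.intensity).max()
        assert abs(d.values[mask].mean()) < 1e-9 * scale

    def test_retains_78_percent_of_znpp(self, refs):
        """Equal backgrounds, ZnPP at excitation ratio 0.22: the difference
        keeps ~78% of the 425-excited amplitude."""
        spec = SpectrumGenSpec(
            znpp_amplitude=2.0, ppix_amplitude=0.0, blood_path_a=0.0
        ).noiseless()
        cyc = generate_spectrum_pair(spec, refs).calibrated()
        d = difference_spectrum(cyc.f425, cyc.f407)
        i593 = int(np.argmin(np.abs(d.grid.values - 593.0)))
        assert d.values[i593] == pytest.approx(0.78 * 2.0, rel=1e-6)

    def test_degenerate_normalisation_band(self, make_spectrum):
        f425 = make_spectrum(1.0, calibrated=True)
        f407 = make_spectrum(0.0, excitation_nm=407, calibrated=True)
        with pytest.raises(ValueError, match="degenerate"):
            difference_spectrum(f425, f407)


class TestSecondDerivative:
    def test_linear_ramp_is_zero(self):
        lam = np.arange(0.0, 100.0)
        d2 = second_derivative(3.0 * lam + 1.0, 1.0)
        np.testing.assert_allclose(d2, 0.0, atol=1e-10)

    def test_quadratic_gives_constant(self):
        lam = np.arange(0.0, 100.0)
        d2 = second_derivative(0.5 * lam**2, 1.0)
        np.testing.assert_allclose(d2, 1.0, rtol=1e-9)

    @pytest.mark.parametrize("period", [20.0, 40.0, 80.0])
    def test_sine_amplitude_scaling(self, period):
        lam = np.arange(0.0, 400.0)
        v = np.sin(2 * np.pi * lam / period)
        d2 = second_derivative(v, 1.0)
        expected = (2 * np.pi / period) ** 2
        assert np.abs(d2).max() == pytest.approx(expected, rel=0.01)


class TestFit:
    def test_featureless_background_gives_zero_amplitudes(self, refs):
        """Nothing to remove: a curvature-free (linear) background yields
        amplitudes of exactly zero, and a gently curved cubic leaks only a
        sliver of its curvature into (z, p) — orders of magnitude below the
        amplitudes the method measures (the leakage is linear in the
        background's second derivative)."""
        from znpp.quantify import DifferenceSpectrum

        grid = default_grid()
        x = (grid.values - 625.0) / 125.0
        linear = 80.0 + 10.0 * x
        fit_lin = fit_difference_spectrum(
            DifferenceSpectrum(grid=grid, values=linear, norm_k=1.0), refs
        )
        assert abs(fit_lin.z) < 1e-9 * 80.0
        assert abs(fit_lin.p) < 1e-9 * 80.0

        cubic = 80.0 + 10.0 * x - 6.0 * x**2 + 2.0 * x**3
        fit_cub = fit_difference_spectrum(
            DifferenceSpectrum(grid=grid, values=cubic, norm_k=1.0), refs
        )
        assert abs(fit_cub.z) < 2e-3  # ~0.1% of a typical z amplitude of 2
        assert abs(fit_cub.p) < 2e-3

    def test_noiseless_parameter_recovery(self, refs):
        spec = SpectrumGenSpec(
            blood_path_a=0.007, znpp_amplitude=2.0, ppix_amplitude=-0.5
        ).noiseless()
        diff, truth = generate_difference_fixture(spec, refs)
        fit = fit_difference_spectrum(diff, refs)
        assert fit.z == pytest.approx(truth["z"], rel=0.01)
        assert fit.p == pytest.approx(truth["p"], rel=0.01)
        assert fit.a == pytest.approx(truth["a"], rel=0.05)
        assert fit.converged

    def test_objective_at_optimum_below_truth(self, refs):
        from znpp.quantify import _curvature_operator

        spec = SpectrumGenSpec(
            blood_path_a=0.007, znpp_amplitude=2.0, ppix_amplitude=-0.5
        ).noiseless()
        diff, truth = generate_difference_fixture(spec, refs)
        fit = fit_difference_spectrum(diff, refs)
        cfg = QuantifyConfig()
        refs_g = refs.on_grid(diff.grid)
        mu = refs_g.mu_a_on(diff.grid)
        curv = _curvature_operator(cfg, diff.grid)
        e = np.exp(-truth["a"] * mu)
        resid = curv(
            (diff.values - truth["z"] * refs_g.znpp.shape
             - truth["p"] * refs_g.ppix.shape) / e
        )
        assert fit.objective_value <= resid @ resid + 1e-15

    def test_recovered_z_linear_in_generated_z(self, refs):
        z_in = np.linspace(0.0, 10.0, 6)
        z_out = []
        for z0 in z_in:
            spec = SpectrumGenSpec(
                blood_path_a=0.007, znpp_amplitude=float(z0), ppix_amplitude=0.3
            ).noiseless()
            diff, _ = generate_difference_fixture(spec, refs)
            z_out.append(fit_difference_spectrum(diff, refs).z)
        slope, intercept = np.polyfit(z_in, z_out, 1)
        pred = slope * z_in + intercept
        ss_res = np.sum((np.array(z_out) - pred) ** 2)
        ss_tot = np.sum((np.array(z_out) - np.mean(z_out)) ** 2)
        assert slope == pytest.approx(1.0, rel=0.02)
        assert 1 - ss_res / ss_tot > 0.999

    def test_z_stable_across_green_zone_blood_paths(self, refs):
        """Site qualification rationale: with ZnPP/haem fixed, the recovered
        amplitude moves < 5% while the blood path spans the green zone."""
        z_hat = []
        for a0 in (0.007, 0.010, 0.014, 0.020):
            spec = SpectrumGenSpec(
                blood_path_a=a0, znpp_amplitude=2.0, ppix_amplitude=-0.5
            ).noiseless()
            diff, _ = generate_difference_fixture(spec, refs)
            z_hat.append(fit_difference_spectrum(diff, refs).z)
        assert (max(z_hat) - min(z_hat)) / np.mean(z_hat) < 0.05


class TestBloodIndex:
    def test_flat_background_reports_zero_red(self, refs):
        spec = SpectrumGenSpec(
            blood_path_a=0.0, znpp_amplitude=0.0, ppix_amplitude=0.0
        ).noiseless()
        cyc = generate_spectrum_pair(spec, refs).calibrated()
        res = blood_absorption_index(cyc.f407, refs)
        assert res.index == pytest.approx(0.0, abs=2e-4)
        assert res.zone == "red"

    def test_round_trip_recovery_green(self, refs):
        spec = SpectrumGenSpec(
            blood_path_a=0.009, znpp_amplitude=0.0, ppix_amplitude=0.0
        ).noiseless()
        cyc = generate_spectrum_pair(spec, refs).calibrated()
        res = blood_absorption_index(cyc.f407, refs)
        assert res.index == pytest.approx(0.009, rel=0.05)
        assert res.zone == "green"

    def test_invariant_to_background_scaling(self, refs):
        spec = SpectrumGenSpec(blood_path_a=0.008).noiseless()
        cyc = generate_spectrum_pair(spec, refs).calibrated()
        r1 = blood_absorption_index(cyc.f407, refs)
        r2 = blood_absorption_index(cyc.f407.scaled(13.0), refs)
        assert r1.index == pytest.approx(r2.index, rel=1e-9)

    @pytest.mark.parametrize(
        "index,zone",
        [
            (0.0050, "orange"),
            (0.0005, "red"),
            (0.0014, "red_orange"),
            (0.0042, "orange"),
            (0.0070, "green"),
            (0.0071, "green"),
            (0.0041, "red_orange"),
        ],
    )
    def test_zone_thresholds(self, index, zone):
        from znpp.quantify import _zone

        assert _zone(index, QuantifyConfig().index_thresholds) == zone

    def test_two_band_mode_round_trip(self, refs):
        """The closed-form 561/576 variant assumes equal underlying
        baselines (its use case: simulated autofluorescence with identical
        generation), so it is checked on a flat background."""
        spec = SpectrumGenSpec(
            blood_path_a=0.009, znpp_amplitude=0.0, ppix_amplitude=0.0,
            background_control_points={500.0: 90.0, 750.0: 90.0},
        ).noiseless()
        cyc = generate_spectrum_pair(spec, refs).calibrated()
        cfg = QuantifyConfig(index_mode="two_band")
        res = blood_absorption_index(cyc.f407, refs, cfg)
        assert res.index == pytest.approx(0.009, rel=0.05)


class TestAcceptSite:
    @pytest.mark.parametrize(
        "index,accepted", [(0.0071, True), (0.0070, True), (0.0, False), (0.005, False)]
    )
    def test_boundary_rule(self, index, accepted):
        from znpp.quantify import _zone

        zone = _zone(index, QuantifyConfig().index_thresholds)
        assert accept_site(BloodIndexResult(index, zone)) is accepted


@pytest.fixture(scope="module")
def session():
    from znpp.references import load_reference_library

    refs = load_reference_library()
    return generate_session(
        SpectrumGenSpec(seed=21), refs, n_sites=3, cycles_per_site=4
    )


class TestQuantifySubject:
    def test_mean_sem_definition(self, refs, session):
        result = quantify_subject(session, refs)
        z = np.array([f.z for f in result.fits])
        assert result.n_cycles == 12
        assert result.mean_z == pytest.approx(z.mean())
        assert result.sem_z == pytest.approx(z.std(ddof=1) / math.sqrt(12))

    def test_refuses_empty_session(self, refs):
        with pytest.raises(ValueError, match="no valid cycles"):
            quantify_subject(Session(subject_id="e", sites=[]), refs)

    def test_single_cycle_flags_sem(self, refs, session):
        one = Session(
            subject_id="one", sites=[Site(cycles=[session.sites[0].cycles[0]])]
        )
        res = quantify_subject(one, refs)
        assert res.n_cycles == 1 and res.sem_z == 0.0 and res.sem_flagged


class TestRepeatability:
    def test_identical_halves_give_zero(self):
        subjects = [[5.0] * 10 for _ in range(8)]
        assert repeatability_split(subjects) == 0.0

    def test_matches_closed_form_at_study_size(self):
        """LoA of half-mean differences ~ 1.96 * sigma_site * sqrt(2/5)."""
        rng = np.random.default_rng(8)
        sigma_site = 4.0
        subjects = [list(60.0 + rng.normal(0, sigma_site, 10)) for _ in range(56)]
        loa = repeatability_split(subjects)
        expected = 1.96 * sigma_site * math.sqrt(2.0 / 5.0)
        assert loa == pytest.approx(expected, rel=0.15)

    def test_needs_cohort_and_ten_sites(self):
        with pytest.raises(ValueError):
            repeatability_split([[1.0] * 10])
        with pytest.raises(ValueError):
            repeatability_split([[1.0] * 9, [1.0] * 9])
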