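import math
from dataclasses import replace

import numpy as np
import pytest
from scipy import integrate

from znpp.mc_fluor import (
    FiberProbe,
    TissueLayer,
    TissueModel,
    default_tissue_model,
    run_excitation,
    run_fluorescence,
    simulated_blood_index,
    sweep,
    transport_emission,
)

PROBE = FiberProbe()


def _uniform_layer(mu_a, mu_s, g=0.0, thickness=5.0, ff=0.1, qy=1.0):
    return TissueLayer(
        thickness_mm=thickness,
        mu_a_exc=mu_a, mu_s_exc=mu_s, g_exc=g,
        mu_a_em=mu_a, mu_s_em=mu_s, g_em=g,
        fluorophore_fraction=ff, quantum_yield=qy,
    )


class TestExcitation:
    def test_vacuum_conserves_and_reaches_bottom(self):
        model = TissueModel(layers=(_uniform_layer(0.0, 0.0, thickness=1.0),))
        res = run_excitation(model, PROBE, n_photons=5000, seed=1)
        assert res.ledger_defect() <= 1e-6
        assert res.ledger["absorbed"] == 0.0
        assert res.ledger["transmitted_bottom"] + res.ledger["escaped_top"] + \
            res.ledger["detected"] == pytest.approx(1.0, abs=1e-12)

    def test_same_seed_bit_identical(self):
        model = default_tissue_model()
        r1 = run_excitation(model, PROBE, n_photons=5000, seed=42)
        r2 = run_excitation(model, PROBE, n_photons=5000, seed=42)
        assert r1.ledger == r2.ledger
        np.testing.assert_array_equal(
            r1.absorbed_depth_profile[1], r2.absorbed_depth_profile[1]
        )
        r3 = run_excitation(model, PROBE, n_photons=5000, seed=43)
        assert r1.ledger != r3.ledger

    def test_energy_conservation_across_configs(self):
        configs = [
            TissueModel(layers=(_uniform_layer(2.0, 0.0),)),
            TissueModel(layers=(_uniform_layer(0.1, 20.0, g=0.9),)),
            default_tissue_model(),
        ]
        for model in configs:
            res = run_excitation(model, PROBE, n_photons=20000, seed=3)
            assert res.ledger_defect() <= 1e-6

    def test_pure_absorber_beer_lambert(self):
        """Absorbed-depth CDF vs the cone-averaged Beer-Lambert law."""
        mu_a = 2.0
        model = TissueModel(layers=(_uniform_layer(mu_a, 0.0),))
        n = 200_000
        res = run_excitation(model, PROBE, n_photons=n, seed=7, depth_bins=100)
        assert res.ledger_defect() <= 1e-6
        z, hist = res.absorbed_depth_profile
        cum = np.cumsum(hist)
        sin_m = PROBE.numerical_aperture / model.refractive_index

        def analytic_cdf(z0):
            f = lambda u: 1.0 - math.exp(-mu_a * z0 / math.sqrt(1 - sin_m**2 * u))
            return integrate.quad(f, 0.0, 1.0)[0]

        for z0 in (0.25, 0.5, 1.0, 2.0):
            idx = int(z0 / 5.0 * 100) - 1
            expected = analytic_cdf(z[idx] + 0.025)
            se = math.sqrt(expected * (1 - expected) / n)
            assert abs(cum[idx] - expected) <= 3 * se

    def test_rejects_tiny_photon_budget(self):
        with pytest.raises(ValueError):
            run_excitation(default_tissue_model(), PROBE, n_photons=10, seed=0)


class TestFluorescence:
    def test_zero_quantum_yield_zero_fluorescence(self):
        model = TissueModel(
            layers=(_uniform_layer(0.5, 10.0, g=0.8, qy=0.0),)
        )
        res = run_fluorescence(model, PROBE, n_photons=5000, seed=2)
        assert res.total_detected_fluorescence("em") == 0.0

    def test_linearity_in_fluorophore_fraction(self):
        m1 = default_tissue_model(fluorophore_fraction=0.1)
        m2 = default_tissue_model(fluorophore_fraction=0.2)
        r1 = run_fluorescence(m1, PROBE, n_photons=60_000, seed=11)
        r2 = run_fluorescence(m2, PROBE, n_photons=60_000, seed=11)
        t1 = r1.total_detected_fluorescence("em")
        t2 = r2.total_detected_fluorescence("em")
        assert t2 / t1 == pytest.approx(2.0, rel=0.05)

    def test_no_epithelial_fluorescence_when_restricted_to_stroma(self):
        base = default_tissue_model()
        model = TissueModel(
            layers=(replace(base.layers[0], fluorophore_fraction=0.0),)
            + base.layers[1:]
        )
        res = run_fluorescence(model, PROBE, n_photons=20_000, seed=4)
        assert res.detected_fluorescence[("em", 0)] == 0.0
        assert res.total_detected_fluorescence("em") > 0.0

    def test_emission_ledger_conserves(self):
        res = run_fluorescence(default_tissue_model(), PROBE, n_photons=20_000, seed=5)
        for ledger in res.fluorescence_ledgers.values():
            assert abs(sum(ledger.values()) - 1.0) <= 1e-6

    def test_point_source_detection_matches_solid_angle(self):
        """Isotropic emitters on the fibre axis in a transparent slab: the
        detected fraction equals the closed-form acceptance solid angle."""
        model = TissueModel(layers=(_uniform_layer(0.0, 0.0),))
        depth = 0.3
        n = 100_000
        pos = np.tile([0.0, 0.0, depth], (n, 1))
        ledger, _ = transport_emission(
            model, PROBE, pos, np.zeros(n, dtype=np.int64), np.ones(n), seed=6
        )
        sin_acc = PROBE.numerical_aperture / model.refractive_index
        theta_min = min(math.atan(PROBE.radius_mm / depth), math.asin(sin_acc))
        expected = (1.0 - math.cos(theta_min)) / 2.0
        se = math.sqrt(expected / n)
        assert abs(ledger["detected"] - expected) <= 3 * se

    def test_reciprocity_of_exc_em_properties(self):
        """Transport reciprocity in a uniform slab: swapping the excitation
        and emission optical properties leaves the detected fluorescence
        unchanged once the generation weighting (proportional to mu_a at
        excitation) is factored out — detected/mu_a_exc is symmetric."""
        lay_a = TissueLayer(
            thickness_mm=5.0, mu_a_exc=0.4, mu_s_exc=15.0, g_exc=0.9,
            mu_a_em=0.2, mu_s_em=10.0, g_em=0.8,
        )
        lay_b = TissueLayer(
            thickness_mm=5.0, mu_a_exc=0.2, mu_s_exc=10.0, g_exc=0.8,
            mu_a_em=0.4, mu_s_em=15.0, g_em=0.9,
        )
        r_ab = run_fluorescence(TissueModel(layers=(lay_a,)), PROBE,
                                n_photons=60_000, seed=12)
        r_ba = run_fluorescence(TissueModel(layers=(lay_b,)), PROBE,
                                n_photons=60_000, seed=13)
        t_ab = r_ab.total_detected_fluorescence("em") / lay_a.mu_a_exc
        t_ba = r_ba.total_detected_fluorescence("em") / lay_b.mu_a_exc
        assert t_ab == pytest.approx(t_ba, rel=0.10)

    def test_detected_fluorescence_nondecreasing_in_fiber_diameter(self):
        totals = []
        for d_um in (400.0, 1000.0):
            probe = FiberProbe(diameter_um=d_um)
            res = run_fluorescence(default_tissue_model(), probe,
                                   n_photons=60_000, seed=14)
            totals.append(res.total_detected_fluorescence("em"))
        assert totals[1] > totals[0]


class TestSimulatedBloodIndex:
    def test_equal_signals_give_zero(self):
        assert simulated_blood_index(0.5, 0.5, 19.1, 28.4) == 0.0

    def test_algebraic_inverse_exact(self):
        a0 = 0.007
        g561 = 0.3 * math.exp(-a0 * 19.07)
        g576 = 0.3 * math.exp(-a0 * 28.42)
        assert simulated_blood_index(g561, g576, 19.07, 28.42) == pytest.approx(
            a0, rel=1e-12
        )

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            simulated_blood_index(0.0, 0.1, 19.0, 28.0)

    def test_index_increases_with_stromal_blood(self, refs):
        from znpp.references import VesselGeometry, corrected_mu_a

        indices = []
        for bf in (0.01, 0.04):
            em_props = {}
            for wl in (561.0, 576.0):
                mu_em = corrected_mu_a(
                    float(refs.blood.mu_a(wl)), VesselGeometry(24.0, bf)
                )
                em_props[wl] = [
                    (0.025, 9.0, 0.9),
                    (0.025 + mu_em, 13.0, 0.9),
                    (0.025 + mu_em, 13.0, 0.9),
                ]
            model = default_tissue_model(blood_fraction=bf)
            res = run_fluorescence(model, PROBE, em_props,
                                   n_photons=60_000, seed=9)
            g561 = res.total_detected_fluorescence(561.0)
            g576 = res.total_detected_fluorescence(576.0)
            indices.append(
                simulated_blood_index(
                    g561, g576,
                    float(refs.blood.mu_a(561.0)), float(refs.blood.mu_a(576.0)),
                )
            )
        assert indices[1] > indices[0]


class TestSweep:
    def test_single_cell_equals_direct_run(self):
        df = sweep(n_photons=5000, seed=17)
        assert len(df) == 1
        direct = run_fluorescence(default_tissue_model(), PROBE,
                                  n_photons=5000, seed=17)
        assert df.loc[0, "detected_fluorescence"] == pytest.approx(
            direct.total_detected_fluorescence("em"), rel=1e-12
        )
        assert df.loc[0, "seed"] == 17

    def test_vessel_diameter_cells_use_packaged_mu_a(self):
        """The 24/38/52-um cells must carry the packaged 425-nm stromal
        absorption 0.413/0.263/0.192 (on top of the stromal baseline)."""
        for d_um, packed in [(24.0, 0.413), (38.0, 0.263), (52.0, 0.192)]:
            model = default_tissue_model(vessel_diameter_um=d_um)
            assert model.layers[2].mu_a_exc - 0.05 == pytest.approx(packed, abs=2e-3)

    def test_16pct_blood_cell_supported(self):
        model = default_tissue_model(blood_fraction=0.16)
        assert model.layers[2].mu_a_exc > default_tissue_model().layers[2].mu_a_exc

    def test_grid_enumerates_cells(self):
        df = sweep(
            epithelium_um=(100.0, 200.0),
            fiber_diameter_um=(400.0, 1000.0),
            n_photons=2000, seed=23,
        )
        assert len(df) == 4
        assert df["ledger_defect"].max() <= 1e-6
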