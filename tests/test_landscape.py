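"""Synthetic permeant engine: landscape shape, titration kinetics, observables."""

import numpy as np
import pytest
from scipy.optimize import brentq

import permweight as pw
from permweight.errors import StabilityWarning
from permweight.landscape import observable_mean, sample_observables


class TestFreeEnergy:
    def test_barrier_height_at_center(self):
        land = pw.ToyLandscape(barrier_height=7.8)
        assert pw.free_energy(land, 0.0, "deprotonated") == pytest.approx(7.8, abs=1e-6)

    def test_preset_marginalized_barrier_is_nominal(self):
        """Presets calibrate the neutral-state amplitude so the observed
        (titration-marginalized) barrier at pH 7.5 equals the nominal
        barrier height."""
        land = pw.make_opioid_presets()["fentanyl"]
        eff = pw.effective_free_energy(land, 0.0, 7.5) - pw.effective_free_energy(
            land, 40.0, 7.5
        )
        assert eff == pytest.approx(7.8, abs=1e-6)
        assert land.barrier_amplitude < land.barrier_height

    def test_bulk_reference_zero(self):
        land = pw.make_opioid_presets()["fentanyl"]
        for state in ("protonated", "deprotonated"):
            assert pw.free_energy(land, 40.0, state) == pytest.approx(0.0, abs=1e-6)

    def test_even_in_z(self):
        land = pw.make_opioid_presets()["morphine"]
        z = np.linspace(0.0, 40.0, 161)
        for state in ("protonated", "deprotonated"):
            np.testing.assert_allclose(
                pw.free_energy(land, z, state), pw.free_energy(land, -z, state)
            )

    def test_charged_penalty_inside_membrane(self):
        land = pw.make_opioid_presets()["fentanyl"]
        gp = pw.free_energy(land, 0.0, "protonated")
        gd = pw.free_energy(land, 0.0, "deprotonated")
        assert gp - gd == pytest.approx(land.charged_penalty, rel=1e-6)

    def test_interface_wells(self):
        land = pw.make_opioid_presets()["fentanyl"]
        assert pw.free_energy(land, 20.0, "deprotonated") < 0.0

    def test_unknown_state_rejected(self):
        with pytest.raises(ValueError):
            pw.free_energy(pw.ToyLandscape(), 0.0, "zwitterionic")


class TestLocalPKa:
    def test_bulk_value_exact(self):
        land = pw.make_opioid_presets()["fentanyl"]
        assert pw.local_pKa(land, 40.0) == land.solution_pKa
        assert pw.local_pKa(land, -40.0) == land.solution_pKa

    def test_full_shift_at_center(self):
        land = pw.ToyLandscape(solution_pKa=8.4, pKa_shift_scale=6.0)
        assert pw.local_pKa(land, 0.0) == pytest.approx(2.4, abs=1e-9)

    @pytest.mark.parametrize("name", list(pw.make_opioid_presets()))
    def test_neutral_midpoint_inside_membrane(self, name):
        """The z where the permeant becomes half-neutral at pH 7.5 lies
        inside the membrane leaflet for every preset."""
        land = pw.make_opioid_presets()[name]
        z_mid = brentq(lambda z: pw.local_pKa(land, z) - 7.5, 0.1, 24.9)
        assert 0.0 < z_mid < 20.0

    def test_monotone_decrease_toward_core(self):
        land = pw.make_opioid_presets()["fentanyl"]
        z = np.linspace(0.0, 25.0, 251)
        pka = land.local_pKa(z)
        assert np.all(np.diff(pka) >= -1e-12 + 0)  # non-decreasing outward
        assert pka[0] < pka[-1]


class TestPresets:
    def test_barriers_and_pkas(self):
        p = pw.make_opioid_presets()
        assert [p[n].barrier_height for n in ("fentanyl", "morphine", "isotonitazene", "naloxone")] == [7.8, 14.2, 24.8, 33.4]
        assert p["fentanyl"].solution_pKa == 8.4
        assert p["morphine"].solution_pKa == 8.2
        assert p["isotonitazene"].solution_pKa == 8.7
        assert p["naloxone"].solution_pKa == 7.9

    def test_scaled_family_preserves_order(self):
        for fam in (pw.make_opioid_presets(), pw.make_scaled_presets()):
            barriers = [fam[n].barrier_height for n in ("fentanyl", "morphine", "isotonitazene", "naloxone")]
            assert barriers == sorted(barriers)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            pw.ToyLandscape(barrier_height=-1.0)
        with pytest.raises(ValueError):
            pw.ToyLandscape(diffusion_coeff=0.0)


class TestPropagate:
    def test_deterministic_given_seed(self, scaled_fentanyl):
        w = pw.Walker(z=25.0, lam=0.0, weight=0.125)
        a = pw.propagate(w, scaled_fentanyl, tau=100.0, dt=10.0, pH=7.5, seed=3)
        b = pw.propagate(w, scaled_fentanyl, tau=100.0, dt=10.0, pH=7.5, seed=3)
        assert a.z == b.z and a.lam == b.lam and a.observables == b.observables

    def test_weight_unchanged(self, scaled_fentanyl):
        w = pw.Walker(z=30.0, lam=1.0, weight=0.07)
        out = pw.propagate(w, scaled_fentanyl, tau=50.0, dt=10.0, pH=7.5, seed=1)
        assert out.weight == 0.07

    def test_free_diffusion_msd(self, flat_landscape):
        """Mean-squared displacement on a flat landscape is 2*D*tau."""
        from permweight.landscape import _step_batch

        n, tau, dt = 4000, 10.0, 0.05
        z, _ = _step_batch(
            np.zeros(n), np.zeros(n), flat_landscape, 7.5, dt, int(tau / dt),
            np.random.default_rng(3), -1e6, 1e6,
        )
        msd = float((z**2).mean())
        expected = 2.0 * flat_landscape.diffusion_coeff * tau
        assert msd == pytest.approx(expected, rel=0.1)

    def test_large_dt_warns(self, scaled_fentanyl):
        w = pw.Walker(z=30.0, lam=0.0, weight=1.0)
        with pytest.warns(StabilityWarning):
            pw.propagate(w, scaled_fentanyl, tau=500.0, dt=500.0, pH=7.5, seed=0)

    def test_invalid_tau_dt(self, scaled_fentanyl):
        w = pw.Walker(z=30.0, lam=0.0, weight=1.0)
        with pytest.raises(ValueError):
            pw.propagate(w, scaled_fentanyl, tau=1.0, dt=10.0, pH=7.5, seed=0)


class TestTitrationKinetics:
    @pytest.mark.parametrize("ph", [7.0, 7.9, 8.4, 9.0])
    def test_pinned_walker_detailed_balance(self, ph):
        """A walker pinned in bulk reaches the Henderson–Hasselbalch
        deprotonated fraction (detailed-balance limit)."""
        states = pw.titration_trajectory(7.9, ph, n_attempts=60_000, seed=17)
        frac = states[30_000:].mean()
        assert frac == pytest.approx(pw.neutral_fraction(7.9, ph), abs=0.02)

    def test_flip_rate_ratio_matches_hh(self):
        """The configured flip rates satisfy k_deprot/k_prot = 10^(pH-pKa)."""
        f = pw.neutral_fraction(8.4, 7.5)
        assert f / (1.0 - f) == pytest.approx(10.0 ** (7.5 - 8.4), rel=1e-12)

    def test_simulated_curve_fit_recovers_pka(self):
        curve = pw.simulate_titration_curve(8.2, n_attempts=30_000, seed=4)
        pka, _ = pw.fit_henderson_hasselbalch(curve)
        assert abs(pka - 8.2) < 0.1


class TestObservables:
    def test_fast_desolvation_near_core(self):
        """Fast-desolvating presets lose essentially all hydration below
        |z| of about 5 Å."""
        obs = pw.make_opioid_presets()["fentanyl"].observables
        assert observable_mean(4.0, "hydration", obs) < 1.0
        assert observable_mean(40.0, "hydration", obs) == pytest.approx(
            obs.hydration_bulk, rel=1e-6
        )

    def test_slow_presets_retain_waters(self):
        obs = pw.make_opioid_presets()["naloxone"].observables
        assert observable_mean(6.0, "hydration", obs) > 1.0

    def test_generator_means_match_samples(self):
        obs = pw.make_opioid_presets()["morphine"].observables
        rng = np.random.default_rng(9)
        for z0 in (0.0, 10.0, 25.0, 40.0):
            z = np.full(4000, z0)
            sample = sample_observables(z, np.ones(4000), obs, rng)
            for channel in ("hydration", "hbond_count", "hydrophobic_contacts"):
                mu = observable_mean(z0, channel, obs)
                assert sample[channel].mean() == pytest.approx(mu, abs=max(0.15, 0.05 * mu))

    def test_orientation_bimodal_at_interface(self):
        obs = pw.make_opioid_presets()["fentanyl"].observables
        rng = np.random.default_rng(2)
        ang = sample_observables(np.full(6000, 20.0), np.ones(6000), obs, rng)[
            "orientation_angle"
        ]
        near_modes = ((np.abs(ang - 30) < 20) | (np.abs(ang - 160) < 20)).mean()
        assert near_modes > 0.8
        ang_bulk = sample_observables(np.full(6000, 40.0), np.ones(6000), obs, rng)[
            "orientation_angle"
        ]
        assert ((np.abs(ang_bulk - 30) < 20) | (np.abs(ang_bulk - 160) < 20)).mean() < 0.5

    def test_thinning_is_charge_dependent(self):
        obs = pw.make_opioid_presets()["naloxone"].observables
        rng = np.random.default_rng(0)
        z = np.zeros(3000)
        charged = sample_observables(z, np.zeros(3000), obs, rng)["delta_thickness"]
        neutral = sample_observables(z, np.ones(3000), obs, rng)["delta_thickness"]
        assert charged.mean() < neutral.mean() < 0.0  # thinning mostly when charged

    def test_unknown_channel(self):
        with pytest.raises(KeyError):
            observable_mean(0.0, "nope", pw.ObservableParams())
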