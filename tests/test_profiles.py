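"""z-resolved profiling: weighted PMF, symmetrization, observables."""

import numpy as np
import pytest

import permweight as pw
from permweight import units
from permweight.landscape import observable_mean
from permweight.we import IterationRecord, WalkerTable


def _record(z, w, lam=None, obs=None, tau=100.0, index=0):
    z = np.asarray(z, dtype=float)
    return IterationRecord(
        index=index,
        tau=tau,
        walkers=WalkerTable(
            z=z,
            lam=np.zeros_like(z) if lam is None else np.asarray(lam, float),
            weight=np.asarray(w, dtype=float),
            lineage=np.zeros(z.size, np.int8),
            tit_lineage=np.zeros(z.size, np.int8),
            observables=obs or {},
        ),
    )


def _boltzmann_records(landscape, pH=7.5, bin_width=0.5, z_range=(-30.0, 30.0)):
    """Records whose weights are the exact Boltzmann bin masses (quadrature)."""
    edges = np.arange(z_range[0], z_range[1] + bin_width / 2, bin_width)
    probs = pw.boltzmann_density(landscape, edges, pH)
    centers = (edges[:-1] + edges[1:]) / 2
    return [_record(centers, probs)]


class TestWeightedPmf:
    def test_uniform_weights_flat_profile(self):
        rec = _record(np.arange(0.5, 10.0, 1.0), np.full(10, 0.1))
        prof = pw.weighted_pmf([rec], bin_width=1.0)
        np.testing.assert_allclose(prof.pmf, 0.0, atol=1e-12)

    def test_thermal_energy_at_300K(self):
        rec = _record([0.0], [1.0])
        assert pw.weighted_pmf([rec]).kT == pytest.approx(0.5961, abs=1e-4)

    @pytest.mark.parametrize("name", ["fentanyl", "naloxone"])
    def test_boltzmann_weights_recover_landscape(self, name):
        """Boltzmann-distributed weights reproduce the generating free
        energy up to an additive constant (quadrature oracle)."""
        land = pw.make_opioid_presets()[name]
        records = _boltzmann_records(land)
        prof = pw.weighted_pmf(records, bin_width=0.5, z_range=(-30, 30))
        # estimator is exactly -kT ln(bin mass), min-shifted
        w = records[0].walkers.weight
        expected = -prof.kT * np.log(w)
        expected -= expected.min()
        np.testing.assert_allclose(prof.pmf, expected, atol=1e-9)
        # and tracks the generating landscape pointwise away from the
        # steep-gradient regions (finite bins average the density)
        g_eff = pw.effective_free_energy(land, prof.z_grid, 7.5)
        gentle = np.abs(np.gradient(g_eff, prof.z_grid)) < 1.0
        diff = (prof.pmf - (g_eff - g_eff.min()))[gentle]
        assert np.nanmax(np.abs(diff - np.median(diff))) < 0.1

    def test_empty_bins_are_nan(self):
        rec = _record([0.25, 5.25], [0.5, 0.5])
        prof = pw.weighted_pmf([rec], bin_width=0.5, z_range=(0.0, 6.0))
        assert np.isnan(prof.pmf[2])
        assert np.isfinite(prof.pmf[0])

    def test_degenerate_profile_warns(self):
        with pytest.warns(UserWarning, match="degenerate"):
            pw.weighted_pmf([_record([0.1, 0.2], [0.5, 0.5])], bin_width=1.0)


class TestSymmetrize:
    def test_symmetric_profile_unchanged(self):
        z = np.array([-1.75, -0.75, 0.75, 1.75])
        rec = _record(z, [0.2, 0.3, 0.3, 0.2])
        prof = pw.weighted_pmf([rec], bin_width=0.5, z_range=(-2, 2))
        sym = pw.symmetrize(prof)
        np.testing.assert_allclose(
            sym.bin_weights, prof.bin_weights, atol=1e-15
        )

    def test_delta_mass_mirrored(self):
        rec = _record([10.25], [1.0])
        prof = pw.weighted_pmf([rec], bin_width=0.5, z_range=(-11, 11))
        sym = pw.symmetrize(prof)
        i_pos = np.argmin(np.abs(sym.z_grid - 10.25))
        i_neg = np.argmin(np.abs(sym.z_grid + 10.25))
        assert sym.bin_weights[i_pos] == pytest.approx(0.5)
        assert sym.bin_weights[i_neg] == pytest.approx(0.5)
        assert sym.pmf[i_pos] == sym.pmf[i_neg]

    def test_idempotent_and_reflection_invariant(self):
        rng = np.random.default_rng(3)
        rec = _record(rng.uniform(-20, 20, 200), rng.uniform(0, 1, 200))
        prof = pw.weighted_pmf([rec], bin_width=1.0, z_range=(-20, 20))
        s1 = pw.symmetrize(prof)
        s2 = pw.symmetrize(s1)
        np.testing.assert_allclose(s1.bin_weights, s2.bin_weights, rtol=1e-12)
        np.testing.assert_allclose(s1.bin_weights, s1.bin_weights[::-1], rtol=1e-12)


class TestDeprotonationProfile:
    def test_fully_deprotonated(self):
        rec = _record([1.0, 2.0], [0.5, 0.5], lam=[1.0, 1.0])
        prof = pw.deprotonation_profile([rec], bin_width=1.0)
        occupied = np.isfinite(prof.deprotonated_fraction)
        np.testing.assert_allclose(prof.deprotonated_fraction[occupied], 1.0)

    def test_bulk_fraction_matches_hh(self, small_run, scaled_fentanyl):
        """Bulk bins show the solution neutral fraction (~10% at pH 7.5)."""
        prof = pw.deprotonation_profile(small_run, bin_width=2.0, window=100)
        bulk = prof.z_grid > 28.0
        frac = np.nanmean(prof.deprotonated_fraction[bulk])
        expected = pw.neutral_fraction(scaled_fentanyl.solution_pKa, 7.5)
        assert frac == pytest.approx(expected, abs=0.04)

    def test_matches_weighted_average_oracle(self, small_run):
        prof = pw.deprotonation_profile(small_run, bin_width=1.0, window=50)
        z = np.concatenate([r.walkers.z for r in small_run[-50:]])
        lam = np.concatenate([r.walkers.lam for r in small_run[-50:]])
        w = np.concatenate([r.walkers.weight for r in small_run[-50:]])
        i = np.argmax(prof.bin_weights)
        lo = prof.z_grid[i] - 0.5
        sel = (z >= lo) & (z < lo + 1.0)
        assert prof.deprotonated_fraction[i] == pytest.approx(
            np.average(lam[sel], weights=w[sel]), rel=1e-9
        )

    def test_threshold_convention(self):
        rec = _record([1.0, 1.2], [0.5, 0.5], lam=[0.4, 0.6])
        mean_lam = pw.deprotonation_profile([rec], bin_width=1.0)
        thresh = pw.deprotonation_profile([rec], bin_width=1.0, convention="threshold")
        i = np.argmax(mean_lam.bin_weights)
        assert mean_lam.deprotonated_fraction[i] == pytest.approx(0.5)
        assert thresh.deprotonated_fraction[i] == pytest.approx(0.5)  # one of two


class TestObservableProfile:
    def test_constant_channel(self):
        rec = _record([1.0, 5.0, 9.0], [0.2, 0.3, 0.5],
                      obs={"hydration": np.full(3, 7.0)})
        prof = pw.observable_profile([rec], "hydration", bin_width=2.0)
        occ = np.isfinite(prof.observable_means["hydration"])
        np.testing.assert_allclose(prof.observable_means["hydration"][occ], 7.0)

    def test_matches_generator_mean(self, small_run, scaled_fentanyl):
        """Profiled hydration tracks the configured conditional mean."""
        prof = pw.observable_profile(small_run, "hydration", bin_width=2.0, window=100)
        mu = observable_mean(prof.z_grid, "hydration", scaled_fentanyl.observables)
        strong = prof.bin_weights > 0.02
        assert strong.sum() >= 3
        dev = np.abs(prof.observable_means["hydration"][strong] - mu[strong])
        assert np.max(dev) < 2.0

    def test_delta_thickness_bulk_reference(self, small_run):
        prof = pw.observable_profile(
            small_run, "delta_thickness", bin_width=2.0, window=100,
            reference_abs_z=30.0,
        )
        bulk = (np.abs(prof.z_grid) > 30.0) & (prof.bin_weights > 0.01)
        vals = prof.observable_means["delta_thickness"][bulk]
        assert np.abs(np.average(vals, weights=prof.bin_weights[bulk])) < 0.05

    def test_unknown_channel_rejected(self, small_run):
        from permweight.errors import ConfigError

        with pytest.raises(ConfigError):
            pw.observable_profile(small_run, "does_not_exist")

    def test_invariant_under_walker_splitting(self, small_run):
        """Splitting every walker into two equal-weight copies leaves all
        profiles unchanged (weight-consistency)."""
        def split(rec):
            t = rec.walkers
            idx = np.repeat(np.arange(t.n), 2)
            s = t.take(idx)
            s.weight = s.weight / 2.0
            return IterationRecord(index=rec.index, tau=rec.tau, walkers=s)

        subset = small_run[-20:]
        doubled = [split(r) for r in subset]
        p1 = pw.weighted_pmf(subset, bin_width=1.0)
        p2 = pw.weighted_pmf(doubled, bin_width=1.0)
        np.testing.assert_allclose(p1.bin_weights, p2.bin_weights, rtol=1e-6)
        d1 = pw.deprotonation_profile(subset, bin_width=1.0)
        d2 = pw.deprotonation_profile(doubled, bin_width=1.0)
        np.testing.assert_allclose(
            d1.deprotonated_fraction, d2.deprotonated_fraction, rtol=1e-6, equal_nan=True
        )


class TestOrientationFreeEnergy:
    def test_uniform_angles_flat(self):
        rng = np.random.default_rng(0)
        n = 20000
        rec = _record(
            np.full(n, 20.0), np.full(n, 1.0 / n),
            obs={"orientation_angle": rng.uniform(0, 180, n)},
        )
        out = pw.orientation_free_energy([rec], regions={"interface": (18, 22)},
                                         angle_bin=30.0)
        _, F = out["interface"]
        assert np.nanmax(F) < 0.15  # flat within sampling noise

    def test_bimodal_interface_minima(self, small_run):
        out = pw.orientation_free_energy(small_run, window=100, angle_bin=15.0)
        ang, F = out["interface"]
        f30 = F[np.argmin(np.abs(ang - 30))]
        f160 = F[np.argmin(np.abs(ang - 160))]
        f90 = F[np.argmin(np.abs(ang - 90))]
        assert np.isfinite(f30) and np.isfinite(f160)
        # the perpendicular orientation is rare: either penalized or never
        # visited at all (empty bin)
        assert np.isnan(f90) or (f30 < f90 and f160 < f90)

    def test_empty_region_all_nan(self):
        rec = _record([20.0], [1.0], obs={"orientation_angle": np.array([30.0])})
        out = pw.orientation_free_energy([rec], regions={"core": (-2, 2)})
        assert np.isnan(out["core"][1]).all()

    def test_matches_weighted_histogram_oracle(self, small_run):
        out = pw.orientation_free_energy(
            small_run, regions={"interface": (18.0, 22.0)}, angle_bin=15.0, window=50
        )
        ang_centers, F = out["interface"]
        z = np.concatenate([r.walkers.z for r in small_run[-50:]])
        w = np.concatenate([r.walkers.weight for r in small_run[-50:]]) / 50
        a = np.concatenate(
            [r.walkers.observables["orientation_angle"] for r in small_run[-50:]]
        )
        sel = (z >= 18.0) & (z <= 22.0)
        hist, _ = np.histogram(a[sel], bins=np.arange(0, 181, 15.0), weights=w[sel])
        kT = units.kT(300.0)
        expected = np.full(hist.size, np.nan)
        expected[hist > 0] = -kT * np.log(hist[hist > 0])
        expected -= np.nanmin(expected)
        np.testing.assert_allclose(F, expected, rtol=1e-9, equal_nan=True)


class TestPlottingHelpers:
    def test_profile_and_flux_plots(self, small_run, tmp_path):
        import matplotlib

        matplotlib.use("Agg")
        from permweight.plotting import plot_flux_series, plot_profile

        prof = pw.weighted_pmf(small_run, bin_width=1.0, window=50)
        ax = plot_profile(prof, quantity="pmf", interpolate=True)
        assert ax.get_xlabel() == "z (Å)"
        ax2 = plot_flux_series(pw.flux_series(small_run))
        assert ax2.get_ylabel() == "flux (1/s)"
        import matplotlib.pyplot as plt

        plt.close("all")
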