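"""WHAM free-energy reconstruction against analytic ground truth."""

import numpy as np
import pytest

from chromion.synthetic import (analytic_profile_1d, double_well,
                                double_well_windows, sample_biased_1d,
                                separable_2d_windows)
from chromion.units import KB
from chromion.wham import (FreeEnergyProfile, UmbrellaWindow, binding_free_energy,
                           independent_error, reweight_observable, wham, wham2d)

KT = KB * 300.0


class TestWham1D:
    def test_unbiased_single_window_reduces_to_log_histogram(self):
        rng = np.random.default_rng(0)
        samples = rng.normal(0.0, 1.0, 50000)
        edges = np.linspace(-3, 3, 25)
        w = UmbrellaWindow(cv_names=("x",), k=0.0, center=0.0, samples=samples)
        prof = wham([w], edges)
        hist, _ = np.histogram(samples, bins=edges)
        expected = -np.log(hist.astype(float))
        expected -= expected.min()
        assert np.allclose(prof.free_energy, expected, atol=1e-9)

    def test_double_well_recovery_rmse(self):
        windows, potential = double_well_windows(seed=11)
        edges = np.arange(-7.0, 7.25, 0.25)
        prof = wham(windows, edges)
        ana = analytic_profile_1d(potential, edges)
        ok = prof.defined()
        rmse = np.sqrt(np.mean((prof.free_energy[ok] - ana[ok]) ** 2))
        assert rmse <= 0.15

    def test_two_windows_same_basin_agree_after_unbiasing(self):
        rng = np.random.default_rng(1)
        harmonic = lambda x: 0.05 * np.asarray(x) ** 2
        edges = np.linspace(-6, 6, 31)
        profs = []
        for c in (-1.0, 1.0):
            s = sample_biased_1d(harmonic, 0.02, c, 100000, rng, (-10, 10))
            w = UmbrellaWindow(cv_names=("x",), k=0.02, center=c, samples=s)
            profs.append(wham([w], edges))
        a, b = profs
        both = a.defined() & b.defined()
        diff = a.free_energy[both] - b.free_energy[both]
        diff -= diff.mean()        # profiles agree up to a constant
        # compare where both are well determined
        good = both.copy()
        good[both] = (a.counts[both] > 200) & (b.counts[both] > 200)
        assert np.abs((a.free_energy - b.free_energy
                       - (a.free_energy - b.free_energy)[good].mean())[good]).max() < 0.2

    def test_bin_refinement_invariance(self):
        windows, potential = double_well_windows(seed=5, n_total=100000)
        coarse = wham(windows, np.arange(-6.0, 6.5, 0.5))
        fine = wham(windows, np.arange(-6.0, 6.25, 0.25))
        # average fine pairs back onto the coarse grid (in probability)
        pf = np.exp(-fine.free_energy)
        pc = pf[0::2] + pf[1::2]
        fc = -np.log(pc)
        fc -= np.nanmin(fc)
        ok = np.isfinite(fc) & coarse.defined()
        assert np.abs(fc[ok] - coarse.free_energy[ok]).max() < 0.1

    def test_nonoverlapping_windows_error(self):
        w1 = UmbrellaWindow(("x",), 1.0, -5.0,
                            np.random.default_rng(0).normal(-5, 0.1, 100))
        w2 = UmbrellaWindow(("x",), 1.0, 5.0,
                            np.random.default_rng(1).normal(5, 0.1, 100))
        with pytest.raises(ValueError, match="shares no"):
            wham([w1, w2], np.linspace(-6, 6, 61))


class TestWham2D:
    def test_separable_potential_recovery(self):
        windows, (ax, ay) = separable_2d_windows(seed=3)
        edges = np.arange(-10, 10.5, 1.0)
        prof = wham2d(windows, (edges, edges))
        xc = prof.bin_centers[0]
        beta = 1.0 / KT
        ana = beta * (ax * xc[:, None] ** 2 + ay * xc[None, :] ** 2)
        ana -= ana.min()
        ok = prof.counts > 200
        rmse = np.sqrt(np.mean((prof.free_energy - ana)[ok] ** 2))
        assert rmse <= 0.15

    def test_marginal_matches_1d_wham(self):
        windows, _ = separable_2d_windows(seed=4)
        edges = np.arange(-10, 10.5, 1.0)
        p2 = wham2d(windows, (edges, edges))
        p_x = np.nansum(np.where(np.isfinite(p2.free_energy),
                                 np.exp(-p2.free_energy), 0.0), axis=1)
        f_marg = -np.log(p_x)
        f_marg -= f_marg.min()
        w1d = [UmbrellaWindow(("x",), w.k[0], w.center[0], w.samples[:, 0])
               for w in windows]
        p1 = wham(w1d, edges)
        ok = np.isfinite(f_marg) & p1.defined()
        assert np.abs(f_marg[ok] - p1.free_energy[ok]).max() < 0.1

    def test_unvisited_corners_flagged_undefined(self):
        windows, _ = separable_2d_windows(seed=5, n_windows=3, n_per=500)
        edges = np.arange(-30, 31, 2.0)
        prof = wham2d(windows, (edges, edges))
        assert np.isnan(prof.free_energy[0, 0])
        assert np.isnan(prof.free_energy[-1, -1])
        assert prof.counts[0, 0] == 0


class TestReweighting:
    def test_constant_observable_has_expectation_one(self):
        windows, _ = double_well_windows(seed=7, n_total=20000)
        obs = [np.ones(w.samples.shape[0]) for w in windows]
        mean, err = reweight_observable(windows, obs, np.arange(-7, 7.25, 0.25))
        assert mean == pytest.approx(1.0, abs=1e-12)

    def test_zero_bias_single_window_is_plain_mean(self):
        rng = np.random.default_rng(2)
        samples = rng.normal(0, 1, 20000)
        w = UmbrellaWindow(("x",), 0.0, 0.0, samples)
        obs = samples ** 2
        mean, _ = reweight_observable([w], [obs], np.linspace(-4, 4, 41))
        assert mean == pytest.approx(obs.mean(), rel=1e-9)

    def test_linear_observable_matches_quadrature(self):
        windows, potential = double_well_windows(seed=9)
        obs = [w.samples[:, 0] + 2.0 for w in windows]
        mean, err = reweight_observable(windows, obs, np.arange(-7, 7.25, 0.25))
        x = np.linspace(-7.5, 7.5, 4001)
        boltz = np.exp(-potential(x) / KT)
        expected = np.trapezoid((x + 2.0) * boltz, x) / np.trapezoid(boltz, x)
        # within 1% of the observable's sampled range (~15 units)
        assert abs(mean - expected) <= 0.15

    def test_length_mismatch_rejected(self):
        windows, _ = double_well_windows(seed=1, n_total=12000)
        obs = [np.ones(3) for _ in windows]
        with pytest.raises(ValueError, match="length"):
            reweight_observable(windows, obs, np.arange(-7, 7.25, 0.25))


class TestIndependentError:
    def make_profile(self, values):
        f = np.asarray(values, float)
        return FreeEnergyProfile(bin_centers=(np.arange(len(f), dtype=float),),
                                 free_energy=f - f.min(),
                                 counts=np.ones(len(f)))

    def test_identical_profiles_have_zero_error(self):
        p = self.make_profile([0.0, 1.0, 2.0])
        assert np.all(independent_error([p, p, p]) == 0.0)

    def test_known_offsets_give_hand_computed_std(self):
        ps = [self.make_profile([0.0, 1.0 + d, 2.0]) for d in (-0.3, 0.0, 0.3)]
        err = independent_error(ps)
        assert err[1] == pytest.approx(np.std([0.7, 1.0, 1.3]))
        assert err[0] == err[2] == 0.0

    def test_error_invariant_to_common_shift_after_normalization(self):
        base = np.array([0.0, 0.8, 1.6, 0.4])
        ps = [self.make_profile(base + c) for c in (0.0, 5.0, -2.0)]
        assert np.all(independent_error(ps) < 1e-12)

    def test_grid_mismatch_rejected(self):
        a = self.make_profile([0.0, 1.0])
        b = self.make_profile([0.0, 1.0, 2.0])
        with pytest.raises(ValueError, match="grid"):
            independent_error([a, b])


def test_binding_free_energy_normalization_invariant():
    x = np.linspace(0, 100, 51)
    f = np.where(x < 30, 0.0, 4.0) + 0.01 * x
    prof = FreeEnergyProfile(bin_centers=(x,), free_energy=f - f.min(),
                             counts=np.ones_like(x))
    df1 = binding_free_energy(prof, (80, 100))
    prof.free_energy = prof.free_energy + 3.0   # unnormalized copy
    df2 = binding_free_energy(prof, (80, 100))
    assert df1 == pytest.approx(df2)
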