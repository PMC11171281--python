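"""Window grids, WHAM self-consistency, and toy-potential recovery."""

import numpy as np
import pytest

from emlekit import (
    FESGrid,
    UmbrellaWindow,
    WhamError,
    fes_rmse,
    make_window_grid,
    wham_2d,
)
from emlekit.umbrella_wham import KB_KCALMOL, wrap_angle
from emlekit.fixtures import sample_umbrella_windows, toy_fes_potential


class TestWindowGrid:
    def test_full_production_grid_has_1296_windows(self):
        centers = make_window_grid(36, 10.0)
        assert len(centers) == 1296

    def test_small_grid(self):
        assert len(make_window_grid(4, 90.0)) == 16

    def test_incomplete_cover_rejected(self):
        with pytest.raises(WhamError, match="cover"):
            make_window_grid(36, 5.0)

    def test_centers_cover_torus_uniquely(self):
        centers = np.array(make_window_grid(6, 60.0))
        assert len(np.unique(centers, axis=0)) == 36
        assert centers.min() == -180.0
        assert centers.max() == 120.0


class TestBias:
    def test_bias_is_minimal_image_periodic(self):
        w = UmbrellaWindow((170.0, 0.0), k=100.0)
        # -175 deg is 15 deg away from +170 through the boundary
        near = w.bias(-175.0, 0.0)
        far = w.bias(125.0, 0.0)  # 45 degrees away
        assert near < far
        d = np.deg2rad(15.0)
        assert near == pytest.approx(0.5 * 100.0 * d**2, rel=1e-12)

    def test_wrap_angle_range(self):
        x = wrap_angle(np.array([-180.0, 180.0, 359.0, -541.0]))
        assert np.all((x >= -180.0) & (x < 180.0))


class TestWham:
    def test_unbiased_uniform_samples_give_flat_fes(self):
        rng = np.random.default_rng(81)
        samples = rng.uniform(-180.0, 180.0, (40000, 2))
        w = UmbrellaWindow((0.0, 0.0), k=0.0, samples=samples)
        fes = wham_2d([w], bins=6, temperature=300.0)
        # statistical noise for ~1100 counts/bin is ~kT/sqrt(n) ~ 0.02
        assert np.nanmax(fes.free_energy) < 0.1

    def test_two_identical_windows_match_pooled_window(self):
        rng = np.random.default_rng(82)
        a = rng.normal(0.0, 25.0, (3000, 2))
        b = rng.normal(0.0, 25.0, (3000, 2))
        k = 5.0
        split = [
            UmbrellaWindow((0.0, 0.0), k, a),
            UmbrellaWindow((0.0, 0.0), k, b),
        ]
        pooled = [UmbrellaWindow((0.0, 0.0), k, np.vstack([a, b]))]
        f1 = wham_2d(split, bins=12)
        f2 = wham_2d(pooled, bins=12)
        m = f1.populated & f2.populated
        assert np.abs(f1.free_energy[m] - f2.free_energy[m]).max() < 1e-9

    def test_empty_window_rejected(self):
        w = UmbrellaWindow((0.0, 0.0), k=10.0)
        with pytest.raises(WhamError, match="empty"):
            wham_2d([w])

    def test_unpopulated_bins_are_nan_and_minimum_zero(self):
        samples = np.full((500, 2), 10.0) + np.random.default_rng(83).normal(
            0, 5.0, (500, 2)
        )
        w = UmbrellaWindow((10.0, 10.0), k=50.0, samples=samples)
        fes = wham_2d([w], bins=36)
        assert np.any(np.isnan(fes.free_energy))
        assert np.nanmin(fes.free_energy) == pytest.approx(0.0, abs=1e-12)

    def test_window_reordering_invariance(self):
        centers = make_window_grid(4, 90.0)
        samples = sample_umbrella_windows(
            centers, k=8.0, n_samples=300, seed=84
        )
        windows = [
            UmbrellaWindow(c, 8.0, s) for c, s in zip(centers, samples)
        ]
        f1 = wham_2d(windows, bins=12, tol=1e-11)
        f2 = wham_2d(windows[::-1], bins=12, tol=1e-11)
        m = f1.populated
        assert np.abs(f1.free_energy[m] - f2.free_energy[m]).max() < 1e-8

    def test_global_angle_shift_invariance(self):
        """Shifting all samples and centers by a bin-aligned offset rolls
        the surface without changing it."""
        centers = make_window_grid(4, 90.0)
        samples = sample_umbrella_windows(
            centers, k=8.0, n_samples=400, seed=85
        )
        windows = [
            UmbrellaWindow(c, 8.0, s) for c, s in zip(centers, samples)
        ]
        bins = 12
        shift = 90.0  # three 30-degree bins
        shifted = [
            UmbrellaWindow(
                (wrap_angle(c[0] + shift), c[1]), 8.0,
                np.column_stack([wrap_angle(s[:, 0] + shift), s[:, 1]]),
            )
            for c, s in zip(centers, samples)
        ]
        f1 = wham_2d(windows, bins=bins)
        f2 = wham_2d(shifted, bins=bins)
        rolled = np.roll(f1.free_energy, 3, axis=0)
        m = ~np.isnan(rolled) & f2.populated
        assert np.abs(f2.free_energy[m] - rolled[m]).max() < 1e-8


class TestToyRecovery:
    def _reference_grid(self, bins):
        edges = np.linspace(-180.0, 180.0, bins + 1)
        c = 0.5 * (edges[:-1] + edges[1:])
        phi, psi = np.meshgrid(c, c, indexing="ij")
        ref = toy_fes_potential(phi, psi)
        ref -= ref.min()
        return FESGrid(edges, edges.copy(), ref, np.ones_like(ref))

    def test_umbrella_wham_recovers_toy_surface(self):
        """Reduced 12x12 grid, fixed seed: offset-aligned RMSE against the
        analytic surface stays within 3x the analytic sampling error."""
        centers = make_window_grid(12, 30.0)
        k = 15.0
        n_samples = 800
        temperature = 300.0
        samples = sample_umbrella_windows(
            centers, k=k, n_samples=n_samples, seed=86,
            temperature=temperature,
        )
        windows = [
            UmbrellaWindow(c, k, s) for c, s in zip(centers, samples)
        ]
        bins = 24
        fes = wham_2d(windows, bins=bins, temperature=temperature)
        ref = self._reference_grid(bins)
        rmse = fes_rmse(fes, ref, cutoff=20.0)
        err = analytic_sampling_error(
            centers, k, n_samples, bins, temperature
        )
        assert rmse < 3.0 * err

    def test_more_sampling_reduces_error(self):
        """Error decreases with samples per window (averaged over seeds)."""
        centers = make_window_grid(6, 60.0)
        k = 10.0
        bins = 12
        ref = self._reference_grid(bins)

        def mean_rmse(n_samples):
            vals = []
            for seed in (1, 2, 3):
                samples = sample_umbrella_windows(
                    centers, k=k, n_samples=n_samples, seed=seed
                )
                windows = [
                    UmbrellaWindow(c, k, s)
                    for c, s in zip(centers, samples)
                ]
                fes = wham_2d(windows, bins=bins)
                vals.append(fes_rmse(fes, ref, cutoff=20.0))
            return np.mean(vals)

        assert mean_rmse(1200) < mean_rmse(120)


def analytic_sampling_error(
    centers, k, n_samples, bins, temperature=300.0
):
    """Expected RMS statistical error (kcal/mol) of the WHAM estimate of
    the toy surface, computed analytically from the known potential.

    For each bin the expected total (bias-reweighted) count over all
    windows is integrated from the exact biased Boltzmann densities; the
    free-energy variance per bin is (kT)²/n_eff for n_eff independent
    samples.  The sampler thins its chains, so samples are treated as
    independent.
    """
    kT = KB_KCALMOL * temperature
    edges = np.linspace(-180.0, 180.0, bins + 1)
    c = 0.5 * (edges[:-1] + edges[1:])
    phi, psi = np.meshgrid(c, c, indexing="ij")
    v = toy_fes_potential(phi, psi)
    centers = np.asarray(centers, float).reshape(-1, 2)
    n_eff = np.zeros_like(v)
    for phi0, psi0 in centers:
        dphi = np.deg2rad(wrap_angle(phi - phi0))
        dpsi = np.deg2rad(wrap_angle(psi - psi0))
        bias = 0.5 * k * (dphi**2 + dpsi**2)
        p = np.exp(-(v + bias) / kT)
        p /= p.sum()
        n_eff += n_samples * p
    var = kT**2 / np.maximum(n_eff, 1e-12)
    return float(np.sqrt(var.mean()))


class TestFesRmse:
    def _grid(self, values):
        bins = values.shape[0]
        edges = np.linspace(-180.0, 180.0, bins + 1)
        return FESGrid(edges, edges.copy(), values, np.ones_like(values))

    def test_identical_grids_give_zero(self):
        v = np.random.default_rng(87).uniform(0, 5, (6, 6))
        assert fes_rmse(self._grid(v), self._grid(v)) == 0.0

    def test_constant_offset_aligned_away(self):
        v = np.random.default_rng(88).uniform(0, 5, (6, 6))
        assert fes_rmse(self._grid(v + 2.5), self._grid(v)) == pytest.approx(
            0.0, abs=1e-12
        )
        assert fes_rmse(
            self._grid(v + 2.5), self._grid(v), align_offset=False
        ) == pytest.approx(2.5, rel=1e-12)

    def test_hand_computed_toy_grids(self):
        a = self._grid(np.array([[0.0, 1.0], [2.0, 3.0]]))
        b = self._grid(np.array([[0.0, 2.0], [2.0, 2.0]]))
        # diffs: 0, -1, 0, 1; mean 0; rmse = sqrt(2/4)
        assert fes_rmse(a, b) == pytest.approx(np.sqrt(0.5), rel=1e-12)

    def test_cutoff_excludes_reference_bins(self):
        a = np.array([[0.0, 1.0], [2.0, 3.0]])
        b = np.array([[0.0, 1.0], [2.0, 30.0]])
        # the 30 kcal/mol reference bin is ignored entirely
        assert fes_rmse(self._grid(a), self._grid(b), cutoff=20.0) == 0.0

    def test_mismatched_binning_rejected(self):
        a = self._grid(np.zeros((4, 4)))
        b = self._grid(np.zeros((6, 6)))
        with pytest.raises(WhamError, match="binning"):
            fes_rmse(a, b)

    def test_no_common_bins_rejected(self):
        a = self._grid(np.full((2, 2), np.nan))
        b = self._grid(np.zeros((2, 2)))
        with pytest.raises(WhamError, match="common"):
            fes_rmse(a, b)
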