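"""Kernel generation, convolution dosimetry, dose maps and DVHs."""

import numpy as np
import pytest

from hoct import dosimetry as dos
from hoct.nuclide import DECAY_CONSTANT_PER_S, HALF_LIFE_S
from hoct.volumes import VOIMask, VoxelGrid


def small_kernel_grid(n=21, spacing=1.0):
    return VoxelGrid((spacing,) * 3,
                     (-(n // 2) * spacing,) * 3, (n, n, n))


@pytest.fixture(scope="module")
def small_kernel():
    """A coarse ¹⁶⁶Ho kernel adequate for convolution-chain tests."""
    return dos.generate_dpk(dos.ho166_spectrum(), small_kernel_grid(21, 1.0),
                            n_histories=20_000, seed=4)


class TestSpectrum:
    def test_negative_yield_rejected(self):
        with pytest.raises(ValueError):
            dos.EmissionSpectrum(beta_branches=((1.0, -0.1),))

    def test_cutoff_below_1kev_rejected(self):
        with pytest.raises(ValueError):
            dos.EmissionSpectrum(beta_branches=((1.0, 1.0),), cutoff_kev=0.5)

    def test_ho166_mean_energy_plausible(self):
        # two ~1.8 MeV branches with allowed-spectrum means near Q/3
        total = dos.ho166_spectrum().total_emitted_mev_per_decay()
        assert 0.6 < total < 0.9


class TestGenerateDPK:
    def test_zero_energy_spectrum_gives_zero_kernel(self):
        spec = dos.EmissionSpectrum(beta_branches=(), photon_lines=((0.0, 1.0),))
        k = dos.generate_dpk(spec, small_kernel_grid(5), n_histories=100, seed=0)
        assert k.total_energy_ev == 0.0

    def test_energy_conservation_bound(self, small_kernel):
        emitted_ev = dos.ho166_spectrum().total_emitted_mev_per_decay() * 1e6
        assert 0.0 < small_kernel.total_energy_ev <= emitted_ev
        # grid extends past the beta range; only photon escape is lost
        assert small_kernel.total_energy_ev > 0.97 * emitted_ev

    def test_determinism(self):
        spec = dos.ho166_spectrum()
        g = small_kernel_grid(7)
        k1 = dos.generate_dpk(spec, g, n_histories=2000, seed=11)
        k2 = dos.generate_dpk(spec, g, n_histories=2000, seed=11)
        np.testing.assert_array_equal(k1.energy_ev, k2.energy_ev)
        k3 = dos.generate_dpk(spec, g, n_histories=2000, seed=12)
        assert not np.array_equal(k1.energy_ev, k3.energy_ev)

    def test_even_grid_rejected(self):
        g = VoxelGrid((1.0, 1.0, 1.0), (0, 0, 0), (10, 11, 11))
        with pytest.raises(ValueError, match="odd"):
            dos.generate_dpk(dos.ho166_spectrum(), g, n_histories=10, seed=0)

    def test_point_symmetry_within_mc_tolerance(self, small_kernel):
        e = small_kernel.energy_ev
        flipped = e[::-1, ::-1, ::-1]
        # symmetric transport: mirrored kernel agrees within MC noise
        scale = e.max()
        assert np.abs(e - flipped).max() / scale < 0.2

    def test_radial_fraction_at_3mm(self, small_kernel):
        assert dos.kernel_radial_fraction(small_kernel, 3.0) >= 0.90


class TestKernelRadialFraction:
    def test_radius_covering_grid_gives_one(self, small_kernel):
        assert dos.kernel_radial_fraction(small_kernel, 1000.0) == pytest.approx(1.0)

    def test_radius_zero_is_center_fraction(self, small_kernel):
        frac = dos.kernel_radial_fraction(small_kernel, 0.0)
        center = small_kernel.energy_ev[small_kernel.center_index]
        assert frac == pytest.approx(center / small_kernel.total_energy_ev)

    def test_monotone_in_radius(self, small_kernel):
        fracs = [dos.kernel_radial_fraction(small_kernel, r) for r in (0, 1, 2, 4, 8)]
        assert all(a <= b + 1e-12 for a, b in zip(fracs, fracs[1:]))


class TestKernelIO:
    def test_save_load_round_trip(self, tmp_path, small_kernel):
        dos.save_dpk(small_kernel, tmp_path / "kern")
        back = dos.load_dpk(tmp_path / "kern")
        np.testing.assert_array_equal(back.energy_ev, small_kernel.energy_ev)
        assert back.grid == small_kernel.grid
        assert back.medium_density == small_kernel.medium_density
        assert back.provenance == small_kernel.provenance

    def test_missing_density_rejected(self, tmp_path, small_kernel):
        import json

        dos.save_dpk(small_kernel, tmp_path / "kern")
        sidecar = tmp_path / "kern.json"
        meta = json.loads(sidecar.read_text())
        del meta["medium_density_kg_per_l"]
        sidecar.write_text(json.dumps(meta))
        with pytest.raises(ValueError, match="density"):
            dos.load_dpk(tmp_path / "kern")

    def test_resampled_external_kernel_conserves_energy(self, small_kernel):
        from hoct.volumes import resample_trilinear

        tgt = VoxelGrid((0.5, 0.5, 1.0), (-10.0, -10.0, -10.0), (41, 41, 21))
        out = resample_trilinear(small_kernel.energy_ev, small_kernel.grid, tgt,
                                 conserve_total=True)
        assert out.sum() == pytest.approx(small_kernel.total_energy_ev, rel=1e-12)


class TestMatchToKernelGrid:
    def test_identity_when_resolution_matches(self, small_kernel):
        g = VoxelGrid(small_kernel.grid.spacing_mm, (0, 0, 0), (9, 9, 9))
        act = np.random.default_rng(0).uniform(0, 10, g.shape)
        out, og = dos.match_to_kernel_grid(act, g, small_kernel)
        assert og is g
        np.testing.assert_array_equal(out, act)

    def test_total_bq_preserved_on_refinement(self, small_kernel):
        g = VoxelGrid((2.0, 2.0, 2.0), (0, 0, 0), (9, 9, 9))
        act = np.zeros(g.shape)
        act[4, 4, 4] = 1234.5
        out, og = dos.match_to_kernel_grid(act, g, small_kernel)
        assert og.spacing_mm == small_kernel.grid.spacing_mm
        assert out.sum() == pytest.approx(1234.5, rel=1e-12)

    def test_uniform_activity_stays_uniform_in_interior(self, small_kernel):
        g = VoxelGrid((2.0, 2.0, 2.0), (0, 0, 0), (11, 11, 11))
        act = np.full(g.shape, 5.0)
        out, og = dos.match_to_kernel_grid(act, g, small_kernel)
        interior = out[4:-4, 4:-4, 4:-4]
        assert np.allclose(interior, interior.flat[0], rtol=1e-9)


def _direct_convolution(act, kernel):
    """Brute-force shifted-kernel summation oracle."""
    out = np.zeros_like(act)
    kc = kernel.center_index
    ke = kernel.energy_ev
    for idx in zip(*np.nonzero(act)):
        a = act[idx]
        for off in np.ndindex(ke.shape):
            tgt = tuple(idx[d] + off[d] - kc[d] for d in range(3))
            if all(0 <= tgt[d] < act.shape[d] for d in range(3)):
                out[tgt] += a * ke[off]
    return out


class TestConvolution:
    def test_delta_function_returns_kernel(self, small_kernel):
        g = small_kernel.grid
        act = np.zeros(g.shape)
        act[small_kernel.center_index] = 1.0
        rate = dos.convolve_dose_rate(act, g, small_kernel)
        np.testing.assert_allclose(rate, small_kernel.energy_ev,
                                   atol=1e-9 * small_kernel.energy_ev.max())

    def test_superposition_matches_direct_sum(self, small_kernel):
        g = VoxelGrid(small_kernel.grid.spacing_mm, (0, 0, 0), (21, 21, 21))
        act = np.zeros(g.shape)
        act[6, 10, 10] = 2.0
        act[14, 9, 11] = 5.0
        rate = dos.convolve_dose_rate(act, g, small_kernel)
        brute = _direct_convolution(act, small_kernel)
        np.testing.assert_allclose(rate, brute, rtol=1e-9,
                                   atol=1e-9 * brute.max())

    def test_energy_conservation_away_from_edges(self):
        kernel = dos.generate_dpk(dos.ho166_spectrum(), small_kernel_grid(11, 1.0),
                                  n_histories=5000, seed=8)
        g = VoxelGrid((1.0, 1.0, 1.0), (0, 0, 0), (31, 31, 31))
        act = np.zeros(g.shape)
        act[15, 15, 15] = 3.0  # ≥ kernel half-width from every edge
        rate = dos.convolve_dose_rate(act, g, kernel)
        assert rate.sum() == pytest.approx(3.0 * kernel.total_energy_ev, rel=1e-9)

    def test_negative_activity_refused(self, small_kernel):
        g = small_kernel.grid
        act = np.zeros(g.shape)
        act[0, 0, 0] = -1.0
        with pytest.raises(ValueError, match="negative"):
            dos.convolve_dose_rate(act, g, small_kernel)

    def test_resolution_mismatch_instructs_resampling(self, small_kernel):
        g = VoxelGrid((2.0, 2.0, 2.0), (0, 0, 0), (5, 5, 5))
        with pytest.raises(ValueError, match="match_to_kernel_grid"):
            dos.convolve_dose_rate(np.ones(g.shape), g, small_kernel)


class TestCumulativeDose:
    def test_zero_rate_zero_dose(self, small_grid):
        dm = dos.cumulative_dose_map(np.zeros(small_grid.shape), small_grid)
        assert np.all(dm.dose_gy == 0.0)

    def test_unit_rate_arithmetic(self):
        # E = 1 eV/s, λ = 7.18e-6 s⁻¹, ρ = 1.06 kg/L, V = 0.25e-6 L
        g = VoxelGrid((0.5, 0.5, 1.0), (0, 0, 0), (1, 1, 1))
        dm = dos.cumulative_dose_map(np.ones(g.shape), g, density=1.06,
                                     decay_constant=7.18e-6)
        expected = (1.0 / 7.18e-6) * 1.602176634e-19 / (1.06 * 0.25e-6)
        assert dm.dose_gy[0, 0, 0] == pytest.approx(expected, rel=1e-12)

    def test_linearity_in_activity(self, small_grid):
        rng = np.random.default_rng(1)
        rate = rng.uniform(0, 10, small_grid.shape)
        d1 = dos.cumulative_dose_map(rate, small_grid).dose_gy
        d2 = dos.cumulative_dose_map(2 * rate, small_grid).dose_gy
        np.testing.assert_allclose(d2, 2 * d1, rtol=1e-12)

    def test_partial_time_dose_fraction(self, small_grid):
        rate = np.ones(small_grid.shape)
        full = dos.cumulative_dose_map(rate, small_grid).dose_gy
        half = dos.cumulative_dose_map(rate, small_grid, elapsed_s=HALF_LIFE_S).dose_gy
        np.testing.assert_allclose(half, 0.5 * full, rtol=1e-9)

    def test_uniform_field_closed_form(self):
        # interior voxel dose of a large uniform activity field approaches
        # (A_voxel/λ) · E_kernel · 1.602e−19 / (ρ·V_voxel)
        kernel = dos.generate_dpk(dos.ho166_spectrum(), small_kernel_grid(15, 1.0),
                                  n_histories=5000, seed=3)
        g = VoxelGrid((1.0, 1.0, 1.0), (0, 0, 0), (41, 41, 41))
        a = 7.0
        act = np.full(g.shape, a)
        rate = dos.convolve_dose_rate(act, g, kernel)
        dm = dos.cumulative_dose_map(rate, g, density=1.06)
        v_l = g.voxel_volume_mm3 * 1e-6
        expected = (a / DECAY_CONSTANT_PER_S) * kernel.total_energy_ev \
            * 1.602176634e-19 / (1.06 * v_l)
        assert dm.dose_gy[20, 20, 20] == pytest.approx(expected, rel=0.01)


class TestDVH:
    def _uniform_dose(self, value=2.0):
        g = VoxelGrid((1.0, 1.0, 1.0), (0, 0, 0), (6, 6, 6))
        return dos.DoseMap(np.full(g.shape, value), g, 1.06), g

    def test_uniform_dose_step_function(self):
        dm, g = self._uniform_dose(2.0)
        curve = dos.dvh(dm, VOIMask(g, np.ones(g.shape, bool)), n_bins=50)
        assert np.all(curve.volume_percent == 100.0)
        assert curve.dose_gy[-1] == pytest.approx(2.0)

    def test_half_high_half_zero(self):
        g = VoxelGrid((1.0, 1.0, 1.0), (0, 0, 0), (6, 6, 6))
        d = np.zeros(g.shape)
        d[:3] = 4.0
        dm = dos.DoseMap(d, g, 1.06)
        curve = dos.dvh(dm, VOIMask(g, np.ones(g.shape, bool)), n_bins=100)
        inside = (curve.dose_gy > 0) & (curve.dose_gy <= 4.0)
        assert np.allclose(curve.volume_percent[inside], 50.0)
        assert curve.volume_percent[0] == 100.0

    def test_monotone_non_increasing_random(self):
        rng = np.random.default_rng(17)
        g = VoxelGrid((1.0, 1.0, 1.0), (0, 0, 0), (8, 8, 8))
        dm = dos.DoseMap(rng.gamma(2.0, 3.0, g.shape), g, 1.06)
        curve = dos.dvh(dm, VOIMask(g, np.ones(g.shape, bool)), n_bins=64)
        assert np.all(np.diff(curve.volume_percent) <= 1e-12)

    def test_integrates_to_mean_dose(self):
        rng = np.random.default_rng(23)
        g = VoxelGrid((1.0, 1.0, 1.0), (0, 0, 0), (10, 10, 10))
        vals = rng.gamma(2.0, 5.0, g.shape)
        dm = dos.DoseMap(vals, g, 1.06)
        curve = dos.dvh(dm, VOIMask(g, np.ones(g.shape, bool)), n_bins=2000)
        assert dos.dvh_mean_dose(curve) == pytest.approx(vals.mean(), rel=5e-3)

    def test_empty_mask_rejected(self):
        dm, g = self._uniform_dose()
        with pytest.raises(ValueError):
            dos.dvh(dm, VOIMask(g, np.zeros(g.shape, bool)), n_bins=10)
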