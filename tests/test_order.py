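import cmath

import numpy as np
import pytest

from premelt.configuration import PointConfiguration2D, minimum_image
from premelt.constants import KERNEL_MASS
from premelt.order import (area_per_lipid, bulk_levels, coarse_grain,
                           compute_phi, estimate_xi, hydrophobic_thickness,
                           number_density_field, phi_from_angles,
                           radial_profile)
from premelt.synth import (gen_bilayer3d, gen_disordered, gen_hexagonal,
                           gen_inclusion)


class TestPhi:
    def test_perfect_lattice_is_one(self, hex_perfect):
        ov = compute_phi(hex_perfect)
        assert np.allclose(ov.phi, 1.0, atol=1e-12)
        assert ov.neighbors.shape == (hex_perfect.n, 6)
        for i in range(0, hex_perfect.n, 97):
            row = ov.neighbors[i]
            assert len(set(row)) == 6 and i not in row

    @pytest.mark.parametrize("alpha", [0.0, 0.3, 1.2, np.pi / 5])
    def test_rotated_hexagonal_star_is_one(self, alpha):
        ang = np.deg2rad([0, 60, 120, 180, 240, 300]) + alpha
        pts = np.concatenate([[[5.0, 5.0]],
                              5.0 + np.column_stack([np.cos(ang),
                                                     np.sin(ang)])])
        cfg = PointConfiguration2D(pts, (10, 10), periodic=(False, False))
        ov = compute_phi(cfg)
        assert ov.phi[0] == pytest.approx(1.0, abs=1e-12)

    def test_seven_point_fixture_against_direct_sum(self):
        # independent oracle: direct evaluation of |(1/6) sum e^{6 i theta}|^2
        deg = [0, 55, 120, 175, 240, 300]
        expected = abs(sum(cmath.exp(6j * cmath.pi * d / 180)
                           for d in deg) / 6) ** 2
        ang = np.deg2rad(deg)
        pts = np.concatenate([[[5.0, 5.0]],
                              5.0 + np.column_stack([np.cos(ang),
                                                     np.sin(ang)])])
        cfg = PointConfiguration2D(pts, (10, 10), periodic=(False, False))
        ov = compute_phi(cfg)
        assert ov.phi[0] == pytest.approx(expected, abs=1e-12)

    def test_against_brute_force_neighbors(self, rng):
        """compute_phi agrees with an O(N^2) minimum-image brute force."""
        pts = rng.random((40, 2)) * 8.0
        cfg = PointConfiguration2D(pts, (8.0, 8.0))
        ov = compute_phi(cfg)
        for l in range(cfg.n):
            d = minimum_image(cfg.positions - cfg.positions[l], cfg.box)
            r = np.hypot(d[:, 0], d[:, 1])
            r[l] = np.inf
            nn = np.argsort(r, kind="stable")[:6]
            theta = np.arctan2(d[nn, 1], d[nn, 0])
            expected = abs(np.exp(6j * theta).mean()) ** 2
            assert ov.phi[l] == pytest.approx(expected, abs=1e-10)
            assert set(ov.neighbors[l]) == set(nn)

    def test_uniform_random_angles_mean_is_one_sixth(self, rng):
        theta = rng.uniform(0, 2 * np.pi, size=(200_000, 6))
        phi = phi_from_angles(theta)
        se = phi.std(ddof=1) / np.sqrt(phi.size)
        assert abs(phi.mean() - 1 / 6) < 3 * se

    def test_too_few_particles(self):
        cfg = PointConfiguration2D([[0, 0], [1, 1], [2, 2]], (10, 10))
        with pytest.raises(ValueError):
            compute_phi(cfg)


class TestEstimateXi:
    def test_exponential_correlation_oracle(self):
        """xi recovers lambda_c * ln(10) for a field with an imposed
        exponential spatial correlation."""
        lam = 0.8
        cfg = gen_hexagonal(0.52, 0.02, (18, 18), seed=1)
        n = cfg.n
        d = np.linalg.norm(minimum_image(
            cfg.positions[:, None, :] - cfg.positions[None, :, :],
            cfg.box), axis=-1)
        cov = np.exp(-d / lam) + 1e-9 * np.eye(n)
        L = np.linalg.cholesky(cov)
        rng = np.random.default_rng(100)
        phi = 0.8 + 0.05 * (L @ rng.standard_normal((n, 25))).T
        est = estimate_xi(cfg, phi, bin_width=0.2)
        expected = lam * np.log(10)
        assert abs(est / expected - 1) < 0.15

    def test_iid_phi_returns_first_shell_with_warning(self, rng):
        cfg = gen_hexagonal(0.52, 0.0, (12, 12), seed=2)
        phi = rng.random(cfg.n)
        with pytest.warns(UserWarning, match="below threshold"):
            est = estimate_xi(cfg, phi, bin_width=0.2)
        assert est < 0.8

    def test_never_crossing_errors(self):
        cfg = gen_hexagonal(0.52, 0.0, (10, 10), seed=3)
        phi = cfg.positions[:, 0] / cfg.box[0]  # long-ranged gradient
        with pytest.raises(ValueError, match="larger box"):
            estimate_xi(cfg, phi, bin_width=0.2, r_max=2.0)


class TestCoarseGrain:
    def test_single_particle_peak_value(self):
        cfg = PointConfiguration2D([[10.0, 10.0]], (20, 20))
        f = coarse_grain(cfg, np.ones(1), 1.5, 0.25)
        peak = 1 / (2 * np.pi * 1.5 ** 2) * (1 - np.exp(-4.5))
        assert peak == pytest.approx(0.06995, abs=5e-6)
        assert f.interpolate([[10.0, 10.0]])[0] == pytest.approx(peak,
                                                                 rel=1e-12)

    def test_zero_beyond_cutoff(self):
        cfg = PointConfiguration2D([[10.0, 10.0]], (40, 40))
        f = coarse_grain(cfg, np.ones(1), 1.5, 0.25)
        ax, ay = f.grid_axes()
        gx, gy = np.meshgrid(ax, ay, indexing="ij")
        rel = minimum_image(np.stack([gx - 10, gy - 10], -1), f.box)
        far = np.hypot(rel[..., 0], rel[..., 1]) > 4.5
        assert np.all(f.values[far] == 0.0)

    def test_kernel_mass(self):
        cfg = gen_disordered(3.0, 0.3, (20, 20), seed=4)
        f = number_density_field(cfg)
        assert abs(f.integral() - KERNEL_MASS * cfg.n) < 1e-3 * cfg.n
        f2 = number_density_field(cfg, renormalize=True)
        assert abs(f2.integral() - cfg.n) < 1e-3 * cfg.n

    def test_linearity_in_weights(self, rng):
        cfg = gen_disordered(2.0, 0.3, (12, 12), seed=5)
        w1 = rng.random(cfg.n)
        w2 = rng.random(cfg.n)
        f1 = coarse_grain(cfg, w1, 1.5, 0.375)
        f2 = coarse_grain(cfg, w2, 1.5, 0.375)
        f12 = coarse_grain(cfg, w1 + w2, 1.5, 0.375)
        assert np.allclose(f12.values, f1.values + f2.values, rtol=1e-10)

    def test_undersampled_grid_rejected(self):
        cfg = PointConfiguration2D([[1, 1]], (10, 10))
        with pytest.raises(ValueError, match="undersample"):
            coarse_grain(cfg, np.ones(1), 1.0, 0.8)

    def test_bulk_levels_match_gridded_mean(self):
        cfg = gen_hexagonal(0.52, 0.03, (12, 12), seed=6)
        phi = compute_phi(cfg).phi
        level_phi, level_rho = bulk_levels(cfg, phi)
        f = coarse_grain(cfg, phi, 1.5, 0.25)
        assert f.values.mean() == pytest.approx(level_phi, rel=1e-3)


class TestRadialProfile:
    def test_constant_phi_gives_constant_ratio(self):
        cfg = gen_disordered(3.0, 0.3, (20, 20), seed=7)
        c = 0.37
        prof = radial_profile(cfg, (10, 10), bin_width=0.5,
                              phi_values=[np.full(cfg.n, c)])
        good = prof.counts > 0
        assert np.allclose(prof.ratio[good], c, rtol=1e-10)
        assert np.allclose(prof.particle_phi[good & (prof.particle_counts > 0)],
                           c)

    def test_inclusion_profile_is_sigmoidal(self):
        frames = [gen_inclusion(R=1.5, R0=5.0, box=(26, 26), seed=s)
                  for s in (11, 12, 13)]
        center = frames[0].metadata["center"]
        prof = radial_profile(frames, center, bin_width=0.5, r_max=12.0)
        inner = prof.ratio[(prof.r > 2.5) & (prof.r < 4.0)].mean()
        outer = prof.ratio[prof.r > 9.0].mean()
        mid = prof.ratio[np.argmin(np.abs(prof.r - 5.0))]
        assert inner < 0.4
        assert outer > 0.7
        assert inner < mid < outer

    def test_homogeneous_sample_ratio_is_flat(self):
        cfg = gen_hexagonal(0.52, 0.03, (20, 20), seed=8)
        prof = radial_profile(cfg, (7.0, 9.0), bin_width=0.5)
        good = prof.counts > 0
        r = prof.ratio[good]
        assert r.std() / r.mean() < 0.02

    def test_overlong_rmax_rejected(self):
        cfg = gen_disordered(2.0, 0.3, (10, 10), seed=9)
        with pytest.raises(ValueError, match="min"):
            radial_profile(cfg, (5, 5), r_max=6.0)


class TestMembraneObservables:
    def test_thickness_translation_invariance(self):
        cfg = gen_bilayer3d(3.1, sigma_z=0.05, box=(8, 8), seed=1)
        shifted = gen_bilayer3d(3.1, sigma_z=0.05, box=(8, 8), seed=1)
        shifted.positions[:, 2] += 2.5
        assert hydrophobic_thickness(cfg) == pytest.approx(
            hydrophobic_thickness(shifted), abs=1e-12)

    def test_area_per_lipid_arithmetic(self):
        cfg = PointConfiguration2D(np.random.default_rng(0).random((64, 2))
                                   * 10, (10.0, 10.0))
        assert area_per_lipid(cfg) == pytest.approx(1.5625)
        half = PointConfiguration2D(cfg.positions[:32], cfg.box)
        assert area_per_lipid(half) == pytest.approx(2 * 1.5625)

    def test_ordered_phase_denser_than_disordered(self):
        ordered = gen_hexagonal(0.52, 0.02, (15, 15), seed=2)
        disordered = gen_disordered(3.3, 0.4, (15, 15), seed=3)
        assert area_per_lipid(ordered) < area_per_lipid(disordered)

    def test_area_per_lipid_3d_leaflet(self):
        cfg = gen_bilayer3d(3.1, box=(8, 8), seed=4)
        apl = area_per_lipid(cfg, leaflet="upper")
        n_upper = np.unique(cfg.lipid_ids[cfg.select(leaflet="upper")]).size
        assert apl == pytest.approx(cfg.box[0] * cfg.box[1] / n_upper)
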