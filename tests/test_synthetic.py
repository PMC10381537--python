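"""Synthetic generator: growth model, augmentation, rendering, noise, gaps."""

import numpy as np
import pytest

from rootrace.errors import InfeasibleSpecError, ValidationError
from rootrace.measures import compute_cnr
from rootrace.rsml import write_rsml
from rootrace.synthetic import (
    GapSpec,
    NoiseSpec,
    SyntheticSpec,
    add_soil_noise,
    augment_root_system,
    default_grid,
    generate_root_system,
    introduce_gaps,
    make_benchmark_case,
    voxelize_root_system,
)
from rootrace.volume import Volume3D

from conftest import sparse_spec, straight_tube_system


class TestGrowth:
    def test_deterministic_limit_is_straight_vertical(self):
        spec = sparse_spec(
            0,
            branch_spacing_mean_mm=np.inf,
            direction_persistence=1.0,
            gravitropism_weight=1.0,
            tap_length_range_mm=(40.0, 40.0),
            taper_per_mm=0.0,
        )
        rs = generate_root_system(spec)
        assert len(rs.roots) == 1
        p = rs.roots[0].positions()
        assert np.allclose(p[:, :2], 0.0)
        assert rs.total_length_mm() == pytest.approx(40.0)

    def test_same_seed_same_rsml_bytes(self, tmp_path):
        spec = sparse_spec(7, max_order=2)
        p1, p2 = tmp_path / "a.rsml", tmp_path / "b.rsml"
        write_rsml(generate_root_system(spec), p1)
        write_rsml(generate_root_system(spec), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_infeasible_container_rejected(self):
        with pytest.raises(InfeasibleSpecError):
            SyntheticSpec(container_height_mm=50.0, tap_length_range_mm=(80.0, 100.0)).validate()

    def test_lateral_count_follows_exponential_spacing(self):
        """Monte-Carlo: with pure exponential spacing (no refractory
        distance, no unbranched zones), the first-order lateral count is
        Poisson with mean L/s; the sample mean over 500 seeds must fall
        within 3 standard errors."""
        L, s, n = 100.0, 10.0, 500
        counts = []
        for seed in range(n):
            spec = sparse_spec(
                seed,
                container_height_mm=200.0,
                container_radius_mm=80.0,
                tap_length_range_mm=(L, L),
                branch_spacing_mean_mm=s,
                branch_spacing_min_mm=0.0,
                basal_zone_mm=0.0,
                apical_zone_mm=0.0,
                lateral_length_factor=(0.05, 0.08),
                direction_persistence=1.0,
                gravitropism_weight=1.0,
            )
            counts.append(generate_root_system(spec).counts_per_order().get(1, 0))
        mean = np.mean(counts)
        expected = L / s
        se = np.sqrt(expected / n)  # Poisson variance = mean
        assert abs(mean - expected) < 3 * se


class TestAugmentation:
    def test_twelve_variants(self, branched_system):
        assert len(augment_root_system(branched_system)) == 12

    def test_identity_member(self, branched_system):
        variants = augment_root_system(branched_system)
        ident = variants[6]  # scale 1 is third of four, rotation 0 first of three
        for a, b in zip(branched_system.roots, ident.roots):
            assert np.allclose(a.positions(), b.positions(), atol=1e-9)
            assert np.allclose(a.radii(), b.radii(), atol=1e-9)

    def test_length_invariant_radius_scaling_exact(self, branched_system):
        rl = branched_system.total_length_mm()
        scales = [1 / 3, 2 / 3, 1.0, 4 / 3]
        for i, v in enumerate(augment_root_system(branched_system)):
            assert v.total_length_mm() == pytest.approx(rl, rel=1e-12)
            expected_scale = scales[i // 3]
            assert v.roots[0].nodes[0].radius == pytest.approx(
                branched_system.roots[0].nodes[0].radius * expected_scale
            )

    def test_rotation_about_collar_axis(self, branched_system):
        rot = augment_root_system(branched_system)[7]  # scale 1, rotation 120
        collar = branched_system.collar_position()
        assert np.allclose(rot.collar_position(), collar, atol=1e-9)
        # depths unchanged, horizontal positions rotated
        for a, b in zip(branched_system.roots, rot.roots):
            assert np.allclose(a.positions()[:, 2], b.positions()[:, 2], atol=1e-9)


class TestVoxelization:
    def test_zero_radius_marks_axis_only(self, small_grid):
        # vertical axis exactly through voxel centers of column (32, 32)
        x = small_grid.voxel_to_physical(np.array([32.0, 32.0, 0.0]))
        rs = straight_tube_system((x[0], x[1], 0.0), (x[0], x[1], -20.0), 0.0)
        vol = voxelize_root_system(rs, small_grid)
        on = np.argwhere(vol.data > 0)
        assert len(on) == 21
        assert set(map(tuple, on[:, :2])) == {(32, 32)}

    def test_capsule_volume_oracle(self):
        """Root voxel count ~ analytic capsule volume: the rendered tube is
        a cylinder pi r^2 L plus two hemispherical end caps (4/3) pi r^3."""
        grid = default_grid((100, 100, 240), (0.25, 0.25, 0.25))
        rs = straight_tube_system((0.0, 0.0, -2.0), (0.0, 0.0, -52.0), 1.0)
        vol = voxelize_root_system(rs, grid)
        count = int((vol.data > 0).sum())
        expected = (np.pi * 1.0**2 * 50.0 + 4.0 / 3.0 * np.pi * 1.0**3) / 0.25**3
        assert abs(count - expected) / expected < 0.05

    def test_outside_grid_warns_and_clips(self, small_grid):
        rs = straight_tube_system((0.0, 0.0, 0.0), (0.0, 0.0, -200.0), 1.0)
        with pytest.warns(UserWarning):
            vol = voxelize_root_system(rs, small_grid)
        assert vol.data.max() == 1.0


class TestNoise:
    def test_noiseless_levels_exact(self, small_grid):
        rs = straight_tube_system((0.0, 0.0, -5.0), (0.0, 0.0, -40.0), 1.0)
        clean = voxelize_root_system(rs, small_grid)
        noise = NoiseSpec(soil_mean=0.0, soil_sd=0.0, root_mean=1.0, root_sd=0.0,
                          dropout_rate_per_cm=0.0)
        out = add_soil_noise(clean, noise)
        assert np.array_equal(out.data, clean.data)

    def test_same_seed_identical(self, small_grid):
        rs = straight_tube_system((0.0, 0.0, -5.0), (0.0, 0.0, -40.0), 1.0)
        clean = voxelize_root_system(rs, small_grid)
        a = add_soil_noise(clean, NoiseSpec(seed=3))
        b = add_soil_noise(clean, NoiseSpec(seed=3))
        assert np.array_equal(a.data, b.data)

    def test_cnr_matches_nominal_parameters(self, small_grid):
        """Measured CNR converges to (root mean - soil mean)/soil sd when
        the zero-truncation mass is negligible; parameters give CNR 11,
        the low-contrast calibration value."""
        rs = straight_tube_system((0.0, 0.0, -5.0), (0.0, 0.0, -55.0), 1.2)
        clean = voxelize_root_system(rs, small_grid)
        assert (clean.data < 0.5).sum() >= 1e5
        noise = NoiseSpec(soil_mean=100.0, soil_sd=10.0, root_mean=210.0, root_sd=10.0)
        noisy = add_soil_noise(clean, noise)
        cnr = compute_cnr(noisy, clean)
        assert noise.nominal_cnr == pytest.approx(11.0)
        assert cnr == pytest.approx(11.0, rel=0.05)

    def test_dropouts_reduce_root_signal(self, small_grid):
        rs = straight_tube_system((0.0, 0.0, -5.0), (0.0, 0.0, -55.0), 1.2)
        clean = voxelize_root_system(rs, small_grid)
        noise = NoiseSpec(soil_mean=0.0, soil_sd=0.0, root_mean=1.0, root_sd=0.0,
                          dropout_rate_per_cm=2.0, dropout_radius_range_mm=(1.0, 2.0),
                          seed=5)
        out = add_soil_noise(clean, noise)
        assert (out.data > 0.5).sum() < (clean.data > 0.5).sum()


class TestGaps:
    def test_zero_rate_identity(self, small_grid):
        rs = straight_tube_system((0.0, 0.0, -5.0), (0.0, 0.0, -40.0), 1.0)
        clean = voxelize_root_system(rs, small_grid)
        out, realized = introduce_gaps(clean, rs, GapSpec(rate_per_cm=0.0))
        assert realized == []
        assert np.array_equal(out.data, clean.data)

    def test_gap_lengths_bounded_and_voxels_removed(self, small_grid):
        rs = straight_tube_system((0.0, 0.0, -5.0), (0.0, 0.0, -55.0), 1.0)
        clean = voxelize_root_system(rs, small_grid)
        gaps = GapSpec(rate_per_cm=1.0, length_range_mm=(1.0, 3.0), seed=2)
        out, realized = introduce_gaps(clean, rs, gaps)
        assert len(realized) >= 1
        assert max(realized) <= 3.0 + 1e-12
        assert (out.data > 0.5).sum() < (clean.data > 0.5).sum()

    def test_invalid_range_rejected(self):
        with pytest.raises(ValidationError):
            GapSpec(length_range_mm=(3.0, 1.0)).validate()


class TestBenchmarkCase:
    def test_reproducible_and_collar_on_root(self, small_grid):
        spec, noise, gaps = sparse_spec(4), NoiseSpec(seed=5), GapSpec(seed=6)
        v1, rs1, c1 = make_benchmark_case(spec, noise, gaps, small_grid)
        v2, rs2, c2 = make_benchmark_case(spec, noise, gaps, small_grid)
        assert np.array_equal(v1.data, v2.data)
        assert c1 == c2
        assert rs1.total_length_mm() == pytest.approx(rs2.total_length_mm())
        assert c1[2] == 0  # collar sits in the uppermost slice

    def test_zero_noise_zero_gaps_equals_clean(self, small_grid):
        spec = sparse_spec(4)
        noise = NoiseSpec(soil_mean=0.0, soil_sd=0.0, root_mean=1.0, root_sd=0.0,
                          dropout_rate_per_cm=0.0)
        vol, rs, _ = make_benchmark_case(spec, noise, GapSpec(rate_per_cm=0.0), small_grid)
        clean = voxelize_root_system(rs, small_grid)
        assert np.array_equal(vol.data, clean.data)
        # ground-truth RL is the polyline length of the generated system
        assert rs.total_length_mm() == pytest.approx(
            sum(r.length_mm() for r in rs.roots)
        )
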