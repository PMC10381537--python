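"""Cost-field construction and the gap-bridging shortest-path extraction.

The extraction is verified against an independent brute-force dynamic
program over (voxel, gap-run length) states, relaxed to a fixpoint.
"""

import itertools

import numpy as np
import pytest

from rootrace.errors import EmptyForegroundError, ValidationError
from rootrace.extraction import (
    CostField,
    TraceConfig,
    compute_cost_field,
    extract_connected_volume,
    find_start_voxel,
)
from rootrace.volume import Volume3D


def _field(cost, gap, spacing=(1.0, 1.0, 1.0)):
    return CostField(
        cost=np.asarray(cost, float),
        gap_mask=np.asarray(gap, bool),
        spacing=spacing,
        min_intensity=0.5,
    )


def _offsets(spacing):
    out = []
    for o in itertools.product((-1, 0, 1), repeat=3):
        if o == (0, 0, 0):
            continue
        length = float(np.linalg.norm(np.multiply(o, spacing)))
        out.append((o, length))
    return out


def brute_force_reachable(cost, gap, spacing, start, t_path, l_gap, eps=0.01):
    """Label-correcting fixpoint over (voxel, gap-run) states.

    Independent of the label-setting implementation: plain relaxation
    sweeps until nothing improves.  Returns {voxel: min path cost} over
    all feasible states.
    """
    offs = _offsets(spacing)
    shape = cost.shape
    labels = {start: {0.0: 0.0}}
    changed = True
    while changed:
        changed = False
        for v, runs in list(labels.items()):
            for run, c in list(runs.items()):
                for off, length in offs:
                    u = tuple(np.add(v, off))
                    if not all(0 <= u[d] < shape[d] for d in range(3)):
                        continue
                    nc = c + ((cost[v] + cost[u]) / 2.0 + eps) * length
                    if nc > t_path + 1e-12:
                        continue
                    if gap[u]:
                        nrun = round(run + length, 9)
                        if nrun > l_gap + 1e-9:
                            continue
                    else:
                        nrun = 0.0
                    cur = labels.setdefault(u, {})
                    if nc < cur.get(nrun, np.inf) - 1e-12:
                        cur[nrun] = nc
                        changed = True
    return {v: min(runs.values()) for v, runs in labels.items()}


class TestCostField:
    def test_uniform_volume_zero_cost(self):
        vol = Volume3D(np.full((3, 3, 3), 7.0))
        cfg = TraceConfig(intensity_weight=1.0, radius_weight=0.0)
        field = compute_cost_field(vol, cfg)
        assert not field.gap_mask.any()
        assert np.allclose(field.cost, 0.0)

    def test_single_supra_voxel_closed_form(self):
        data = np.full((5, 5, 5), 0.1)
        data[2, 2, 2] = 1.0
        vol = Volume3D(data)
        cfg = TraceConfig(min_intensity_frac=0.5, intensity_weight=0.7, radius_weight=0.3)
        field = compute_cost_field(vol, cfg)
        assert field.gap_mask.sum() == 124
        # the lone voxel has normalized intensity 1 and normalized EDT 1
        assert field.cost[2, 2, 2] == pytest.approx(1.0 - (0.7 * 1.0 + 0.3 * 1.0))
        assert np.all(field.cost[field.gap_mask] == cfg.gap_cost)

    def test_tube_axis_cheaper_than_surface(self):
        data = np.zeros((9, 9, 9))
        ii, jj = np.meshgrid(np.arange(9), np.arange(9), indexing="ij")
        tube = (ii - 4) ** 2 + (jj - 4) ** 2 <= 9
        data[tube, :] = 1.0
        vol = Volume3D(data)
        field = compute_cost_field(vol, TraceConfig())
        assert field.cost[4, 4, 4] < field.cost[1, 4, 4]

    def test_empty_foreground_rejected(self):
        with pytest.raises(EmptyForegroundError):
            compute_cost_field(Volume3D(np.zeros((3, 3, 3))), TraceConfig())

    def test_config_invariants(self):
        with pytest.raises(ValidationError):
            TraceConfig(intensity_weight=0.5, radius_weight=0.2).validate()
        with pytest.raises(ValidationError):
            TraceConfig(gap_cost=0.5).validate()


class TestExtraction:
    def test_full_cube_all_reached(self):
        field = _field(np.zeros((3, 3, 3)), np.zeros((3, 3, 3), bool))
        cfg = TraceConfig(start_voxel=(0, 0, 0), path_cost_threshold=1e9,
                          max_gap_length_mm=0.0)
        mask, out = extract_connected_volume(field, cfg)
        assert mask.data.sum() == 27
        assert out.path_cost[0, 0, 0] == 0.0

    def test_line_bridges_iff_budget_covers_gap(self):
        """1x1x7 line root,root,gap,gap,root,root,root at 1 mm spacing:
        a 2 mm budget bridges the 2 mm gap, a 1 mm budget does not."""
        cost = np.full((1, 1, 7), 0.1)
        gap = np.zeros((1, 1, 7), bool)
        gap[0, 0, 2:4] = True
        cost[gap] = 2.0
        for l_gap, expected in [(2.0, 5), (1.0, 2)]:
            field = _field(cost.copy(), gap)
            cfg = TraceConfig(start_voxel=(0, 0, 0), path_cost_threshold=1e9,
                              max_gap_length_mm=l_gap)
            mask, _ = extract_connected_volume(field, cfg)
            got = mask.data[0, 0, :] > 0
            assert got[~gap[0, 0]].sum() == expected

    @pytest.mark.parametrize("seed", range(20))
    def test_agrees_with_brute_force_dp(self, seed):
        """Random 5x5x5 costs/gaps/budgets: reachable supra-threshold set
        and minimal path costs equal the brute-force fixpoint."""
        rng = np.random.default_rng(seed)
        shape = (5, 5, 5)
        gap = rng.random(shape) < 0.35
        cost = rng.uniform(0.0, 1.0, shape)
        c_gap = rng.uniform(1.5, 3.0)
        cost[gap] = c_gap
        spacing = tuple(rng.uniform(0.5, 1.5, 3))
        start = tuple(int(x) for x in rng.integers(0, 5, 3))
        gap[start] = False
        t_path = rng.uniform(2.0, 8.0)
        l_gap = rng.uniform(0.0, 3.0)
        field = _field(cost, gap, spacing)
        cfg = TraceConfig(start_voxel=start, path_cost_threshold=t_path,
                          max_gap_length_mm=l_gap, gap_cost=c_gap)
        mask, out = extract_connected_volume(field, cfg)
        expected = brute_force_reachable(cost, gap, spacing, start, t_path, l_gap)
        exp_supra = {v for v in expected if not gap[v]}
        got_supra = set(map(tuple, np.argwhere(mask.data > 0))) - set(
            map(tuple, np.argwhere(gap))
        )
        assert got_supra == exp_supra
        for v in exp_supra:
            assert out.path_cost[v] == pytest.approx(expected[v], abs=1e-9)

    @pytest.mark.parametrize("seed", range(8))
    def test_monotone_in_budgets(self, seed):
        """The extracted set grows (set inclusion) with the gap budget and
        the path-cost threshold."""
        rng = np.random.default_rng(100 + seed)
        shape = (5, 5, 5)
        gap = rng.random(shape) < 0.3
        cost = rng.uniform(0.0, 1.0, shape)
        cost[gap] = 2.0
        start = (2, 2, 2)
        gap[start] = False
        prev = None
        for l_gap, t_path in [(0.0, 3.0), (1.0, 5.0), (2.0, 8.0), (3.5, 1e9)]:
            field = _field(cost, gap)
            cfg = TraceConfig(start_voxel=start, path_cost_threshold=t_path,
                              max_gap_length_mm=l_gap)
            mask, _ = extract_connected_volume(field, cfg)
            cur = set(map(tuple, np.argwhere(mask.data > 0)))
            if prev is not None:
                assert prev <= cur
            prev = cur

    def test_zero_budget_equals_connected_component(self):
        from scipy import ndimage

        rng = np.random.default_rng(42)
        supra = rng.random((6, 6, 6)) < 0.45
        supra[3, 3, 3] = True
        cost = np.where(supra, 0.2, 2.0)
        field = _field(cost, ~supra)
        cfg = TraceConfig(start_voxel=(3, 3, 3), path_cost_threshold=1e9,
                          max_gap_length_mm=0.0)
        mask, _ = extract_connected_volume(field, cfg)
        lab, _ = ndimage.label(supra, structure=np.ones((3, 3, 3)))
        comp = lab == lab[3, 3, 3]
        assert np.array_equal(mask.data > 0, comp)

    def test_distant_noise_cluster_never_included(self):
        """An isolated supra cluster farther than the gap budget from the
        component stays excluded regardless of the cost threshold."""
        supra = np.zeros((3, 3, 12), bool)
        supra[1, 1, :4] = True  # root segment
        supra[1, 1, 10:] = True  # noise cluster 6 mm away
        cost = np.where(supra, 0.0, 2.0)
        field = _field(cost, ~supra)
        cfg = TraceConfig(start_voxel=(1, 1, 0), path_cost_threshold=1e9,
                          max_gap_length_mm=4.0)
        mask, _ = extract_connected_volume(field, cfg)
        assert not mask.data[1, 1, 10:].any()

    def test_sub_threshold_start_rejected(self):
        gap = np.ones((3, 3, 3), bool)
        gap[0, 0, 0] = False
        field = _field(np.full((3, 3, 3), 2.0), gap)
        cfg = TraceConfig(start_voxel=(1, 1, 1))
        with pytest.raises(ValidationError):
            extract_connected_volume(field, cfg)

    def test_optimal_substructure_of_predecessors(self):
        rng = np.random.default_rng(9)
        cost = rng.uniform(0.0, 1.0, (5, 5, 5))
        gap = np.zeros((5, 5, 5), bool)
        field = _field(cost, gap)
        cfg = TraceConfig(start_voxel=(0, 0, 0), path_cost_threshold=1e9,
                          max_gap_length_mm=0.0)
        _, out = extract_connected_volume(field, cfg)
        strides = (25, 5, 1)
        for v in np.ndindex(5, 5, 5):
            flat = np.ravel_multi_index(v, (5, 5, 5))
            p = out.predecessor[v]
            if p < 0:
                continue
            pv = np.unravel_index(p, (5, 5, 5))
            step = np.linalg.norm(np.subtract(v, pv).astype(float))
            edge = ((cost[v] + cost[pv]) / 2.0 + cfg.edge_epsilon) * step
            assert out.path_cost[v] == pytest.approx(out.path_cost[pv] + edge, abs=1e-9)


def test_automatic_start_is_uppermost_tube_interior(small_grid):
    from conftest import straight_tube_system
    from rootrace.synthetic import voxelize_root_system

    rs = straight_tube_system((0.0, 0.0, 0.0), (0.0, 0.0, -40.0), 1.5)
    vol = voxelize_root_system(rs, small_grid)
    field = compute_cost_field(vol, TraceConfig())
    start = find_start_voxel(field)
    assert start[2] == 0  # uppermost slice
    pos = small_grid.voxel_to_physical(np.array(start, float))
    assert np.hypot(pos[0], pos[1]) <= 0.8  # near the tube axis
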