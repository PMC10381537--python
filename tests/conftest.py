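import numpy as np
import pytest

from rootrace.rootsystem import Root, RootNode, RootSystem
from rootrace.synthetic import SyntheticSpec, default_grid


@pytest.fixture
def small_grid():
    """Isotropic-in-plane desk-scale grid (32 x 32 x 64 mm)."""
    return default_grid((64, 64, 64), (0.5, 0.5, 1.0))


@pytest.fixture
def two_node_system():
    """One vertical 30 mm root: the minimal valid RootSystem."""
    tap = Root([RootNode((0.0, 0.0, 0.0), 0.5), RootNode((0.0, 0.0, -30.0), 0.4)])
    return RootSystem([tap], plant_age_days=10.0, label="minimal")


@pytest.fixture
def branched_system():
    """Tap plus two first-order laterals, hand-built."""
    tap = Root(
        [RootNode((0.0, 0.0, -10.0 * i), 1.0 - 0.1 * i) for i in range(5)],
        order=0,
    )
    lat1 = Root(
        [RootNode((0.0, 0.0, -10.0), 0.4), RootNode((8.0, 0.0, -12.0), 0.35),
         RootNode((15.0, 0.0, -15.0), 0.3)],
        order=1, parent=tap, parent_node_index=1,
    )
    lat2 = Root(
        [RootNode((0.0, 0.0, -20.0), 0.4), RootNode((-6.0, 3.0, -24.0), 0.3)],
        order=1, parent=tap, parent_node_index=2,
    )
    return RootSystem([tap, lat1, lat2], plant_age_days=12.0, label="branched")


def sparse_spec(seed: int, **overrides) -> SyntheticSpec:
    """Lupine-like system with well-separated laterals on a desk-scale grid."""
    kwargs = dict(
        container_height_mm=60.0,
        container_radius_mm=14.0,
        tap_length_range_mm=(40.0, 52.0),
        segment_step_mm=2.0,
        direction_persistence=0.85,
        gravitropism_weight=0.7,
        branch_spacing_mean_mm=11.0,
        branching_angle_deg=(55.0, 80.0),
        lateral_gravitropism_weight=0.05,
        max_order=1,
        base_radius_mm=(1.1, 0.7),
        taper_per_mm=0.003,
        lateral_length_factor=(0.2, 0.4),
        seed=seed,
    )
    kwargs.update(overrides)
    return SyntheticSpec(**kwargs)


def straight_tube_system(a, b, radius: float) -> RootSystem:
    """Single straight root from a to b (mm) with constant radius."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    mid = (a + b) / 2.0
    nodes = [RootNode(tuple(p), radius) for p in (a, mid, b)]
    return RootSystem([Root(nodes, order=0)])
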