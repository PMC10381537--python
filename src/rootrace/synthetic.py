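"""Ground-truthed synthetic root systems and volumetric phantom rendering.

The generator emulates the construction used to train and evaluate
MRI root-segmentation/tracing pipelines: stochastically grown lupine-like
root systems (a dominant tap root with lateral whorls) are rendered as
tubes into an anisotropic voxel grid, composited with parametric soil
noise, and interrupted by controllable signal gaps.  Every stage is a pure
function of its inputs and RNG seed, so downstream tracing stages can be
tested against exact ground truth without any external data.

Growth model: each root advances by fixed-length steps whose direction is
a renormalized blend

    d_new = normalize( w_p * d_prev + w_g * (0,0,-1) + w_n * u ),

with persistence weight ``w_p``, gravitropism weight ``w_g``, isotropic
random unit perturbation ``u`` and noise weight ``w_n = (1-w_p)*(1-w_g)``
(zero noise in the fully deterministic limit).  Lateral initiation points
follow a Poisson (exponential-spacing) process along the parent; each
lateral leaves at a branching angle drawn uniformly from a configured
interval, with uniform azimuth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats

from .errors import InfeasibleSpecError, ValidationError
from .rootsystem import Root, RootNode, RootSystem
from .volume import Volume3D

__all__ = [
    "SyntheticSpec",
    "NoiseSpec",
    "GapSpec",
    "default_grid",
    "generate_root_system",
    "augment_root_system",
    "voxelize_root_system",
    "add_soil_noise",
    "introduce_gaps",
    "make_benchmark_case",
]

RADIUS_SCALES = (1.0 / 3.0, 2.0 / 3.0, 1.0, 4.0 / 3.0)
ROTATIONS_DEG = (0.0, 120.0, 240.0)


@dataclass
class SyntheticSpec:
    """Stochastic growth parameters for one synthetic root system.

    Defaults describe an 8- to 15-day-old white lupine in a laboratory
    soil column (21 cm tall, 5.6 cm inner diameter).
    """

    container_height_mm: float = 210.0
    container_radius_mm: float = 28.0
    tap_length_range_mm: tuple[float, float] = (100.0, 160.0)
    segment_step_mm: float = 2.0
    direction_persistence: float = 0.7  # w_p in [0, 1]
    gravitropism_weight: float = 0.5  # w_g in [0, 1]
    branch_spacing_mean_mm: float = 8.0
    # renewal process for lateral initiation: interarrival = minimum
    # spacing + exponential remainder (primordia keep a refractory
    # distance); basal/apical unbranched zones as in standard
    # architecture models
    branch_spacing_min_mm: float = 2.0
    basal_zone_mm: float = 2.0
    apical_zone_mm: float = 5.0
    branching_angle_deg: tuple[float, float] = (40.0, 80.0)
    # laterals are plagiotropic: much weaker gravitropic response than the
    # tap, so they radiate outward instead of bundling along the axis
    lateral_gravitropism_weight: float = 0.1
    max_order: int = 2
    base_radius_mm: tuple[float, ...] = (1.2, 0.45, 0.3)  # per order
    taper_per_mm: float = 0.004  # linear radius taper fraction per mm
    lateral_length_factor: tuple[float, float] = (0.15, 0.45)  # of parent target
    seed: int = 0

    def validate(self) -> None:
        if self.container_height_mm <= 0 or self.container_radius_mm <= 0:
            raise ValidationError("container dimensions must be positive")
        lo, hi = self.tap_length_range_mm
        if not (0 < lo <= hi):
            raise ValidationError("invalid tap length range")
        if self.segment_step_mm <= 0:
            raise ValidationError("segment step must be positive")
        for w in (
            self.direction_persistence,
            self.gravitropism_weight,
            self.lateral_gravitropism_weight,
        ):
            if not 0 <= w <= 1:
                raise ValidationError("direction weights must lie in [0, 1]")
        a, b = self.branching_angle_deg
        if not (0 < a <= b <= 90):
            raise ValidationError("branching angle interval must lie in (0, 90]")
        if self.branch_spacing_min_mm < 0 or self.basal_zone_mm < 0 or self.apical_zone_mm < 0:
            raise ValidationError("branch zones and minimum spacing must be >= 0")
        if self.max_order < 0:
            raise ValidationError("max order must be >= 0")
        if any(r <= 0 for r in self.base_radius_mm):
            raise ValidationError("base radii must be positive")
        if hi > self.container_height_mm:
            raise InfeasibleSpecError(
                "container shorter than the maximum tap length"
            )


@dataclass
class NoiseSpec:
    """Parametric soil/root intensity model.

    Intensities are drawn from normals truncated at zero.  Defaults place
    the image in the low-contrast regime CNR = (root mean - soil mean) /
    soil sd = (120 - 10)/10 = 11, the difficult end of soil-grown MRI
    image quality; the soil mean is kept low enough that a 30%-of-max
    threshold separates most soil from root, as in segmented images.
    Spherical signal dropouts emulate losses caused by ferromagnetic soil
    particles.
    """

    soil_mean: float = 10.0
    soil_sd: float = 10.0
    root_mean: float = 120.0
    root_sd: float = 10.0
    dropout_rate_per_cm: float = 0.0
    dropout_radius_range_mm: tuple[float, float] = (0.5, 1.5)
    seed: int = 0

    def validate(self) -> None:
        if self.soil_sd < 0 or self.root_sd < 0:
            raise ValidationError("intensity sds must be >= 0")
        if self.dropout_rate_per_cm < 0:
            raise ValidationError("dropout rate must be >= 0")

    @property
    def nominal_cnr(self) -> float:
        return (self.root_mean - self.soil_mean) / self.soil_sd


@dataclass
class GapSpec:
    """Root-signal gap model: a Poisson process of intensity ``rate`` per
    cm of root arc length; each gap blanks an axial interval whose length
    is uniform in ``length_range_mm``."""

    rate_per_cm: float = 0.5
    length_range_mm: tuple[float, float] = (1.0, 3.0)
    seed: int = 0

    def validate(self) -> None:
        if self.rate_per_cm < 0:
            raise ValidationError("gap rate must be >= 0")
        lo, hi = self.length_range_mm
        if not (0 < lo <= hi):
            raise ValidationError("invalid gap length range")


def default_grid(
    shape: tuple[int, int, int] = (256, 256, 70),
    spacing: tuple[float, float, float] = (0.273, 0.273, 1.0),
) -> Volume3D:
    """Empty image grid; default emulates a 70 mm field-of-view MRI stack.

    The vertical container axis passes through x = y = 0 and the soil
    surface (z = 0) lies in the first slice.
    """
    nx, ny, _ = shape
    dx, dy, _ = spacing
    origin = (-(nx - 1) * dx / 2.0, -(ny - 1) * dy / 2.0, 0.0)
    return Volume3D(np.zeros(shape, dtype=np.float32), spacing, origin)


# ---------------------------------------------------------------------------
# growth


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    return v / n if n > 0 else np.array([0.0, 0.0, -1.0])


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return _unit(v)


def _perp_basis(d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    helper = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(helper, d)) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    u = _unit(np.cross(d, helper))
    v = np.cross(d, u)
    return u, v


def _grow_polyline(
    spec: SyntheticSpec,
    rng: np.random.Generator,
    start: np.ndarray,
    direction: np.ndarray,
    target_length: float,
    base_radius: float,
    order: int = 0,
) -> list[RootNode]:
    """Step a single root tip until target length or the container wall."""
    w_p = spec.direction_persistence
    w_g = spec.gravitropism_weight if order == 0 else spec.lateral_gravitropism_weight
    w_n = (1.0 - w_p) * (1.0 - w_g)
    down = np.array([0.0, 0.0, -1.0])
    pos = start.astype(float).copy()
    d = _unit(direction)

    def radius_at(s: float) -> float:
        return base_radius * max(0.1, 1.0 - spec.taper_per_mm * s)

    nodes = [RootNode(tuple(pos), radius_at(0.0))]
    grown = 0.0
    while grown < target_length - 1e-9:
        step = min(spec.segment_step_mm, target_length - grown)
        d = _unit(w_p * d + w_g * down + w_n * _random_unit(rng))
        nxt = pos + step * d
        if (
            np.hypot(nxt[0], nxt[1]) > spec.container_radius_mm
            or nxt[2] < -spec.container_height_mm
            or nxt[2] > 0.0 + 1e-9
        ):
            break
        pos = nxt
        grown += step
        nodes.append(RootNode(tuple(pos), radius_at(grown)))
    return nodes


def _branch_direction(
    spec: SyntheticSpec, rng: np.random.Generator, parent_dir: np.ndarray
) -> np.ndarray:
    lo, hi = spec.branching_angle_deg
    theta = np.deg2rad(rng.uniform(lo, hi))
    phi = rng.uniform(0.0, 2.0 * np.pi)
    u, v = _perp_basis(parent_dir)
    return _unit(
        np.cos(theta) * parent_dir + np.sin(theta) * (np.cos(phi) * u + np.sin(phi) * v)
    )


def generate_root_system(spec: SyntheticSpec) -> RootSystem:
    """Grow one synthetic root system (deterministic given ``spec.seed``)."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    tap_length = rng.uniform(*spec.tap_length_range_mm)
    tap_nodes = _grow_polyline(
        spec,
        rng,
        np.zeros(3),
        np.array([0.0, 0.0, -1.0]),
        tap_length,
        spec.base_radius_mm[0],
    )
    tap = Root(tap_nodes, order=0)
    roots = [tap]

    def branch(parent: Root, parent_target: float) -> None:
        order = parent.order + 1
        if order > spec.max_order or not np.isfinite(spec.branch_spacing_mean_mm):
            return
        arcs = parent.arc_lengths_mm()
        length = arcs[-1]
        s_min = spec.branch_spacing_min_mm
        exp_mean = max(spec.branch_spacing_mean_mm - s_min, 1e-9)

        def interarrival() -> float:
            return s_min + rng.exponential(exp_mean)

        s = spec.basal_zone_mm + rng.exponential(exp_mean)
        while s < length - spec.apical_zone_mm:
            idx = int(np.argmin(np.abs(arcs - s)))
            if idx >= 1:  # never branch off the very collar node
                p = np.array(parent.nodes[idx].position)
                seg_dir = _unit(
                    np.array(parent.nodes[idx].position)
                    - np.array(parent.nodes[idx - 1].position)
                )
                d0 = _branch_direction(spec, rng, seg_dir)
                target = max(
                    spec.segment_step_mm,
                    rng.uniform(*spec.lateral_length_factor) * parent_target,
                )
                base_r = spec.base_radius_mm[min(order, len(spec.base_radius_mm) - 1)]
                nodes = _grow_polyline(spec, rng, p, d0, target, base_r, order=order)
                if len(nodes) >= 2:
                    child = Root(nodes, order=order, parent=parent, parent_node_index=idx)
                    roots.append(child)
                    branch(child, target)
            s += interarrival()

    branch(tap, tap_length)
    rs = RootSystem(roots, plant_age_days=10.0, label=f"synthetic-{spec.seed}")
    rs.validate()
    return rs


def augment_root_system(rs: RootSystem) -> list[RootSystem]:
    """The 12 standard augmentations: radius scales {1/3, 2/3, 1, 4/3}
    crossed with rotations {0, 120, 240} degrees about the vertical axis
    through the collar (radius scale as the outer loop)."""
    return [
        rs.transformed(radius_scale=s, rotation_deg=r)
        for s in RADIUS_SCALES
        for r in ROTATIONS_DEG
    ]


# ---------------------------------------------------------------------------
# rendering


def _capsule_paint(
    vol: Volume3D,
    a: np.ndarray,
    b: np.ndarray,
    ra: float,
    rb: float,
    value: float,
    margin: float = 0.0,
    flat_ends: bool = False,
) -> bool:
    """Set voxels whose centers lie within the linearly interpolated tube
    radius of segment a->b.  Returns False if the bounding box was clipped."""
    data = vol.data
    rmax = max(ra, rb) + margin
    lo_phys = np.minimum(a, b) - rmax
    hi_phys = np.maximum(a, b) + rmax
    # physical box -> index box (z axis is inverted)
    corners = np.array(
        [vol.physical_to_voxel(np.array([x, y, z]))
         for x in (lo_phys[0], hi_phys[0])
         for y in (lo_phys[1], hi_phys[1])
         for z in (lo_phys[2], hi_phys[2])]
    )
    lo = np.floor(corners.min(axis=0)).astype(int)
    hi = np.ceil(corners.max(axis=0)).astype(int)
    clipped = bool(np.any(lo < 0) or np.any(hi >= data.shape))
    lo_c = np.maximum(lo, 0)
    hi_c = np.minimum(hi, np.array(data.shape) - 1)
    if np.any(lo_c > hi_c):
        return not clipped
    ii, jj, kk = np.meshgrid(
        np.arange(lo_c[0], hi_c[0] + 1),
        np.arange(lo_c[1], hi_c[1] + 1),
        np.arange(lo_c[2], hi_c[2] + 1),
        indexing="ij",
    )
    idx = np.stack([ii, jj, kk], axis=-1)
    centers = vol.voxel_to_physical(idx)
    ab = b - a
    ab2 = float(np.dot(ab, ab))
    rel = centers - a
    if ab2 == 0.0:
        t = np.zeros(centers.shape[:-1])
    else:
        t = np.einsum("...i,i->...", rel, ab) / ab2
    tc = np.clip(t, 0.0, 1.0)
    closest = a + tc[..., None] * ab
    dist = np.linalg.norm(centers - closest, axis=-1)
    radius = ra + tc * (rb - ra) + margin
    inside = dist <= radius + 1e-9
    if flat_ends:
        inside &= (t >= 0.0) & (t <= 1.0)
    sub = data[lo_c[0]:hi_c[0] + 1, lo_c[1]:hi_c[1] + 1, lo_c[2]:hi_c[2] + 1]
    sub[inside] = value
    return not clipped


def voxelize_root_system(rs: RootSystem, grid: Volume3D) -> Volume3D:
    """Render a root system as a binary-in-intensity tube image.

    A voxel is root (intensity 1.0) iff its center lies within the
    linearly interpolated tube radius of some segment's axis; all other
    voxels are 0.0.  Parts outside the grid are clipped with a warning.
    """
    out = grid.like(np.zeros(grid.shape, dtype=np.float32))
    fully_inside = True
    for _root, _i, na, nb in rs.iter_segments():
        ok = _capsule_paint(
            out,
            np.array(na.position),
            np.array(nb.position),
            na.radius,
            nb.radius,
            1.0,
        )
        fully_inside = fully_inside and ok
    if not fully_inside:
        warnings.warn("root system extends outside the grid; clipped")
    return out


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, size: int
) -> np.ndarray:
    if sd == 0:
        return np.full(size, float(mean))
    a = (0.0 - mean) / sd
    return stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=size, random_state=rng)


def _estimate_root_length_cm(vol: Volume3D, root_mask: np.ndarray) -> float:
    """Root arc length estimated from a clean rendering: V / (pi r^2) with
    r = 3x the mean distance-to-boundary (exact for a solid cylinder)."""
    if not root_mask.any():
        return 0.0
    edt = ndimage.distance_transform_edt(root_mask, sampling=vol.spacing)
    r_hat = 3.0 * float(edt[root_mask].mean())
    v_mm3 = float(root_mask.sum()) * vol.voxel_volume_mm3
    if r_hat <= 0:
        return 0.0
    return v_mm3 / (np.pi * r_hat**2) / 10.0


def add_soil_noise(vol: Volume3D, noise: NoiseSpec) -> Volume3D:
    """Composite a clean root rendering with parametric soil/root noise.

    Background voxels get Normal(soil mean, soil sd) truncated at 0, root
    voxels Normal(root mean, root sd) truncated at 0; spherical dropouts
    (rate per cm of root) replace root signal with background draws.
    """
    noise.validate()
    rng = np.random.default_rng(noise.seed)
    root_mask = vol.data > 0.5
    out = np.empty(vol.shape, dtype=np.float32)
    n_bg = int((~root_mask).sum())
    n_rt = int(root_mask.sum())
    out[~root_mask] = _truncated_normal(rng, noise.soil_mean, noise.soil_sd, n_bg)
    out[root_mask] = _truncated_normal(rng, noise.root_mean, noise.root_sd, n_rt)
    result = vol.like(out)

    if noise.dropout_rate_per_cm > 0 and n_rt > 0:
        length_cm = _estimate_root_length_cm(vol, root_mask)
        n_drop = rng.poisson(noise.dropout_rate_per_cm * length_cm)
        if n_drop > 0:
            root_idx = np.argwhere(root_mask)
            picks = root_idx[rng.integers(0, len(root_idx), size=n_drop)]
            centers = result.voxel_to_physical(picks)
            lo, hi = noise.dropout_radius_range_mm
            for c in centers:
                r = rng.uniform(lo, hi)
                _paint_sphere_background(result, c, r, rng, noise)
    return result


def _paint_sphere_background(
    vol: Volume3D, center: np.ndarray, radius: float, rng: np.random.Generator, noise: NoiseSpec
) -> None:
    corners = np.array(
        [vol.physical_to_voxel(center + radius * np.array(s))
         for s in [(-1, -1, -1), (1, 1, 1), (-1, 1, -1), (1, -1, 1)]]
    )
    lo = np.maximum(np.floor(corners.min(axis=0)).astype(int), 0)
    hi = np.minimum(np.ceil(corners.max(axis=0)).astype(int), np.array(vol.shape) - 1)
    if np.any(lo > hi):
        return
    ii, jj, kk = np.meshgrid(
        *[np.arange(lo[d], hi[d] + 1) for d in range(3)], indexing="ij"
    )
    centers = vol.voxel_to_physical(np.stack([ii, jj, kk], axis=-1))
    inside = np.linalg.norm(centers - center, axis=-1) <= radius
    n = int(inside.sum())
    if n:
        sub = vol.data[lo[0]:hi[0] + 1, lo[1]:hi[1] + 1, lo[2]:hi[2] + 1]
        sub[inside] = _truncated_normal(rng, noise.soil_mean, noise.soil_sd, n)


def introduce_gaps(
    vol: Volume3D, rs: RootSystem, gaps: GapSpec
) -> tuple[Volume3D, list[float]]:
    """Blank axial intervals of root signal along each root.

    Gap centers follow a Poisson process over arc length; interval lengths
    are uniform in the configured range (so every realized gap is at most
    the configured maximum).  Cleared voxels are set to the background
    level (0 in a clean rendering).  Returns the modified copy and the
    list of realized gap lengths (mm).
    """
    gaps.validate()
    rng = np.random.default_rng(gaps.seed)
    out = vol.copy()
    realized: list[float] = []
    margin = 0.75 * max(vol.spacing)
    for root in rs.roots:
        arcs = root.arc_lengths_mm()
        length = arcs[-1]
        n = rng.poisson(gaps.rate_per_cm * length / 10.0)
        for _ in range(n):
            center = rng.uniform(0.0, length)
            glen = rng.uniform(*gaps.length_range_mm)
            s0 = max(0.0, center - glen / 2.0)
            s1 = min(length, center + glen / 2.0)
            if s1 <= s0:
                continue
            realized.append(s1 - s0)
            _clear_interval(out, root, arcs, s0, s1, margin)
    return out, realized


def _point_at(root: Root, arcs: np.ndarray, s: float) -> tuple[np.ndarray, float]:
    i = int(np.searchsorted(arcs, s, side="right")) - 1
    i = min(max(i, 0), len(arcs) - 2)
    seg = arcs[i + 1] - arcs[i]
    t = 0.0 if seg == 0 else (s - arcs[i]) / seg
    a, b = np.array(root.nodes[i].position), np.array(root.nodes[i + 1].position)
    ra, rb = root.nodes[i].radius, root.nodes[i + 1].radius
    return a + t * (b - a), ra + t * (rb - ra)


def _clear_interval(
    vol: Volume3D, root: Root, arcs: np.ndarray, s0: float, s1: float, margin: float
) -> None:
    # flat-ended cylindrical cut so the axial gap extent equals s1 - s0
    samples = [s0] + [s for s in arcs if s0 < s < s1] + [s1]
    for u, v in zip(samples[:-1], samples[1:]):
        (pa, ra), (pb, rb) = _point_at(root, arcs, u), _point_at(root, arcs, v)
        _capsule_paint(vol, pa, pb, ra, rb, 0.0, margin=margin, flat_ends=True)


def make_benchmark_case(
    spec: SyntheticSpec,
    noise: NoiseSpec,
    gaps: GapSpec,
    grid: Volume3D,
) -> tuple[Volume3D, RootSystem, tuple[int, int, int]]:
    """Generate, render, gap and noise one ground-truthed benchmark case.

    Returns the final volume, the ground-truth system, and the voxel index
    of the collar (uppermost tap node) — the analogue of an automatically
    detected trace start point.
    """
    rs = generate_root_system(spec)
    clean = voxelize_root_system(rs, grid)
    gapped, _ = introduce_gaps(clean, rs, gaps)
    noisy = add_soil_noise(gapped, noise)
    collar = np.rint(grid.physical_to_voxel(rs.collar_position())).astype(int)
    collar = tuple(int(np.clip(collar[d], 0, grid.shape[d] - 1)) for d in range(3))
    return noisy, rs, collar
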