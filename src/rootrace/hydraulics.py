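"""Water flow on the root hydraulic architecture: K_rs, SUF and zSUF.

The root system is treated as a network of xylem segments.  Segment i of
length L_i (cm) and radius r_i (cm) exchanges water radially with the
soil through conductance

    K_rad,i = kr_i * 2 pi r_i L_i        (cm^3 hPa^-1 d^-1)

and conducts water axially between its end nodes through

    K_ax,i = kx_i / L_i                  (cm^3 hPa^-1 d^-1),

with kr the radial conductivity of the root surface (cm hPa^-1 d^-1) and
kx the intrinsic axial conductance (cm^3 hPa^-1 d^-1 cm).  Node-wise mass
balance under a uniform soil water potential psi_soil and a Dirichlet
collar potential psi_collar yields a sparse symmetric positive-definite
system for the xylem potentials.  Derived quantities:

* collar flux          Q = sum of radial fluxes (cm^3 d^-1),
* equivalent root system conductance
                       K_rs = Q / (psi_soil - psi_collar),
* standard uptake fraction
                       SUF_i = flux_i / Q  (sums to 1),
* mean uptake depth    zSUF = sum_i SUF_i z_i (cm, negative down).

Since 1 hPa is numerically ~1 cm of water column, K_rs in
cm^3 d^-1 hPa^-1 is conventionally reported as cm^2 d^-1.

Two scenarios are supported: *constant* (one kr, one kx for every
segment) and *variable* (kr, kx looked up by root-order class — tap vs
lateral — and segment age, piecewise-linear in age).  Segment ages
decrease linearly from the root base to 0 at the tip; a lateral's base
age is the age of the parent node it attaches to.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import spsolve

from .errors import SolverError, ValidationError
from .rootsystem import Root, RootSystem

__all__ = [
    "AgeTable",
    "HydraulicScenario",
    "FlowSolution",
    "solve_water_flow",
    "equivalent_conductance",
    "zsuf",
]


@dataclass
class AgeTable:
    """Piecewise-linear lookup value(age); ages in days, clamped ends."""

    points: list[tuple[float, float]]

    def __post_init__(self) -> None:
        self.points = sorted((float(a), float(v)) for a, v in self.points)
        if not self.points or any(v <= 0 for _, v in self.points):
            raise ValidationError("conductivity table values must be positive")

    def __call__(self, age: float | np.ndarray) -> np.ndarray:
        ages = np.array([a for a, _ in self.points])
        vals = np.array([v for _, v in self.points])
        return np.interp(age, ages, vals)


# Default order/age-dependent conductivities: order-of-magnitude values for
# young lupine; laterals more radially permeable than the tap, radial
# conductivity declining and axial conductance rising with tissue age.
_DEFAULT_KR = {
    "tap": AgeTable([(0.0, 3.0e-4), (10.0, 1.2e-4), (30.0, 6.0e-5)]),
    "lateral": AgeTable([(0.0, 6.0e-4), (10.0, 3.0e-4), (30.0, 1.5e-4)]),
}
_DEFAULT_KX = {
    "tap": AgeTable([(0.0, 0.05), (10.0, 0.2), (30.0, 0.4)]),
    "lateral": AgeTable([(0.0, 2.0e-3), (10.0, 8.0e-3), (30.0, 2.0e-2)]),
}


@dataclass
class HydraulicScenario:
    """Conductivity model plus boundary potentials.

    ``mode='constant'``: ``kr_constant`` / ``kx_constant`` apply to every
    segment.  ``mode='variable'``: ``kr_tables`` / ``kx_tables`` map the
    order class ('tap' for order 0, 'lateral' otherwise) to an
    :class:`AgeTable`.
    """

    mode: Literal["constant", "variable"] = "constant"
    kr_constant: float = 1.8e-4  # cm hPa^-1 d^-1
    kx_constant: float = 0.1  # cm^3 hPa^-1 d^-1 cm
    kr_tables: dict = field(default_factory=lambda: dict(_DEFAULT_KR))
    kx_tables: dict = field(default_factory=lambda: dict(_DEFAULT_KX))
    psi_soil: float = -100.0  # hPa
    psi_collar: float = -1000.0  # hPa

    def validate(self) -> None:
        if self.mode not in ("constant", "variable"):
            raise ValidationError(f"unknown scenario mode {self.mode!r}")
        if self.mode == "constant" and (self.kr_constant <= 0 or self.kx_constant <= 0):
            raise ValidationError("constant kr and kx must be positive")
        if self.psi_soil == self.psi_collar:
            raise ValidationError("psi_soil must differ from psi_collar")

    def kr(self, order: int, age: float) -> float:
        if self.mode == "constant":
            return self.kr_constant
        return float(self.kr_tables["tap" if order == 0 else "lateral"](age))

    def kx(self, order: int, age: float) -> float:
        if self.mode == "constant":
            return self.kx_constant
        return float(self.kx_tables["tap" if order == 0 else "lateral"](age))


@dataclass
class FlowSolution:
    node_potentials_hPa: np.ndarray
    segment_radial_flux_cm3_d: np.ndarray
    collar_flux_cm3_d: float
    suf: np.ndarray
    segment_mid_depth_cm: np.ndarray
    krs_cm2_d: float
    conservation_residual: float


def _node_ages(rs: RootSystem) -> dict[tuple[int, int], float]:
    """Age (days) of each (root index, node index): linear from base to tip."""
    ages: dict[tuple[int, int], float] = {}
    index = {id(r): i for i, r in enumerate(rs.roots)}

    def fill(root: Root, base_age: float) -> None:
        ri = index[id(root)]
        arcs = root.arc_lengths_mm()
        total = arcs[-1] if arcs[-1] > 0 else 1.0
        for ni in range(len(root.nodes)):
            ages[(ri, ni)] = base_age * (1.0 - arcs[ni] / total)
        for child in rs.children_of(root):
            fill(child, ages[(ri, child.parent_node_index or 0)])

    fill(rs.tap, float(rs.plant_age_days))
    return ages


def solve_water_flow(rs: RootSystem, sc: HydraulicScenario) -> FlowSolution:
    """Assemble and solve the hydraulic network for one root system."""
    sc.validate()
    rs.validate()
    index = {id(r): i for i, r in enumerate(rs.roots)}

    # global node numbering; a lateral's first node is its parent's node
    node_id: dict[tuple[int, int], int] = {}
    coords: list[np.ndarray] = []

    def gid(root: Root, ni: int) -> int:
        ri = index[id(root)]
        if ni == 0 and root.parent is not None:
            return gid(root.parent, root.parent_node_index or 0)
        key = (ri, ni)
        if key not in node_id:
            node_id[key] = len(coords)
            coords.append(np.array(root.nodes[ni].position) / 10.0)  # mm -> cm
        return node_id[key]

    ages = _node_ages(rs)
    seg_nodes: list[tuple[int, int]] = []
    seg_krad: list[float] = []
    seg_kax: list[float] = []
    seg_depth: list[float] = []
    for root in rs.roots:
        ri = index[id(root)]
        for i in range(len(root.nodes) - 1):
            a, b = root.nodes[i], root.nodes[i + 1]
            length_cm = float(np.linalg.norm(np.subtract(b.position, a.position))) / 10.0
            if length_cm <= 0:
                continue
            radius_cm = (a.radius + b.radius) / 2.0 / 10.0
            age = (ages[(ri, i)] + ages[(ri, i + 1)]) / 2.0
            kr = sc.kr(root.order, age)
            kx = sc.kx(root.order, age)
            if kr <= 0 or kx <= 0:
                raise SolverError("non-positive conductance in scenario")
            seg_nodes.append((gid(root, i), gid(root, i + 1)))
            seg_krad.append(kr * 2.0 * np.pi * radius_cm * length_cm)
            seg_kax.append(kx / length_cm)
            seg_depth.append((a.position[2] + b.position[2]) / 2.0 / 10.0)

    n = len(coords)
    if n < 2 or not seg_nodes:
        raise SolverError("root system has no hydraulic segments")
    collar = 0  # first node created is the tap base

    rows, cols, vals = [], [], []
    rhs = np.zeros(n)

    def add(i: int, j: int, v: float) -> None:
        rows.append(i)
        cols.append(j)
        vals.append(v)

    for (na, nb), krad, kax in zip(seg_nodes, seg_krad, seg_kax):
        add(na, na, kax)
        add(nb, nb, kax)
        add(na, nb, -kax)
        add(nb, na, -kax)
        # half the radial conductance lumped to each end node
        for nd in (na, nb):
            add(nd, nd, krad / 2.0)
            rhs[nd] += (krad / 2.0) * sc.psi_soil

    a_mat = sparse.csr_matrix(
        sparse.coo_matrix((vals, (rows, cols)), shape=(n, n))
    )
    # Dirichlet condition at the collar
    free = np.ones(n, dtype=bool)
    free[collar] = False
    a_ff = a_mat[free][:, free]
    b_f = rhs[free] - a_mat[free][:, [collar]].toarray().ravel() * sc.psi_collar
    try:
        psi_free = spsolve(a_ff.tocsc(), b_f)
    except Exception as exc:
        raise SolverError(f"hydraulic system solve failed: {exc}") from exc
    if not np.all(np.isfinite(psi_free)):
        raise SolverError("singular hydraulic system")
    psi = np.empty(n)
    psi[collar] = sc.psi_collar
    psi[free] = psi_free

    seg_nodes_arr = np.array(seg_nodes)
    krad_arr = np.array(seg_krad)
    psi_mid = (psi[seg_nodes_arr[:, 0]] + psi[seg_nodes_arr[:, 1]]) / 2.0
    flux = krad_arr * (sc.psi_soil - psi_mid)
    q = float(flux.sum())

    # independent collar balance for the conservation check
    q_collar = 0.0
    for (na, nb), krad, kax in zip(seg_nodes, seg_krad, seg_kax):
        if na == collar:
            q_collar += kax * (psi[nb] - psi[collar]) + (krad / 2.0) * (
                sc.psi_soil - psi[collar]
            )
        elif nb == collar:
            q_collar += kax * (psi[na] - psi[collar]) + (krad / 2.0) * (
                sc.psi_soil - psi[collar]
            )
    residual = abs(q - q_collar) / max(abs(q), 1e-300)

    dpsi = sc.psi_soil - sc.psi_collar
    suf = flux / q if q != 0 else np.zeros_like(flux)
    return FlowSolution(
        node_potentials_hPa=psi,
        segment_radial_flux_cm3_d=flux,
        collar_flux_cm3_d=q,
        suf=suf,
        segment_mid_depth_cm=np.array(seg_depth),
        krs_cm2_d=q / dpsi,
        conservation_residual=residual,
    )


def equivalent_conductance(rs: RootSystem, sc: HydraulicScenario) -> float:
    """K_rs = Q / (psi_soil - psi_collar); independent of the potentials."""
    return solve_water_flow(rs, sc).krs_cm2_d


def zsuf(rs: RootSystem, sc: HydraulicScenario) -> float:
    """SUF-weighted mean uptake depth (cm, negative below the surface)."""
    sol = solve_water_flow(rs, sc)
    return float(np.dot(sol.suf, sol.segment_mid_depth_cm))
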