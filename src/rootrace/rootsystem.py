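"""Root system architecture as a rooted tree of polyline roots.

A :class:`RootSystem` is one plant: exactly one order-0 (tap/primary) root,
plus laterals of order k attached to parents of order k-1.  Each
:class:`Root` is an ordered polyline of :class:`RootNode` (position in mm,
z <= 0 below the soil surface) with a per-node radius in mm.  A lateral's
first node coincides with the parent node it attaches to.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional

import numpy as np

from .errors import ValidationError

__all__ = ["RootNode", "Root", "RootSystem"]


@dataclass
class RootNode:
    position: tuple[float, float, float]  # mm; z negative below soil surface
    radius: float = 0.0  # mm

    def __post_init__(self) -> None:
        self.position = tuple(float(p) for p in self.position)
        self.radius = float(self.radius)
        if not all(np.isfinite(self.position)):
            raise ValidationError(f"non-finite node position {self.position}")
        if not np.isfinite(self.radius) or self.radius < 0:
            raise ValidationError(f"node radius must be >= 0, got {self.radius}")


@dataclass
class Root:
    nodes: list[RootNode]
    order: int = 0
    parent: Optional["Root"] = None
    parent_node_index: Optional[int] = None

    def positions(self) -> np.ndarray:
        return np.array([n.position for n in self.nodes], dtype=float)

    def radii(self) -> np.ndarray:
        return np.array([n.radius for n in self.nodes], dtype=float)

    def segment_lengths_mm(self) -> np.ndarray:
        p = self.positions()
        if len(p) < 2:
            return np.zeros(0)
        return np.linalg.norm(np.diff(p, axis=0), axis=1)

    def length_mm(self) -> float:
        return float(self.segment_lengths_mm().sum())

    def arc_lengths_mm(self) -> np.ndarray:
        """Cumulative arc length at each node, starting at 0."""
        seg = self.segment_lengths_mm()
        return np.concatenate([[0.0], np.cumsum(seg)])


@dataclass
class RootSystem:
    roots: list[Root] = field(default_factory=list)
    plant_age_days: float = 10.0
    label: str = ""

    # -- structure ---------------------------------------------------------

    @property
    def tap(self) -> Root:
        taps = [r for r in self.roots if r.order == 0]
        if len(taps) != 1:
            raise ValidationError(f"expected exactly one order-0 root, got {len(taps)}")
        return taps[0]

    def children_of(self, root: Root) -> list[Root]:
        return [r for r in self.roots if r.parent is root]

    def collar_position(self) -> np.ndarray:
        return np.array(self.tap.nodes[0].position)

    def validate(self) -> None:
        taps = [r for r in self.roots if r.order == 0]
        if len(taps) != 1:
            raise ValidationError(f"expected exactly one order-0 root, got {len(taps)}")
        if taps[0].parent is not None:
            raise ValidationError("tap root must not have a parent")
        seen: set[int] = set()
        for r in self.roots:
            if len(r.nodes) < 2:
                raise ValidationError("degenerate root with < 2 nodes")
            if id(r) in seen:
                raise ValidationError("duplicate root object in system")
            seen.add(id(r))
            if r.order > 0:
                if r.parent is None or r.parent not in self.roots:
                    raise ValidationError("lateral without a parent in the system")
                if r.order != r.parent.order + 1:
                    raise ValidationError(
                        f"child order {r.order} != parent order {r.parent.order} + 1"
                    )
                if r.parent_node_index is None or not (
                    0 <= r.parent_node_index < len(r.parent.nodes)
                ):
                    raise ValidationError("attachment node missing on parent")
        # acyclicity / connectivity: walking parent links must reach the tap
        for r in self.roots:
            hops, cur = 0, r
            while cur.parent is not None:
                cur = cur.parent
                hops += 1
                if hops > len(self.roots):
                    raise ValidationError("cycle in parent links")
            if cur is not taps[0]:
                raise ValidationError("root not connected to the tap")

    # -- measures ----------------------------------------------------------

    def total_length_mm(self) -> float:
        return float(sum(r.length_mm() for r in self.roots))

    def total_length_cm(self) -> float:
        return self.total_length_mm() / 10.0

    def counts_per_order(self) -> dict[int, int]:
        counts: dict[int, int] = {}
        for r in self.roots:
            counts[r.order] = counts.get(r.order, 0) + 1
        return counts

    def iter_segments(self) -> Iterator[tuple[Root, int, RootNode, RootNode]]:
        """Yield (root, segment index, node a, node b) over all segments."""
        for r in self.roots:
            for i in range(len(r.nodes) - 1):
                yield r, i, r.nodes[i], r.nodes[i + 1]

    # -- transforms --------------------------------------------------------

    def transformed(
        self,
        radius_scale: float = 1.0,
        rotation_deg: float = 0.0,
    ) -> "RootSystem":
        """Copy with radii scaled and positions rotated about the vertical
        axis through the collar."""
        theta = np.deg2rad(rotation_deg)
        c, s = np.cos(theta), np.sin(theta)
        cx, cy, _ = self.collar_position()

        def rot(p: tuple[float, float, float]) -> tuple[float, float, float]:
            x, y, z = p
            x, y = x - cx, y - cy
            return (cx + c * x - s * y, cy + s * x + c * y, z)

        mapping: dict[int, Root] = {}
        new_roots: list[Root] = []
        for r in self.roots:
            nr = Root(
                nodes=[RootNode(rot(n.position), n.radius * radius_scale) for n in r.nodes],
                order=r.order,
                parent=None,
                parent_node_index=r.parent_node_index,
            )
            mapping[id(r)] = nr
            new_roots.append(nr)
        for r, nr in zip(self.roots, new_roots):
            if r.parent is not None:
                nr.parent = mapping[id(r.parent)]
        return RootSystem(new_roots, self.plant_age_days, self.label)
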