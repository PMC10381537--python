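"""From curve skeleton to a rooted, ordered root system.

The skeleton voxels are classified by 26-neighbor count (1 = end,
2 = chain, >= 3 = junction); maximal chains between classified vertices
become graph edges annotated with physical length, mean traversal cost
and local radius estimates (distance-transform values of the pre-skeleton
mask).  Cycles — typically produced by touching roots merged in the
volume extraction — are broken by a minimum-cost spanning tree, the tap
root is the collar-to-leaf path reaching the greatest depth, and at every
branch point the child chain that deviates least from the incoming
direction continues the current root while all other children start
laterals of the next order.
"""

from __future__ import annotations

from itertools import product

import networkx as nx
import numpy as np
from scipy import ndimage

from .errors import ValidationError
from .extraction import CostField
from .rootsystem import Root, RootNode, RootSystem
from .volume import Volume3D

__all__ = [
    "build_skeleton_graph",
    "extract_root_system",
    "nearest_vertex",
    "prune_short_spurs",
]

_NEIGH26 = [o for o in product((-1, 0, 1), repeat=3) if o != (0, 0, 0)]


def build_skeleton_graph(
    skel: Volume3D,
    field: CostField | None = None,
    mask: Volume3D | None = None,
) -> nx.MultiGraph:
    """Convert a thin skeleton into a vertex/chain multigraph.

    Vertices are end (degree 1), junction (degree >= 3) and isolated
    voxels; degree-2 voxels form the chain interiors.  Radius annotations
    come from the Euclidean distance transform of ``mask`` (the
    pre-skeleton extracted volume) or, failing that, of the
    supra-threshold mask in ``field``.  Cycles are permitted here.
    """
    sk = np.asarray(skel.data) > 0.5
    if not sk.any():
        raise ValidationError("empty skeleton")

    if mask is not None:
        radius_src = np.asarray(mask.data) > 0.5
    elif field is not None:
        radius_src = field.supra_mask
    else:
        radius_src = sk
    edt = ndimage.distance_transform_edt(radius_src, sampling=skel.spacing)
    cost = field.cost if field is not None else np.zeros(sk.shape)

    voxels = set(map(tuple, np.argwhere(sk)))

    def neighbors(v: tuple[int, int, int]) -> list[tuple[int, int, int]]:
        out = []
        for o in _NEIGH26:
            n = (v[0] + o[0], v[1] + o[1], v[2] + o[2])
            if n in voxels:
                out.append(n)
        return out

    degree = {v: len(neighbors(v)) for v in voxels}
    vertices = {v for v, d in degree.items() if d != 2}
    if not vertices:  # pure cycle: promote an arbitrary voxel to a vertex
        vertices = {next(iter(sorted(voxels)))}

    g = nx.MultiGraph()
    spacing = np.array(skel.spacing)
    for v in vertices:
        g.add_node(
            v,
            pos=skel.voxel_to_physical(np.array(v, dtype=float)),
            radius=float(edt[v]),
        )

    def step_len(a, b) -> float:
        d = (np.array(a) - np.array(b)) * spacing
        return float(np.linalg.norm(d))

    visited_steps: set[frozenset] = set()

    def walk(start, first):
        chain = [start, first]
        prev, cur = start, first
        while cur not in vertices:
            nbs = [n for n in neighbors(cur) if n != prev]
            if len(nbs) != 1:
                break  # defensive: treat as chain end
            prev, cur = cur, nbs[0]
            chain.append(cur)
        return chain

    for v in sorted(vertices):
        for first in neighbors(v):
            key = frozenset((v, first))
            if first in vertices and key in visited_steps:
                continue
            chain = walk(v, first)
            end = chain[-1]
            if end in vertices:
                # avoid adding each vertex-vertex chain twice
                step_keys = [frozenset((chain[0], chain[1])), frozenset((chain[-2], chain[-1]))]
                if any(k in visited_steps for k in step_keys):
                    continue
                for k in step_keys:
                    visited_steps.add(k)
            length = sum(step_len(a, b) for a, b in zip(chain[:-1], chain[1:]))
            weight = sum(
                ((cost[a] + cost[b]) / 2.0 + 0.01) * step_len(a, b)
                for a, b in zip(chain[:-1], chain[1:])
            )
            g.add_edge(
                v,
                end,
                chain=chain,
                length=length,
                weight=weight,
                mean_cost=float(np.mean([cost[c] for c in chain])),
                radii=[float(edt[c]) for c in chain],
            )
            if end not in g.nodes or "pos" not in g.nodes[end]:
                g.add_node(
                    end,
                    pos=skel.voxel_to_physical(np.array(end, dtype=float)),
                    radius=float(edt[end]),
                )
    # annotate the volume metadata for downstream position mapping
    g.graph["spacing"] = skel.spacing
    g.graph["origin"] = skel.origin
    return g


def nearest_vertex(g: nx.MultiGraph, voxel: tuple[int, int, int]) -> tuple[int, int, int]:
    """Skeleton vertex closest (in index space) to the given voxel."""
    vs = list(g.nodes)
    d = [sum((a - b) ** 2 for a, b in zip(v, voxel)) for v in vs]
    return vs[int(np.argmin(d))]


def prune_short_spurs(
    g: nx.MultiGraph, keep: set, factor: float = 2.0, min_length_mm: float = 3.0
) -> nx.MultiGraph:
    """Iteratively drop terminal chains shorter than ``factor`` x the local
    radius at their junction (plus one voxel diagonal), and never shorter
    than ``min_length_mm`` — the stubble that thinning leaves on thick or
    noise-roughened tubes; real lateral roots are longer than a few
    voxels.  Vertices in ``keep`` are never removed."""
    g = g.copy()
    diag = float(np.linalg.norm(g.graph.get("spacing", (1.0, 1.0, 1.0))))
    changed = True
    while changed:
        changed = False
        for v in list(g.nodes):
            if v not in g or v in keep or g.degree(v) != 1:
                continue
            (a, b, key, data) = next(iter(g.edges(v, keys=True, data=True)))
            other = b if a == v else a
            if other == v:  # self loop
                continue
            if g.degree(other) < 3 and other not in keep:
                continue  # only prune off junctions to avoid eating real roots
            thresh = max(factor * g.nodes[other].get("radius", 0.0) + diag, min_length_mm)
            if data["length"] < thresh:
                g.remove_edge(a, b, key)
                g.remove_node(v)
                changed = True
    # merge degree-2 vertices created by pruning
    _merge_degree2(g, keep)
    return g


def _merge_degree2(g: nx.MultiGraph, keep: set) -> None:
    changed = True
    while changed:
        changed = False
        for v in list(g.nodes):
            if v not in g or v in keep or g.degree(v) != 2:
                continue
            edges = list(g.edges(v, keys=True, data=True))
            if len(edges) != 2:
                continue  # self-loop at v
            (a1, b1, k1, d1), (a2, b2, k2, d2) = edges
            n1 = b1 if a1 == v else a1
            n2 = b2 if a2 == v else a2
            if n1 == v or n2 == v:
                continue
            c1 = d1["chain"] if d1["chain"][-1] == v else d1["chain"][::-1]
            c2 = d2["chain"] if d2["chain"][0] == v else d2["chain"][::-1]
            merged = c1 + c2[1:]
            r1 = d1["radii"] if d1["chain"][-1] == v else d1["radii"][::-1]
            r2 = d2["radii"] if d2["chain"][0] == v else d2["radii"][::-1]
            g.remove_edge(a1, b1, k1)
            g.remove_edge(a2, b2, k2)
            g.remove_node(v)
            g.add_edge(
                n1,
                n2,
                chain=merged,
                length=d1["length"] + d2["length"],
                weight=d1["weight"] + d2["weight"],
                mean_cost=(d1["mean_cost"] + d2["mean_cost"]) / 2.0,
                radii=r1 + r2[1:],
            )
            changed = True


def _oriented(data: dict, src) -> tuple[list, list]:
    chain, radii = data["chain"], data["radii"]
    if chain[0] == src:
        return chain, radii
    return chain[::-1], radii[::-1]


def _direction(chain: list, spacing: np.ndarray, n: int = 3) -> np.ndarray:
    a = np.array(chain[0], dtype=float) * spacing
    b = np.array(chain[min(n, len(chain) - 1)], dtype=float) * spacing
    d = b - a
    nrm = np.linalg.norm(d)
    return d / nrm if nrm > 0 else d


def extract_root_system(
    g: nx.MultiGraph,
    collar_vertex: tuple[int, int, int],
    plant_age_days: float = 10.0,
    smooth: bool = False,
    prune: bool = True,
) -> RootSystem:
    """Derive a rooted, ordered RootSystem from a skeleton graph.

    Cycle breaking: minimum total edge cost spanning tree (edge cost =
    accumulated Dijkstra edge weights along the chain).  Tap selection:
    the collar-to-leaf path reaching the minimum z coordinate, ties
    broken by greater path length.  Branch grouping: straightest
    continuation extends the current root; other children start laterals
    of order + 1.
    """
    if collar_vertex not in g.nodes:
        raise ValidationError(f"collar vertex {collar_vertex} not in skeleton graph")
    if prune:
        g = prune_short_spurs(g, keep={collar_vertex})
    spacing = np.array(g.graph.get("spacing", (1.0, 1.0, 1.0)))

    # 1. cycle breaking
    tree = nx.MultiGraph()
    tree.add_nodes_from(g.nodes(data=True))
    tree.graph.update(g.graph)
    for u, v, key, data in nx.minimum_spanning_edges(g, weight="weight", keys=True, data=True):
        tree.add_edge(u, v, key=key, **data)
    tree.remove_nodes_from(list(nx.isolates(tree)))
    if prune:
        # breaking a cycle leaves half of it dangling as a false branch;
        # prune those remnants off the tree as well
        tree = prune_short_spurs(tree, keep={collar_vertex})

    # helper: physical position of a voxel
    origin = g.graph.get("origin", (0.0, 0.0, 0.0))
    vol = Volume3D(np.zeros((1, 1, 1)), tuple(spacing), tuple(origin))

    def pos_of(voxel) -> tuple[float, float, float]:
        return tuple(vol.voxel_to_physical(np.array(voxel, dtype=float)))

    # 2. tap selection: DFS to find per-leaf (min z along path, path length)
    best = {"leaf": None, "minz": np.inf, "length": -1.0, "path": []}

    def dfs_tap(v, incoming_key, minz, length, path):
        z = pos_of(v)[2]
        minz = min(minz, z)
        out_edges = [
            (u, w, k, d)
            for u, w, k, d in tree.edges(v, keys=True, data=True)
            if (u, w, k) != incoming_key and (w, u, k) != incoming_key
        ]
        if not out_edges:
            if (minz < best["minz"] - 1e-9) or (
                abs(minz - best["minz"]) <= 1e-9 and length > best["length"]
            ):
                best.update(leaf=v, minz=minz, length=length, path=list(path))
            return
        for u, w, k, d in out_edges:
            nxt = w if u == v else u
            if nxt == v:
                continue
            path.append((v, nxt, k))
            dfs_tap(nxt, (u, w, k), minz, length + d["length"], path)
            path.pop()

    import sys

    old_limit = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old_limit, 10000))
    try:
        dfs_tap(collar_vertex, None, np.inf, 0.0, [])
        tap_edges = {(a, b, k) for a, b, k in best["path"]}
        tap_edges |= {(b, a, k) for a, b, k in best["path"]}

        # 3. walk the tree building roots
        roots: list[Root] = []

        def make_nodes(chain, radii):
            return [RootNode(pos_of(c), r) for c, r in zip(chain, radii)]

        def grow_root(
            start_vertex,
            incoming_key,
            order: int,
            parent: Root | None,
            parent_idx: int | None,
            seed_nodes: list[RootNode],
            seed_dir: np.ndarray | None,
            on_tap: bool,
        ):
            nodes = list(seed_nodes)
            root = Root(nodes, order=order, parent=parent, parent_node_index=parent_idx)
            roots.append(root)
            v = start_vertex
            inc_key = incoming_key
            inc_dir = seed_dir
            while True:
                out_edges = []
                for a, b, k, d in tree.edges(v, keys=True, data=True):
                    if (a, b, k) == inc_key or (b, a, k) == inc_key:
                        continue
                    out_edges.append((a, b, k, d))
                if not out_edges:
                    break
                # choose continuation
                def child_dir(e):
                    a, b, k, d = e
                    chain, _ = _oriented(d, v)
                    return _direction(chain, spacing)

                if on_tap:
                    cont = next(
                        (e for e in out_edges if (e[0], e[1], e[2]) in tap_edges), None
                    )
                    if cont is None:
                        cont = max(
                            out_edges,
                            key=lambda e: float(np.dot(inc_dir, child_dir(e)))
                            if inc_dir is not None
                            else -e[3]["mean_cost"],
                        )
                else:
                    cont = max(
                        out_edges,
                        key=lambda e: float(np.dot(inc_dir, child_dir(e)))
                        if inc_dir is not None
                        else -e[3]["mean_cost"],
                    )
                attach_idx = len(root.nodes) - 1
                for e in out_edges:
                    if e is cont:
                        continue
                    a, b, k, d = e
                    nxt = b if a == v else a
                    chain, radii = _oriented(d, v)
                    child_seed = make_nodes(chain, radii)
                    grow_root(
                        nxt,
                        (a, b, k),
                        order + 1,
                        root,
                        attach_idx,
                        child_seed,
                        _chain_end_dir(chain, spacing),
                        False,
                    )
                a, b, k, d = cont
                nxt = b if a == v else a
                chain, radii = _oriented(d, v)
                root.nodes.extend(make_nodes(chain[1:], radii[1:]))
                inc_dir = _chain_end_dir(chain, spacing)
                inc_key = (a, b, k)
                v = nxt

        grow_root(collar_vertex, None, 0, None, None,
                  [RootNode(pos_of(collar_vertex), g.nodes[collar_vertex].get("radius", 0.0))],
                  None, True)
    finally:
        sys.setrecursionlimit(old_limit)

    # drop degenerate stubs (single-node laterals)
    kept = [r for r in roots if len(r.nodes) >= 2]
    dropped = {id(r) for r in roots if len(r.nodes) < 2}
    for r in kept:
        while r.parent is not None and id(r.parent) in dropped:
            r.parent = r.parent.parent  # reattach upward (rare)
    if smooth:
        for r in kept:
            _smooth_positions(r)
    rs = RootSystem(kept, plant_age_days=plant_age_days, label="traced")
    rs.validate()
    return rs


def _chain_end_dir(chain: list, spacing: np.ndarray, n: int = 3) -> np.ndarray:
    a = np.array(chain[max(0, len(chain) - 1 - n)], dtype=float) * spacing
    b = np.array(chain[-1], dtype=float) * spacing
    d = b - a
    nrm = np.linalg.norm(d)
    return d / nrm if nrm > 0 else d


def _smooth_positions(root: Root, window: int = 3) -> None:
    """In-place moving-average smoothing of interior node positions."""
    p = root.positions()
    if len(p) <= 2:
        return
    sm = p.copy()
    sm[1:-1] = (p[:-2] + p[1:-1] + p[2:]) / 3.0
    for node, q in zip(root.nodes, sm):
        node.position = tuple(q)
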