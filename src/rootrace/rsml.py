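"""Reading and writing Root System Markup Language (RSML) files.

RSML is the XML interchange format used across root phenotyping tools:
a ``scene`` contains ``plant`` elements, each a nesting of ``root``
elements carrying a polyline ``geometry`` and per-node ``functions``
(here: ``diameter``).  One scene with one plant is assumed; root order is
recomputed from nesting depth on read.  Units are converted to mm
internally, honoring the metadata ``unit`` element (cm, mm, or pixel
together with ``resolution``).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
from lxml import etree

from .errors import FormatError, StructureError, ValidationError
from .rootsystem import Root, RootNode, RootSystem

__all__ = ["read_rsml", "write_rsml"]

_UNIT_TO_MM = {"mm": 1.0, "cm": 10.0, "m": 1000.0, "um": 1e-3, "inch": 25.4}


def _unit_factor(metadata: etree._Element | None) -> float:
    """mm per RSML coordinate unit."""
    if metadata is None:
        return 1.0
    unit = metadata.findtext("unit", default="mm").strip().lower()
    res_text = metadata.findtext("resolution", default="1")
    try:
        resolution = float(res_text)
    except ValueError:
        resolution = 1.0
    if unit in ("pixel", "pixels", "voxel"):
        # resolution = pixels per mm in most emitters; guard against zero
        return 1.0 / resolution if resolution > 0 else 1.0
    if unit not in _UNIT_TO_MM:
        raise FormatError(f"unsupported RSML unit: {unit!r}")
    return _UNIT_TO_MM[unit]


def _parse_polyline(root_el: etree._Element, factor: float) -> list[tuple[float, float, float]]:
    poly = root_el.find("./geometry/polyline")
    if poly is None:
        raise FormatError("RSML root element without geometry/polyline")
    pts = []
    for pt in poly.findall("point"):
        try:
            x = float(pt.get("x", "nan")) * factor
            y = float(pt.get("y", "nan")) * factor
            z = float(pt.get("z", "0")) * factor
        except ValueError as exc:
            raise FormatError(f"bad point coordinates: {pt.attrib}") from exc
        if not all(np.isfinite((x, y, z))):
            raise FormatError(f"non-finite point coordinates: {pt.attrib}")
        pts.append((x, y, z))
    if len(pts) < 2:
        raise FormatError("RSML polyline with fewer than 2 points")
    return pts


def _parse_radii(root_el: etree._Element, n: int, factor: float) -> list[float]:
    for fn in root_el.findall("./functions/function"):
        name = (fn.get("name") or "").lower()
        if name in ("diameter", "radius"):
            vals = [float(s.get("value", s.text or "0")) for s in fn.findall("sample")]
            if len(vals) != n:
                raise FormatError(
                    f"function {name!r} has {len(vals)} samples for {n} nodes"
                )
            scale = 0.5 if name == "diameter" else 1.0
            return [v * factor * scale for v in vals]
    return [0.0] * n


def read_rsml(path: str | Path) -> RootSystem:
    """Parse an RSML file into a validated :class:`RootSystem`."""
    try:
        tree = etree.parse(str(path))
    except (etree.XMLSyntaxError, OSError) as exc:
        raise FormatError(f"cannot parse RSML file {path}: {exc}") from exc
    rsml = tree.getroot()
    factor = _unit_factor(rsml.find("metadata"))
    plant = rsml.find(".//scene/plant")
    if plant is None:
        plant = rsml.find(".//plant")
    if plant is None:
        raise FormatError(f"{path}: no plant element found")

    roots: list[Root] = []
    by_id: dict[str, Root] = {}
    deferred: list[tuple[Root, str]] = []  # flat roots with a parent-id attribute

    def walk(el: etree._Element, parent: Root | None, depth: int) -> None:
        pts = _parse_polyline(el, factor)
        radii = _parse_radii(el, len(pts), factor)
        root = Root(
            nodes=[RootNode(p, r) for p, r in zip(pts, radii)],
            order=depth,
            parent=parent,
        )
        rid = el.get("ID") or el.get("id")
        if rid is not None:
            by_id[rid] = root
        pid = el.get("parent") or el.get("parent_id")
        if parent is None and pid is not None:
            deferred.append((root, pid))
        roots.append(root)
        for child in el.findall("root"):
            walk(child, root, depth + 1)

    for top in plant.findall("root"):
        walk(top, None, 0)

    for root, pid in deferred:
        target = by_id.get(pid)
        if target is None:
            raise StructureError(f"root references non-existent parent id {pid!r}")
        cur: Root | None = target
        while cur is not None:
            if cur is root:
                raise StructureError(f"cyclic parent reference at id {pid!r}")
            cur = cur.parent
        root.parent = target

    # recompute orders from resolved parent links (nesting depth)
    def order_of(r: Root) -> int:
        o, cur = 0, r
        while cur.parent is not None:
            cur = cur.parent
            o += 1
            if o > len(roots):
                raise StructureError("cyclic root structure")
        return o

    for r in roots:
        r.order = order_of(r)
        if r.parent is not None:
            d = np.linalg.norm(
                r.parent.positions() - np.array(r.nodes[0].position), axis=1
            )
            r.parent_node_index = int(np.argmin(d))

    taps = [r for r in roots if r.parent is None]
    if len(taps) != 1:
        raise StructureError(f"expected one top-level root, found {len(taps)}")

    age = plant.get("age")
    rs = RootSystem(
        roots,
        plant_age_days=float(age) if age else 10.0,
        label=plant.get("label") or "",
    )
    rs.validate()
    return rs


def write_rsml(rs: RootSystem, path: str | Path) -> None:
    """Serialize a RootSystem to RSML (one scene, one plant, unit mm).

    Per-node radii are stored in the conventional ``diameter`` polyline
    function (values = 2x radius); laterals are nested inside their parent.
    """
    rs.validate()
    rsml = etree.Element("rsml")
    meta = etree.SubElement(rsml, "metadata")
    etree.SubElement(meta, "version").text = "1"
    etree.SubElement(meta, "unit").text = "mm"
    etree.SubElement(meta, "resolution").text = "1"
    etree.SubElement(meta, "software").text = "rootrace"
    scene = etree.SubElement(rsml, "scene")
    plant = etree.SubElement(scene, "plant", id="1")
    if rs.label:
        plant.set("label", rs.label)
    plant.set("age", repr(float(rs.plant_age_days)))

    ids: dict[int, str] = {}

    def emit(root: Root, parent_el: etree._Element) -> None:
        rid = str(len(ids) + 1)
        ids[id(root)] = rid
        el = etree.SubElement(parent_el, "root", ID=rid)
        geom = etree.SubElement(el, "geometry")
        poly = etree.SubElement(geom, "polyline")
        for n in root.nodes:
            x, y, z = n.position
            etree.SubElement(poly, "point", x=repr(x), y=repr(y), z=repr(z))
        fns = etree.SubElement(el, "functions")
        fn = etree.SubElement(fns, "function", name="diameter", domain="polyline")
        for n in root.nodes:
            etree.SubElement(fn, "sample", value=repr(2.0 * n.radius))
        for child in sorted(
            (r for r in rs.roots if r.parent is root),
            key=lambda r: (r.parent_node_index or 0),
        ):
            emit(child, el)

    emit(rs.tap, plant)
    tree = etree.ElementTree(rsml)
    tree.write(str(path), pretty_print=True, xml_declaration=True, encoding="UTF-8")
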