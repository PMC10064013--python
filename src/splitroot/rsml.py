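"""RSML 1.0 export/import of root architectures, plus OBJ export.

The Root System Markup Language is the community XML standard for
exchanging root architecture data: a scene of plants whose roots nest to
encode topology, each root carrying a polyline, per-root properties and
per-node functions.  This writer stores coordinates in cm to six decimal
places, keeps every realised growth parameter as a root property, and a
constant diameter function per root.  ``write → read → write`` is
byte-identical, which is how seeded runs prove reproducibility by hash.

Re-imported systems are measurement-ready (trait tables, summaries,
re-export) but carry no random state, so they cannot be grown further.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
from lxml import etree

from . import __version__
from .rsa import BOX_DIMS, RootAxis, RootSystem

__all__ = ["RSMLError", "write_rsml", "read_rsml", "write_obj"]


class RSMLError(ValueError):
    """Malformed or unsupported RSML input."""


_FLOAT_PROPS = ("birth_time", "axial_angle", "radial_angle", "r", "lmax",
                "ln", "radius", "linear_density")


def _fmt(x: float) -> str:
    return f"{x:.6f}"


def _root_element(system: RootSystem, axis: RootAxis,
                  children: dict[int, list[RootAxis]]) -> etree._Element:
    el = etree.Element("root", ID=str(axis.axis_id),
                       label=f"root {axis.axis_id}")
    props = etree.SubElement(el, "properties")

    def prop(name, value):
        etree.SubElement(props, "property", name=name, value=value)

    prop("branching_number", str(axis.branching_number))
    if axis.insertion_arclength is not None:
        prop("insertion_arclength", repr(float(axis.insertion_arclength)))
    for name in _FLOAT_PROPS:
        prop(name, repr(float(getattr(axis, name))))
    prop("growth_law", axis.growth_law)
    geom = etree.SubElement(el, "geometry")
    poly = etree.SubElement(geom, "polyline")
    pts = axis.polyline
    for x, y, z in pts:
        etree.SubElement(poly, "point", x=_fmt(x), y=_fmt(y), z=_fmt(z))
    funcs = etree.SubElement(el, "functions")
    diam = etree.SubElement(funcs, "function", name="diameter",
                            domain="polyline")
    for _ in range(len(pts)):
        etree.SubElement(diam, "sample", value=repr(2 * float(axis.radius)))
    for child in children.get(axis.axis_id, ()):
        el.append(_root_element(system, child, children))
    return el


def write_rsml(system: RootSystem, path: str | Path | None = None) -> bytes:
    """Serialise a root system to RSML 1.0; returns the document bytes."""
    rsml = etree.Element("rsml", version="1.0")
    meta = etree.SubElement(rsml, "metadata")
    etree.SubElement(meta, "version").text = "1"
    etree.SubElement(meta, "unit").text = "cm"
    etree.SubElement(meta, "resolution").text = "1"
    etree.SubElement(meta, "software").text = f"splitroot {__version__}"
    scene = etree.SubElement(rsml, "scene")
    sprops = etree.SubElement(scene, "properties")

    def sprop(name, value):
        etree.SubElement(sprops, "property", name=name, value=value)

    sprop("clock", repr(float(system.clock)))
    sprop("compartment", system.compartment_tag)
    sprop("side", str(system.side))
    sprop("box_dims", " ".join(repr(float(d)) for d in system.box_dims))
    sprop("barrier_top_depth", repr(float(system.barrier_top_depth)))
    plant = etree.SubElement(scene, "plant", id="1", label="plant 1")
    children: dict[int, list[RootAxis]] = {}
    for a in system.axes:
        if a.parent_id is not None:
            children.setdefault(a.parent_id, []).append(a)
    for lst in children.values():
        lst.sort(key=lambda a: a.axis_id)
    for a in system.axes:
        if a.parent_id is None:
            plant.append(_root_element(system, a, children))
    blob = etree.tostring(rsml, xml_declaration=True, encoding="UTF-8",
                          pretty_print=True)
    if path is not None:
        Path(path).write_bytes(blob)
    return blob


def _parse_root(el, parent_id, axes, clock):
    try:
        axis_id = int(el.get("ID"))
    except (TypeError, ValueError):
        raise RSMLError(
            f"root element without integer ID at line {el.sourceline}")
    props = {p.get("name"): p.get("value")
             for p in el.findall("properties/property")}
    pts = [(float(p.get("x")), float(p.get("y")), float(p.get("z")))
           for p in el.findall("geometry/polyline/point")]
    if len(pts) < 2:
        raise RSMLError(f"root {axis_id}: polyline needs >= 2 points "
                        f"(line {el.sourceline})")
    points = np.asarray(pts)
    cumlen = np.concatenate(
        [[0.0], np.cumsum(np.linalg.norm(np.diff(points, axis=0), axis=1))])
    try:
        kwargs = {name: float(props[name]) for name in _FLOAT_PROPS}
        bn = int(props["branching_number"])
    except KeyError as e:
        raise RSMLError(f"root {axis_id}: missing property {e} "
                        f"(line {el.sourceline})") from None
    ins = props.get("insertion_arclength")
    axis = RootAxis(
        axis_id=axis_id, branching_number=bn, parent_id=parent_id,
        insertion_arclength=None if ins is None else float(ins),
        axial_angle=kwargs.pop("axial_angle"),
        radial_angle=kwargs.pop("radial_angle"),
        birth_time=kwargs.pop("birth_time"),
        r=kwargs.pop("r"), lmax=kwargs.pop("lmax"), ln=kwargs.pop("ln"),
        radius=kwargs.pop("radius"),
        linear_density=kwargs.pop("linear_density"),
        growth_law=props.get("growth_law", "linear"),
        static=True, _points=points, _cumlen=cumlen)
    axes.append(axis)
    for child in el.findall("root"):
        _parse_root(child, axis_id, axes, clock)


def read_rsml(source: str | Path | bytes) -> RootSystem:
    """Parse an RSML document back into a (static) root system."""
    try:
        if isinstance(source, bytes):
            rsml = etree.fromstring(source)
        else:
            rsml = etree.parse(str(source)).getroot()
    except etree.XMLSyntaxError as e:
        raise RSMLError(f"malformed XML: {e}") from None
    if rsml.tag != "rsml":
        raise RSMLError(f"not an RSML document (root tag {rsml.tag!r})")
    version = rsml.findtext("metadata/version")
    if version not in ("1", "1.0", None):
        raise RSMLError(f"unsupported RSML schema version {version!r}")
    sprops = {p.get("name"): p.get("value")
              for p in rsml.findall("scene/properties/property")}
    system = object.__new__(RootSystem)
    system.box_dims = tuple(
        float(v) for v in sprops.get(
            "box_dims", " ".join(str(d) for d in BOX_DIMS)).split())
    system.barrier_top_depth = float(sprops.get("barrier_top_depth", 1.0))
    system.side = int(sprops.get("side", 1))
    system.compartment_tag = sprops.get("compartment", "")
    system.clock = float(sprops.get("clock", 0.0))
    system.seed = None
    system.params_by_order = {}
    system.axes = []
    system._heap = []
    system._seq = 0
    system._rng = None
    system.origin = None
    for plant in rsml.findall("scene/plant"):
        for root_el in plant.findall("root"):
            _parse_root(root_el, None, system.axes, system.clock)
    system.axes.sort(key=lambda a: a.axis_id)
    for a in system.axes:
        a._system = system
    return system


def write_obj(system: RootSystem, path: str | Path) -> None:
    """Wavefront OBJ export of the current polylines, for 3D inspection.

    Each axis becomes one polyline object; coordinates are written with z
    negated so that depth renders downward in y-up viewers.
    """
    lines = [f"# splitroot {__version__} root system export",
             f"# {len(system.axes)} axes, clock {system.clock} d"]
    offset = 1
    for a in system.axes:
        pts = a.polyline
        lines.append(f"o root_{a.axis_id}_bn{a.branching_number}")
        for x, y, z in pts:
            lines.append(f"v {x:.4f} {-z:.4f} {y:.4f}")
        idx = " ".join(str(offset + i) for i in range(len(pts)))
        lines.append(f"l {idx}")
        offset += len(pts)
    Path(path).write_text("\n".join(lines) + "\n")
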