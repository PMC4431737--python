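"""Circular-dendrogram layout and SVG output for the Functional Tree.

Visible leaves are spaced evenly around the circle in the tree's
deterministic child order (angular origin at 12 o'clock, clockwise by
default); every internal node sits on its layer's ring at the mean angle of
its children.  The hidden Undefined subtree is never laid out.  Mapped
values become circles whose radius encodes the value either linearly
(``radius`` normalization) or with the circle *area* linear in the value
(``area`` normalization), clamped to [r_min, r_max].
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping
from xml.etree import ElementTree as ET

from .errors import RenderError
from .hierarchy import FunctionalTree

DEFAULT_LAYER_RADII = {
    "root": 0.0,
    "biological_category": 70.0,
    "biological_process": 140.0,
    "pathway": 210.0,
    "module": 280.0,
    "ko": 350.0,
}


@dataclass(frozen=True)
class RenderSpec:
    """Normalization mode, radius bounds and ring/styling defaults."""

    normalization: str = "radius"
    r_min: float = 2.0
    r_max: float = 14.0
    layer_radii: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_LAYER_RADII))
    default_color: str = "#1f77b4"
    default_opacity: float = 0.8
    ring_color: str = "#f0f0f0"
    edge_color: str = "#bbbbbb"
    draw_rings: bool = True
    straight_edges: bool = False
    clockwise: bool = True
    center_on: str | None = None
    margin: float = 20.0

    def validate(self) -> None:
        if self.normalization not in ("radius", "area"):
            raise RenderError("normalization must be 'radius' or 'area'")
        if not 0 <= self.r_min < self.r_max:
            raise RenderError("need 0 <= r_min < r_max")
        radii = [self.layer_radii[l] for l in
                 ("root", "biological_category", "biological_process",
                  "pathway", "module", "ko")]
        if any(b <= a for a, b in zip(radii, radii[1:])):
            raise RenderError("layer radii must strictly increase from root outward")


@dataclass(frozen=True)
class LayoutNode:
    """Polar and Cartesian position of one visible placement."""

    placement_id: str
    angle: float  # radians in [0, 2*pi), from 12 o'clock
    radius: float
    x: float
    y: float


def _resolve_center(tree: FunctionalTree, center_on: str) -> str:
    if center_on in tree.nodes:
        return center_on
    placements = tree.by_function.get(center_on)
    if not placements:
        raise RenderError("center_on id %r not in the tree" % center_on)
    if len(placements) > 1:
        raise RenderError(
            "center_on function %r has %d placements; pass a placement id (one of %s)"
            % (center_on, len(placements), ", ".join(sorted(placements))))
    return next(iter(placements))


def layout(tree: FunctionalTree, spec: RenderSpec) -> list[LayoutNode]:
    """Position every visible placement (of the chosen subtree) on its ring."""
    spec.validate()
    start = _resolve_center(tree, spec.center_on) if spec.center_on else tree.root
    if tree.nodes[start].hidden:
        raise RenderError("cannot center on a hidden placement: %r" % start)

    leaves: list[str] = []

    def collect(pid: str) -> None:
        node = tree.nodes[pid]
        visible_children = [c for c in node.children if not tree.nodes[c].hidden]
        if not visible_children:
            leaves.append(pid)
        for c in visible_children:
            collect(c)

    collect(start)
    if not leaves:
        raise RenderError("no visible leaves under %r" % start)
    step = 2.0 * math.pi / len(leaves)
    angles: dict[str, float] = {pid: i * step for i, pid in enumerate(leaves)}

    def assign(pid: str) -> float:
        if pid in angles:
            return angles[pid]
        node = tree.nodes[pid]
        child_angles = [assign(c) for c in node.children if not tree.nodes[c].hidden]
        angles[pid] = sum(child_angles) / len(child_angles)
        return angles[pid]

    assign(start)
    extent = max(self_r for self_r in spec.layer_radii.values()) + spec.r_max + spec.margin
    out = []
    for pid in sorted(angles):
        node = tree.nodes[pid]
        theta = angles[pid] if spec.clockwise else (-angles[pid]) % (2.0 * math.pi)
        r = spec.layer_radii[node.layer]
        out.append(LayoutNode(
            placement_id=pid, angle=angles[pid], radius=r,
            x=extent + r * math.sin(theta), y=extent - r * math.cos(theta)))
    return out


def scale_values(values: Mapping[str, float], spec: RenderSpec) -> dict[str, float]:
    """Map positive values onto circle radii in [r_min, r_max].

    ``radius`` normalization maps the value linearly onto the radius;
    ``area`` normalization makes pi r^2 linear in the value over the same
    bounds.  Non-positive or absent values draw nothing and are dropped.
    """
    spec.validate()
    positive = {fid: v for fid, v in values.items() if v > 0.0}
    if not positive:
        raise RenderError("no strictly positive values to scale")
    vmin = min(positive.values())
    vmax = max(positive.values())
    span = vmax - vmin
    out: dict[str, float] = {}
    for fid, v in positive.items():
        t = (v - vmin) / span if span > 0 else 1.0
        if spec.normalization == "radius":
            out[fid] = spec.r_min + t * (spec.r_max - spec.r_min)
        else:
            out[fid] = math.sqrt(spec.r_min ** 2 + t * (spec.r_max ** 2 - spec.r_min ** 2))
    return out


def _fmt(x: float) -> str:
    return "%.3f" % x


def render_svg(tree: FunctionalTree, nodes: list[LayoutNode],
               radii: Mapping[str, float], spec: RenderSpec,
               styles: Mapping[str, tuple[str | None, float | None]] | None = None,
               ) -> str:
    """Emit the dendrogram plus one value circle per positive-valued visible
    placement, as a deterministic standalone SVG 1.1 document.

    ``radii`` is keyed by function id (from scale_values); ``styles`` may
    override (color, opacity) per function id.
    """
    spec.validate()
    styles = styles or {}
    pos = {n.placement_id: n for n in nodes}
    extent = max(spec.layer_radii.values()) + spec.r_max + spec.margin
    side = 2.0 * extent
    svg = ET.Element("svg", {
        "xmlns": "http://www.w3.org/2000/svg",
        "version": "1.1",
        "width": _fmt(side), "height": _fmt(side),
        "viewBox": "0 0 %s %s" % (_fmt(side), _fmt(side)),
    })

    if spec.draw_rings:
        rings = ET.SubElement(svg, "g", {"class": "rings", "fill": "none",
                                         "stroke": spec.ring_color})
        for layer in ("biological_category", "biological_process",
                      "pathway", "module", "ko"):
            ET.SubElement(rings, "circle", {
                "cx": _fmt(extent), "cy": _fmt(extent),
                "r": _fmt(spec.layer_radii[layer])})

    edges = ET.SubElement(svg, "g", {"class": "edges", "fill": "none",
                                     "stroke": spec.edge_color})
    for pid in sorted(pos):
        node = tree.nodes[pid]
        for cid in node.children:
            if cid not in pos:
                continue
            p, c = pos[pid], pos[cid]
            if spec.straight_edges or p.radius == 0.0:
                d = "M %s %s L %s %s" % (_fmt(p.x), _fmt(p.y), _fmt(c.x), _fmt(c.y))
            else:
                # arc along the parent ring to the child's angle, then radial
                theta_c = c.angle if spec.clockwise else (-c.angle) % (2 * math.pi)
                mx = extent + p.radius * math.sin(theta_c)
                my = extent - p.radius * math.cos(theta_c)
                cw_screen = (c.angle > p.angle) == spec.clockwise
                d = "M %s %s A %s %s 0 0 %d %s %s L %s %s" % (
                    _fmt(p.x), _fmt(p.y), _fmt(p.radius), _fmt(p.radius),
                    1 if cw_screen else 0, _fmt(mx), _fmt(my), _fmt(c.x), _fmt(c.y))
            ET.SubElement(edges, "path", {"d": d})

    circles = ET.SubElement(svg, "g", {"class": "values"})
    for pid in sorted(pos):
        node = tree.nodes[pid]
        r = radii.get(node.function_id)
        if r is None or r <= 0.0:
            continue
        color, opacity = styles.get(node.function_id, (None, None))
        ET.SubElement(circles, "circle", {
            "cx": _fmt(pos[pid].x), "cy": _fmt(pos[pid].y), "r": _fmt(r),
            "fill": color or spec.default_color,
            "fill-opacity": _fmt(opacity if opacity is not None
                                 else spec.default_opacity),
            "data-function": node.function_id,
        })

    body = ET.tostring(svg, encoding="unicode")
    return '<?xml version="1.0" encoding="UTF-8"?>\n' + body + "\n"
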