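"""SVG rendering of the Edgeworth box.

The figure shows the box (h by w*), both optimality lines, the trade
line through the shared specialization corner S = (0, h), the autarky
points, and the equilibrium E where the three rays intersect.  All
geometry is drawn in *model coordinates* inside a single group whose
transform flips the y-axis, so the line endpoints in the SVG source can
be read back directly as model values (the test-suite round-trips them).
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from typing import Mapping, Optional

from .conditions import ExchangeRegime
from .equilibrium import EquilibriumAllocation
from .stoichiometry import Uptake

_SVG_NS = "http://www.w3.org/2000/svg"

_STYLES = {
    "box": ("#333333", "1", "none"),
    "optimality_legume": ("#1b7837", "1", "4 2"),
    "optimality_rhizobium": ("#762a83", "1", "4 2"),
    "trade": ("#d73027", "1.5", "none"),
}


def _line(parent, x1, y1, x2, y2, role, scale):
    colour, width, dash = _STYLES.get(role, ("#888888", "1", "none"))
    el = ET.SubElement(parent, f"{{{_SVG_NS}}}line")
    el.set("x1", f"{x1 * scale:.9g}")
    el.set("y1", f"{y1 * scale:.9g}")
    el.set("x2", f"{x2 * scale:.9g}")
    el.set("y2", f"{y2 * scale:.9g}")
    el.set("stroke", colour)
    el.set("stroke-width", width)
    if dash != "none":
        el.set("stroke-dasharray", dash)
    el.set("vector-effect", "non-scaling-stroke")
    el.set("data-role", role)
    # model-space coordinates, exactly recoverable by a parser
    el.set("data-model", f"{x1!r},{y1!r},{x2!r},{y2!r}")
    return el


def _point(parent, x, y, role, scale, colour="#000000"):
    el = ET.SubElement(parent, f"{{{_SVG_NS}}}circle")
    el.set("cx", f"{x * scale:.9g}")
    el.set("cy", f"{y * scale:.9g}")
    el.set("r", "0.8")
    el.set("fill", colour)
    el.set("data-role", role)
    el.set("data-model", f"{x!r},{y!r}")
    return el


def render_edgeworth(
    alloc: EquilibriumAllocation,
    autarky_points: Optional[Mapping[str, Uptake]] = None,
    regime: Optional[ExchangeRegime] = None,
    out: Optional[str] = None,
) -> str:
    """Render the box to an SVG string; write it to ``out`` when given.

    ``autarky_points`` may carry ``"legume"`` (legume frame) and
    ``"rhizobium"`` (Rhizobium's own frame; drawn via the affine flip
    ``(w - x_N, h - x_C)``).  A warning annotation is added when the
    allocation carries a feasibility warning or when ``regime`` marks
    the exchange ratio as outside the open feasible interval.
    """
    box = alloc.box
    h, w, r = box.h, box.w, box.r
    # scale so the drawing is ~100 units tall regardless of h
    scale = 100.0 / h

    ET.register_namespace("", _SVG_NS)
    svg = ET.Element(f"{{{_SVG_NS}}}svg")
    margin = 12.0
    width_u, height_u = w * scale, h * scale
    svg.set("viewBox", f"{-margin} {-margin} {width_u + 2 * margin} {height_u + 2 * margin}")
    svg.set("width", f"{width_u + 2 * margin:.6g}")
    svg.set("height", f"{height_u + 2 * margin:.6g}")

    # flip y so the legume origin is bottom-left
    g = ET.SubElement(svg, f"{{{_SVG_NS}}}g")
    g.set("transform", f"translate(0,{height_u:.9g}) scale(1,-1)")

    # box outline
    for (x1, y1, x2, y2) in [(0, 0, w, 0), (w, 0, w, h), (w, h, 0, h), (0, h, 0, 0)]:
        _line(g, x1, y1, x2, y2, "box", scale)

    # rays: legume optimality (origin -> beyond E), rhizobium optimality
    # (top-right origin in the flipped frame), trade line through S=(0,h)
    _line(g, 0.0, 0.0, w, box.c_L * w, "optimality_legume", scale)
    _line(g, w, h, 0.0, h - box.c_R * w, "optimality_rhizobium", scale)
    _line(g, 0.0, h, w, h - r * w, "trade", scale)

    E = alloc.legume_uptake
    _point(g, E.x_N, E.x_C, "equilibrium", scale, colour="#d73027")
    _point(g, 0.0, h, "specialization_corner", scale)

    if autarky_points:
        if "legume" in autarky_points:
            p = autarky_points["legume"]
            _point(g, p.x_N, p.x_C, "autarky_legume", scale, colour="#1b7837")
        if "rhizobium" in autarky_points:
            p = autarky_points["rhizobium"]
            _point(g, w - p.x_N, h - p.x_C, "autarky_rhizobium", scale, colour="#762a83")

    notes = []
    if alloc.feasibility_warning:
        notes.append(alloc.feasibility_warning)
    if regime is not None and not regime.is_feasible():
        lo, hi = regime.interval
        notes.append(f"r={regime.r} at or outside the open interval ({lo}, {hi})")
    if notes:
        warn = ET.SubElement(svg, f"{{{_SVG_NS}}}text")
        warn.set("x", "0")
        warn.set("y", f"{height_u + margin - 2:.6g}")
        warn.set("font-size", "5")
        warn.set("fill", "#b30000")
        warn.set("data-role", "warning")
        warn.text = "; ".join(notes)

    out_str = ET.tostring(svg, encoding="unicode")
    if out is not None:
        with open(out, "w", encoding="utf-8") as fh:
            fh.write(out_str + "\n")
    return out_str
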