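"""Scene composition and SVG output.

Geometry from :mod:`nodeglyphs.glyph_geometry` arrives in unit-box
coordinates.  This module turns it into styled scenes, places up to nine
scenes per node (one per *slot*), and writes the whole network as an
SVG 1.1 document.  Output is deterministic: identical inputs produce
byte-identical SVG, and gradient/clip ids are derived from node id and
slot so diffs of rendered files are meaningful.

Slots are arranged on a 3x3 grid: slot 1 sits at the node centre and
slots 2-9 step clockwise through the compass points (N, NE, E, SE, S,
SW, W, NW), each offset by one node-size unit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from xml.etree import ElementTree as ET

from .errors import CapabilityError, DuplicateSlotError, RangeBoundError, SlotOverflowError
from .glyph_geometry import (
    BarRect,
    LinearPaint,
    Polyline,
    RadialPaint,
    Slice,
    VerticalGradientFill,
)
from .instruction_parser import RGBA

# slot -> (dx, dy) in node-size units; slot 1 = centre, 2-9 clockwise from N
SLOT_OFFSETS = {
    1: (0.0, 0.0),
    2: (0.0, -1.0),
    3: (1.0, -1.0),
    4: (1.0, 0.0),
    5: (1.0, 1.0),
    6: (0.0, 1.0),
    7: (-1.0, 1.0),
    8: (-1.0, 0.0),
    9: (-1.0, -1.0),
}

DEFAULT_FONT = "DejaVu Sans, sans-serif"
KNOWN_FONTS = {"serif", "sans-serif", "monospace", "dejavu sans", "dejavu serif"}


@dataclass(frozen=True)
class LabelStyle:
    font: str = DEFAULT_FONT
    size: float = 8.0
    style: str = "plain"  # italics | bold | bolditalic | plain
    color: RGBA = RGBA(0, 0, 0, 255)

    def __post_init__(self):
        if self.size <= 0:
            raise RangeBoundError("label size must be positive")


@dataclass(frozen=True)
class SlotPlacement:
    slot: int
    offset: tuple[float, float] | None = None  # node-size units; default per slot

    def __post_init__(self):
        if not 1 <= self.slot <= 9:
            raise SlotOverflowError(f"slot {self.slot} outside 1..9")

    @property
    def zorder(self) -> int:
        return self.slot

    def resolved_offset(self) -> tuple[float, float]:
        return self.offset if self.offset is not None else SLOT_OFFSETS[self.slot]


# scene primitives ------------------------------------------------------------

@dataclass(frozen=True)
class RectPrim:
    x0: float
    y0: float
    x1: float
    y1: float
    fill: RGBA | VerticalGradientFill


@dataclass(frozen=True)
class SectorPrim:
    cx: float
    cy: float
    inner: float
    outer: float
    start_angle: float  # degrees, 0 at 12 o'clock, clockwise
    extent: float
    fill: RGBA


@dataclass(frozen=True)
class PolylinePrim:
    points: tuple[tuple[float, float], ...]
    width: float
    color: RGBA


@dataclass(frozen=True)
class TextPrim:
    x: float
    y: float
    text: str
    style: LabelStyle


@dataclass(frozen=True)
class PaintPrim:
    """A gradient paint that fills the whole node shape."""

    paint: LinearPaint | RadialPaint


Primitive = object  # RectPrim | SectorPrim | PolylinePrim | TextPrim | PaintPrim


@dataclass(frozen=True)
class VectorScene:
    primitives: tuple = ()
    scale: float = 1.0  # applied about the scene centre at composition


# ---------------------------------------------------------------------------
# scene building
# ---------------------------------------------------------------------------

def _slice_label_pos(s: Slice) -> tuple[float, float]:
    mid = math.radians(s.start_angle + s.extent / 2.0)
    r = (s.inner_radius + s.outer_radius) / 2.0
    return (0.5 + r * math.sin(mid), 0.5 - r * math.cos(mid))


def _bar_label_pos(b: BarRect) -> tuple[float, float]:
    x = (b.x0 + b.x1) / 2.0
    # above the tip when there is headroom, else just below the bar
    return (x, b.y0 - 0.03) if b.y0 >= 0.08 else (x, b.y1 + 0.06)


def build_scene(
    elements,
    label_style: LabelStyle | None = None,
    showlabels: bool = True,
    scale: float = 1.0,
) -> VectorScene:
    """Assemble geometry elements and their labels into a scene.

    Chart primitives come first, label text after (so labels draw on
    top); ``showlabels=False`` omits every text primitive.  Bars label
    above/below their tip, slices at mid-angle and mid-radius.
    """
    style = label_style or LabelStyle()
    prims: list = []
    texts: list = []
    items = elements if isinstance(elements, (list, tuple)) else [elements]
    for el in items:
        if isinstance(el, Slice):
            prims.append(
                SectorPrim(
                    cx=0.5,
                    cy=0.5,
                    inner=el.inner_radius,
                    outer=el.outer_radius,
                    start_angle=el.start_angle,
                    extent=el.extent,
                    fill=el.color,
                )
            )
            if el.label:
                x, y = _slice_label_pos(el)
                texts.append(TextPrim(x=x, y=y, text=el.label, style=style))
        elif isinstance(el, BarRect):
            prims.append(RectPrim(x0=el.x0, y0=el.y0, x1=el.x1, y1=el.y1, fill=el.fill))
            if el.label:
                x, y = _bar_label_pos(el)
                texts.append(TextPrim(x=x, y=y, text=el.label, style=style))
        elif isinstance(el, Polyline):
            prims.append(PolylinePrim(points=el.points, width=el.width, color=el.color))
            for (x, y), lab in zip(el.points, el.labels):
                if lab:
                    texts.append(TextPrim(x=x, y=y - 0.04, text=lab, style=style))
        elif isinstance(el, (LinearPaint, RadialPaint)):
            prims.append(PaintPrim(paint=el))
        else:
            raise TypeError(f"cannot build a scene from {type(el).__name__}")
    if showlabels:
        prims.extend(texts)
    return VectorScene(primitives=tuple(prims), scale=scale)


# ---------------------------------------------------------------------------
# composition
# ---------------------------------------------------------------------------

def _place(pt: tuple[float, float], scale: float, origin: tuple[float, float], size: tuple[float, float]) -> tuple[float, float]:
    ux = 0.5 + (pt[0] - 0.5) * scale
    uy = 0.5 + (pt[1] - 0.5) * scale
    return (origin[0] + ux * size[0], origin[1] + uy * size[1])


@dataclass(frozen=True)
class ComposedNode:
    node_id: str
    bbox: tuple[float, float, float, float]  # x, y, w, h (top-left anchored)
    shape: str  # rect | ellipse
    scene: VectorScene  # canvas coordinates


def compose_node(
    scenes: list[tuple[VectorScene, SlotPlacement]],
    node_bbox: tuple[float, float, float, float],
    node_shape: str = "ellipse",
    node_id: str = "",
) -> ComposedNode:
    """Place up to nine scenes on one node, in slot (z) order.

    Each scene is scaled by its own ``scale`` about its centre, then
    translated to the node centre plus the slot offset.  Gradient paints
    fill (and are clipped to) the node shape itself.
    """
    if not 1 <= len(scenes) <= 9:
        raise SlotOverflowError(
            f"a node composes 1..9 glyphs, got {len(scenes)}"
        )
    slots = [p.slot for _, p in scenes]
    if len(set(slots)) != len(slots):
        dup = sorted({s for s in slots if slots.count(s) > 1})
        raise DuplicateSlotError(f"slots {dup} assigned more than once")

    x, y, w, h = node_bbox
    out: list = []
    for scene, placement in sorted(scenes, key=lambda sp: sp[1].zorder):
        dx, dy = placement.resolved_offset()
        origin = (x + dx * w, y + dy * h)
        size = (w, h)
        k = scene.scale
        for prim in scene.primitives:
            if isinstance(prim, RectPrim):
                p0 = _place((prim.x0, prim.y0), k, origin, size)
                p1 = _place((prim.x1, prim.y1), k, origin, size)
                out.append(RectPrim(x0=p0[0], y0=p0[1], x1=p1[0], y1=p1[1], fill=prim.fill))
            elif isinstance(prim, SectorPrim):
                c = _place((prim.cx, prim.cy), k, origin, size)
                radius_scale = k * min(w, h)
                out.append(
                    SectorPrim(
                        cx=c[0],
                        cy=c[1],
                        inner=prim.inner * radius_scale,
                        outer=prim.outer * radius_scale,
                        start_angle=prim.start_angle,
                        extent=prim.extent,
                        fill=prim.fill,
                    )
                )
            elif isinstance(prim, PolylinePrim):
                pts = tuple(_place(p, k, origin, size) for p in prim.points)
                out.append(
                    PolylinePrim(points=pts, width=prim.width * k * min(w, h), color=prim.color)
                )
            elif isinstance(prim, TextPrim):
                p = _place((prim.x, prim.y), k, origin, size)
                out.append(TextPrim(x=p[0], y=p[1], text=prim.text, style=prim.style))
            elif isinstance(prim, PaintPrim):
                out.append(prim)  # resolved against the node shape at SVG time
            else:
                raise TypeError(f"unknown primitive {type(prim).__name__}")
    return ComposedNode(
        node_id=node_id, bbox=node_bbox, shape=node_shape, scene=VectorScene(primitives=tuple(out))
    )


# ---------------------------------------------------------------------------
# SVG emission
# ---------------------------------------------------------------------------

def _css(color: RGBA) -> str:
    return f"#{color.r:02x}{color.g:02x}{color.b:02x}"


def _opacity(color: RGBA) -> str:
    return f"{color.a / 255:.4g}"


def _num(v: float) -> str:
    return f"{v:.4f}".rstrip("0").rstrip(".")


def _sector_path(p: SectorPrim) -> str:
    """SVG path for an annular sector (or full pie slice when inner=0)."""

    def point(r: float, ang_deg: float) -> tuple[float, float]:
        a = math.radians(ang_deg)
        return (p.cx + r * math.sin(a), p.cy - r * math.cos(a))

    extent = min(p.extent, 360.0)
    full = extent >= 360.0 - 1e-9
    a0, a1 = p.start_angle, p.start_angle + extent
    large = 1 if extent > 180.0 else 0
    ox0, oy0 = point(p.outer, a0)
    if full:
        # a closed ring: two half arcs outer, then inner if annular
        oxm, oym = point(p.outer, a0 + 180.0)
        d = (
            f"M {_num(ox0)} {_num(oy0)} "
            f"A {_num(p.outer)} {_num(p.outer)} 0 1 1 {_num(oxm)} {_num(oym)} "
            f"A {_num(p.outer)} {_num(p.outer)} 0 1 1 {_num(ox0)} {_num(oy0)} Z"
        )
        if p.inner > 0:
            ix0, iy0 = point(p.inner, a0)
            ixm, iym = point(p.inner, a0 + 180.0)
            d += (
                f" M {_num(ix0)} {_num(iy0)} "
                f"A {_num(p.inner)} {_num(p.inner)} 0 1 0 {_num(ixm)} {_num(iym)} "
                f"A {_num(p.inner)} {_num(p.inner)} 0 1 0 {_num(ix0)} {_num(iy0)} Z"
            )
        return d
    ox1, oy1 = point(p.outer, a1)
    if p.inner <= 0:
        return (
            f"M {_num(p.cx)} {_num(p.cy)} L {_num(ox0)} {_num(oy0)} "
            f"A {_num(p.outer)} {_num(p.outer)} 0 {large} 1 {_num(ox1)} {_num(oy1)} Z"
        )
    ix0, iy0 = point(p.inner, a0)
    ix1, iy1 = point(p.inner, a1)
    return (
        f"M {_num(ix0)} {_num(iy0)} L {_num(ox0)} {_num(oy0)} "
        f"A {_num(p.outer)} {_num(p.outer)} 0 {large} 1 {_num(ox1)} {_num(oy1)} "
        f"L {_num(ix1)} {_num(iy1)} "
        f"A {_num(p.inner)} {_num(p.inner)} 0 {large} 0 {_num(ix0)} {_num(iy0)} Z"
    )


_STYLE_MAP = {
    "plain": {},
    "bold": {"font-weight": "bold"},
    "italics": {"font-style": "italic"},
    "bolditalic": {"font-weight": "bold", "font-style": "italic"},
}


def resolve_font(name: str | None) -> str:
    """Map a requested label font to a usable family, falling back to a
    default sans face when the name is unknown."""
    if name is None or name == DEFAULT_FONT:
        return DEFAULT_FONT
    if name.lower() in KNOWN_FONTS:
        return name
    import logging

    logging.getLogger("nodeglyphs").warning(
        "font %r not available; falling back to %s", name, DEFAULT_FONT
    )
    return DEFAULT_FONT


def _stop_elements(parent: ET.Element, stops) -> None:
    for s in stops:
        ET.SubElement(
            parent,
            "stop",
            {
                "offset": _num(s.position),
                "stop-color": _css(s.color),
                "stop-opacity": _opacity(s.color),
            },
        )


def render_svg(
    nodes: list[ComposedNode],
    edges: list[tuple[tuple[float, float], tuple[float, float]]] | None = None,
    canvas: tuple[float, float] = (800.0, 600.0),
) -> str:
    """Emit the composed network as an SVG 1.1 document string.

    Gradients become ``linearGradient``/``radialGradient`` defs with the
    parsed stops; ids are stable functions of node id and element index,
    so identical input yields byte-identical output.
    """
    w, h = canvas
    root = ET.Element(
        "svg",
        {
            "xmlns": "http://www.w3.org/2000/svg",
            "version": "1.1",
            "width": _num(w),
            "height": _num(h),
            "viewBox": f"0 0 {_num(w)} {_num(h)}",
        },
    )
    defs = ET.SubElement(root, "defs")
    edge_group = ET.SubElement(root, "g", {"id": "edges", "stroke": "#999999", "stroke-width": "1"})
    for (x1, y1), (x2, y2) in edges or []:
        ET.SubElement(
            edge_group,
            "line",
            {"x1": _num(x1), "y1": _num(y1), "x2": _num(x2), "y2": _num(y2)},
        )
    node_group = ET.SubElement(root, "g", {"id": "nodes"})

    for node in nodes:
        nx, ny, nw, nh = node.bbox
        gid = node.node_id.replace(" ", "_")
        g = ET.SubElement(node_group, "g", {"id": f"node-{gid}"})
        shape_attrs = {"fill": "#e8e8e8", "stroke": "#555555", "stroke-width": "1"}
        if node.shape == "ellipse":
            ET.SubElement(
                g,
                "ellipse",
                {
                    "cx": _num(nx + nw / 2),
                    "cy": _num(ny + nh / 2),
                    "rx": _num(nw / 2),
                    "ry": _num(nh / 2),
                    **shape_attrs,
                },
            )
        else:
            ET.SubElement(
                g,
                "rect",
                {"x": _num(nx), "y": _num(ny), "width": _num(nw), "height": _num(nh), **shape_attrs},
            )
        grad_count = 0
        for prim in node.scene.primitives:
            if isinstance(prim, PaintPrim):
                grad_id = f"grad-{gid}-{grad_count}"
                grad_count += 1
                paint = prim.paint
                if isinstance(paint, LinearPaint):
                    gel = ET.SubElement(
                        defs,
                        "linearGradient",
                        {
                            "id": grad_id,
                            "x1": _num(paint.start[0]),
                            "y1": _num(paint.start[1]),
                            "x2": _num(paint.end[0]),
                            "y2": _num(paint.end[1]),
                        },
                    )
                else:
                    gel = ET.SubElement(
                        defs,
                        "radialGradient",
                        {
                            "id": grad_id,
                            "cx": _num(paint.center[0]),
                            "cy": _num(paint.center[1]),
                            "r": _num(paint.radius),
                        },
                    )
                _stop_elements(gel, paint.stops)
                fill = f"url(#{grad_id})"
                if node.shape == "ellipse":
                    ET.SubElement(
                        g,
                        "ellipse",
                        {
                            "cx": _num(nx + nw / 2),
                            "cy": _num(ny + nh / 2),
                            "rx": _num(nw / 2),
                            "ry": _num(nh / 2),
                            "fill": fill,
                        },
                    )
                else:
                    ET.SubElement(
                        g,
                        "rect",
                        {"x": _num(nx), "y": _num(ny), "width": _num(nw), "height": _num(nh), "fill": fill},
                    )
            elif isinstance(prim, RectPrim):
                attrs = {
                    "x": _num(min(prim.x0, prim.x1)),
                    "y": _num(min(prim.y0, prim.y1)),
                    "width": _num(abs(prim.x1 - prim.x0)),
                    "height": _num(abs(prim.y1 - prim.y0)),
                }
                if isinstance(prim.fill, VerticalGradientFill):
                    grad_id = f"grad-{gid}-{grad_count}"
                    grad_count += 1
                    gel = ET.SubElement(
                        defs,
                        "linearGradient",
                        {"id": grad_id, "x1": "0", "y1": "0", "x2": "0", "y2": "1"},
                    )
                    for off, col in ((0.0, prim.fill.top), (1.0, prim.fill.bottom)):
                        ET.SubElement(
                            gel,
                            "stop",
                            {
                                "offset": _num(off),
                                "stop-color": _css(col),
                                "stop-opacity": _opacity(col),
                            },
                        )
                    attrs["fill"] = f"url(#{grad_id})"
                else:
                    attrs["fill"] = _css(prim.fill)
                    if prim.fill.a != 255:
                        attrs["fill-opacity"] = _opacity(prim.fill)
                ET.SubElement(g, "rect", attrs)
            elif isinstance(prim, SectorPrim):
                attrs = {"d": _sector_path(prim), "fill": _css(prim.fill)}
                if prim.fill.a != 255:
                    attrs["fill-opacity"] = _opacity(prim.fill)
                ET.SubElement(g, "path", attrs)
            elif isinstance(prim, PolylinePrim):
                ET.SubElement(
                    g,
                    "polyline",
                    {
                        "points": " ".join(f"{_num(x)},{_num(y)}" for x, y in prim.points),
                        "fill": "none",
                        "stroke": _css(prim.color),
                        "stroke-width": _num(prim.width),
                    },
                )
            elif isinstance(prim, TextPrim):
                st = prim.style
                attrs = {
                    "x": _num(prim.x),
                    "y": _num(prim.y),
                    "font-family": resolve_font(st.font),
                    "font-size": _num(st.size),
                    "fill": _css(st.color),
                    "text-anchor": "middle",
                }
                attrs.update(_STYLE_MAP.get(st.style, {}))
                ET.SubElement(g, "text", attrs).text = prim.text
            else:
                raise TypeError(f"unknown primitive {type(prim).__name__}")

    return ET.tostring(root, encoding="unicode", xml_declaration=True) + "\n"


def render_raster(svg_text: str, dpi: float = 96.0) -> bytes:
    """Rasterize an SVG document to PNG bytes at the requested dpi.

    Requires the optional ``cairosvg`` package; without it a
    :class:`CapabilityError` is raised with an install hint.
    """
    try:
        import cairosvg  # type: ignore[import-not-found]
    except ImportError as exc:
        raise CapabilityError(
            "raster preview needs the optional 'cairosvg' package; "
            "install it with: pip install cairosvg"
        ) from exc
    return cairosvg.svg2png(bytestring=svg_text.encode(), dpi=dpi)
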