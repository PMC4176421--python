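"""Chart geometry in node-local unit coordinates.

Every glyph is laid out inside the *unit box*: x and y in [0, 1], origin
at the top-left, y increasing downward.  The renderer later scales and
translates the unit box onto an actual node bounding box, so all the
proportional arithmetic — pie extents, circos ring radii, bar baselines,
stripe partitions, gradient axes — happens here once, independent of
canvas size.

Conventions (fixed so rendered output is stable; see docs/methods.md):

* ``arcstart = 0`` points at 12 o'clock and slices advance clockwise;
* the signed value normalization divides by ``max(|min|, |max|)`` when
  the range straddles zero, so 0 always lands on the chart baseline,
  and maps affinely onto [0, 1] otherwise;
* ``separation`` and ``linewidth`` are given in reference units of a
  100x100 node box and divided by 100 into unit-box units;
* data values outside the declared range clamp (with a logged warning)
  rather than erroring — one outlier should not kill a figure;
* NaN values produce zero-extent elements and a logged warning.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

from .color_engine import (
    GradientRamp,
    Palette,
    generate_palette,
    interpolate,
    ramp_for_keyword,
    ramp_zero_color,
    resolve_updown,
    updown_ramp,
)
from .errors import (
    DegenerateAxisError,
    DegeneratePieError,
    LayoutOverflowError,
    MissingAttributeError,
    MissingValueError,
    NegativeSliceError,
    RangeBoundError,
    TooFewPointsError,
    ValueTypeError,
)
from .instruction_parser import (
    RGBA,
    ColorListSpec,
    GlyphSpec,
    GradientStop,
    LinGradArgs,
    RadGradArgs,
)

log = logging.getLogger("nodeglyphs")

REFERENCE_BOX = 100.0  # separation/linewidth are given relative to this


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NodeRecord:
    """One node: an id, scalar columns, and list-valued columns."""

    node_id: str
    scalars: dict = field(default_factory=dict)
    lists: dict = field(default_factory=dict)

    def __post_init__(self):
        overlap = set(self.scalars) & set(self.lists)
        if overlap:
            raise ValueTypeError(
                f"node {self.node_id!r}: columns {sorted(overlap)} are both scalar and list"
            )


@dataclass(frozen=True)
class ResolvedSeries:
    values: tuple[float, ...]
    labels: tuple[str, ...]
    colors: Palette

    def __post_init__(self):
        if not (len(self.values) == len(self.labels) == len(self.colors.colors)):
            raise ValueTypeError(
                "values, labels and colors must all have the same length"
            )


@dataclass(frozen=True)
class Slice:
    """An annular sector: full pie slices have inner_radius 0."""

    start_angle: float  # degrees, 0 = 12 o'clock, clockwise
    extent: float  # degrees, >= 0
    inner_radius: float
    outer_radius: float
    color: RGBA
    label: str = ""

    def __post_init__(self):
        if self.extent < 0:
            raise RangeBoundError(f"slice extent {self.extent} negative")
        if not 0 <= self.inner_radius <= self.outer_radius <= 0.5:
            raise RangeBoundError(
                f"slice radii ({self.inner_radius}, {self.outer_radius}) "
                "must satisfy 0 <= inner <= outer <= 0.5"
            )


@dataclass(frozen=True)
class VerticalGradientFill:
    """Bar fill shading from ``top`` at y0 to ``bottom`` at y1."""

    top: RGBA
    bottom: RGBA


@dataclass(frozen=True)
class BarRect:
    x0: float
    x1: float
    y0: float
    y1: float
    fill: RGBA | VerticalGradientFill
    label: str = ""

    def __post_init__(self):
        if not self.x0 < self.x1:
            raise RangeBoundError(f"bar needs x0 < x1, got ({self.x0}, {self.x1})")
        if self.y0 > self.y1:
            raise RangeBoundError(f"bar needs y0 <= y1, got ({self.y0}, {self.y1})")


@dataclass(frozen=True)
class Polyline:
    points: tuple[tuple[float, float], ...]
    width: float  # unit-box units
    color: RGBA
    labels: tuple[str, ...] = ()


@dataclass(frozen=True)
class LinearPaint:
    start: tuple[float, float]
    end: tuple[float, float]
    stops: tuple[GradientStop, ...]


@dataclass(frozen=True)
class RadialPaint:
    center: tuple[float, float]
    radius: float
    stops: tuple[GradientStop, ...]


# ---------------------------------------------------------------------------
# series resolution
# ---------------------------------------------------------------------------

def _lookup_scalar(node: NodeRecord, column: str) -> float:
    if column in node.scalars:
        v = node.scalars[column]
        if isinstance(v, bool) or not isinstance(v, (int, float)):
            raise ValueTypeError(
                f"node {node.node_id!r}: column {column!r} is not numeric ({v!r})"
            )
        return float(v)
    if column in node.lists:
        raise ValueTypeError(
            f"node {node.node_id!r}: column {column!r} is a list, expected a scalar"
        )
    raise MissingAttributeError(
        f"node {node.node_id!r} has no column {column!r}"
    )


def _lookup_list(node: NodeRecord, column: str) -> tuple[float, ...]:
    if column in node.lists:
        return tuple(float(v) for v in node.lists[column])
    if column in node.scalars:
        # a single scalar makes a one-element ring
        return (_lookup_scalar(node, column),)
    raise MissingAttributeError(
        f"node {node.node_id!r} has no column {column!r}"
    )


def _series_range(values: tuple[float, ...]) -> tuple[float, float]:
    finite = [v for v in values if not math.isnan(v)]
    if not finite:
        raise MissingValueError("series is entirely NaN")
    lo, hi = min(finite), max(finite)
    if lo == hi:
        # degenerate constant series: widen symmetrically so t is defined
        lo, hi = lo - 1.0, hi + 1.0
    return lo, hi


def _default_colorlist(prefix: str) -> ColorListSpec:
    if prefix == "heatstripchart":
        from .instruction_parser import parse_colorlist

        return parse_colorlist("up:red,down:blue,zero:black")
    return ColorListSpec(mode="keyword", keyword="contrasting")


def resolve_colors(
    colorlist: ColorListSpec,
    values: tuple[float, ...],
    value_range: tuple[float, float] | None,
    seed: int = 0,
) -> Palette:
    """Assign one color per value according to the colorlist form."""
    n = len(values)
    if colorlist.mode == "keyword":
        return generate_palette(colorlist.keyword, n, seed)
    if colorlist.mode == "explicit":
        pool = colorlist.explicit
        return Palette(
            colors=tuple(pool[i % len(pool)] for i in range(n)), origin="explicit"
        )
    if colorlist.mode == "updown":
        return Palette(
            colors=tuple(
                resolve_updown(0.0 if math.isnan(v) else v, colorlist.updown)
                for v in values
            ),
            origin="updown",
        )
    # gradient keyword: tip color at each value's normalized position
    ramp = ramp_for_keyword(colorlist.gradient_keyword)
    rng = value_range if value_range is not None else _series_range(values)
    return Palette(
        colors=tuple(interpolate(ramp, _signed_norm(v, rng)) for v in values),
        origin="gradient_keyword",
    )


def resolve_series(spec: GlyphSpec, node: NodeRecord, seed: int = 0) -> ResolvedSeries:
    """Resolve a chart's values, labels and colors from a node record.

    Values come from the literal ``values`` list when present, otherwise
    from scalar lookups over ``attributelist``; labels default to the
    attribute names (already filled at parse time) or empty strings.
    """
    common = spec.common
    if common.values is not None:
        values = common.values
    elif common.attributelist is not None:
        values = tuple(_lookup_scalar(node, col) for col in common.attributelist)
    else:
        raise MissingValueError(
            f"{spec.prefix} needs either values or attributelist"
        )
    labels = common.labels if common.labels is not None else ("",) * len(values)
    if len(labels) != len(values):
        raise ValueTypeError(
            f"{len(labels)} labels given for {len(values)} values"
        )
    colorlist = common.colorlist or _default_colorlist(spec.prefix)
    colors = resolve_colors(colorlist, values, common.range, seed)
    return ResolvedSeries(values=values, labels=labels, colors=colors)


def resolve_rings(spec: GlyphSpec, node: NodeRecord, seed: int = 0) -> list[ResolvedSeries]:
    """Resolve circos rings: each attributelist entry is one list column."""
    common = spec.common
    if common.values is not None:
        ring_values = [common.values]
        ring_labels = [common.labels or ("",) * len(common.values)]
    elif common.attributelist is not None:
        ring_values = [_lookup_list(node, col) for col in common.attributelist]
        ring_labels = [("",) * len(v) for v in ring_values]
    else:
        raise MissingValueError("circoschart needs either values or attributelist")
    colorlist = common.colorlist or _default_colorlist(spec.prefix)
    rings = []
    for vals, labs in zip(ring_values, ring_labels):
        colors = resolve_colors(colorlist, vals, common.range, seed)
        rings.append(ResolvedSeries(values=vals, labels=labs, colors=colors))
    return rings


# ---------------------------------------------------------------------------
# value normalization
# ---------------------------------------------------------------------------

def _signed_norm(v: float, rng: tuple[float, float]) -> float:
    """normalize_value without the precondition re-checks (internal)."""
    lo, hi = rng
    if math.isnan(v):
        log.warning("NaN value rendered as zero extent")
        return 0.0
    if lo < 0.0 < hi:
        t = v / max(abs(lo), abs(hi))
        if t > 1.0 or t < -1.0:
            log.warning("value %s outside range (%s, %s); clamped", v, lo, hi)
        return min(1.0, max(-1.0, t))
    t = (v - lo) / (hi - lo)
    if t > 1.0 or t < 0.0:
        log.warning("value %s outside range (%s, %s); clamped", v, lo, hi)
    return min(1.0, max(0.0, t))


def normalize_value(v: float, value_range: tuple[float, float]) -> float:
    """Normalize a value for consistent scaling across nodes.

    When the range straddles zero the value is divided by
    ``max(|min|, |max|)`` giving a signed t in [-1, 1] with 0 at the
    baseline; otherwise [min, max] maps affinely onto [0, 1].
    Out-of-range values clamp with a logged warning.
    """
    lo, hi = value_range
    if lo >= hi:
        raise RangeBoundError(f"range min {lo} must be below max {hi}")
    return _signed_norm(v, (lo, hi))


# ---------------------------------------------------------------------------
# chart layouts
# ---------------------------------------------------------------------------

def _angular_layout(
    series: ResolvedSeries,
    arcstart: float,
    sortslices: bool,
    inner: float,
    outer: float,
) -> list[Slice]:
    order = list(range(len(series.values)))
    for i in order:
        v = series.values[i]
        if math.isnan(v):
            raise MissingValueError("NaN value in pie/circos series")
        if v < 0:
            raise NegativeSliceError(f"negative slice value {v}")
    total = sum(series.values)
    if total <= 0:
        raise DegeneratePieError("pie/circos values sum to zero")
    if sortslices:
        # descending by value, stable on ties
        order.sort(key=lambda i: -series.values[i])
    slices = []
    angle = arcstart
    for i in order:
        extent = 360.0 * series.values[i] / total
        slices.append(
            Slice(
                start_angle=angle,
                extent=extent,
                inner_radius=inner,
                outer_radius=outer,
                color=series.colors.colors[i],
                label=series.labels[i],
            )
        )
        angle += extent
    return slices


def pie_layout(
    series: ResolvedSeries, arcstart: float = 0.0, sortslices: bool = False
) -> list[Slice]:
    """Lay out pie slices: extent_i = 360 * v_i / sum(v)."""
    return _angular_layout(series, arcstart, sortslices, inner=0.0, outer=0.5)


def circos_layout(
    rings: list[ResolvedSeries],
    firstarc: float = 0.2,
    firstarcwidth: float = 0.4,
    arcwidth: float = 0.2,
    arcstart: float = 0.0,
    sortslices: bool = False,
) -> list[Slice]:
    """Lay out concentric donut rings.

    Radial proportions are node-diameter fractions, halved into radius
    units: ring 0 starts at ``firstarc/2`` with thickness
    ``firstarcwidth/2``; later rings are ``arcwidth/2`` thick each.
    """
    if not rings:
        raise DegeneratePieError("circos chart with no rings")
    inner = firstarc / 2.0
    slices = []
    for k, ring in enumerate(rings):
        width = (firstarcwidth if k == 0 else arcwidth) / 2.0
        outer = inner + width
        if outer > 0.5 + 1e-12:
            raise LayoutOverflowError(
                f"circos ring {k} reaches radius {outer:.3f} > 0.5 (unit box)"
            )
        slices.extend(
            _angular_layout(ring, arcstart, sortslices, inner=inner, outer=min(outer, 0.5))
        )
        inner = outer
    return slices


def _ybase_to_y(ybase: str | float) -> float:
    if ybase == "top":
        return 0.0
    if ybase == "middle":
        return 0.5
    if ybase == "bottom":
        return 1.0
    return float(ybase)


def _bar_frames(
    n: int, separation: float
) -> list[tuple[float, float]]:
    sep = separation / REFERENCE_BOX
    if n > 1 and sep * (n - 1) >= 1.0:
        raise LayoutOverflowError(
            f"{n} bars with separation {separation} overflow the unit box"
        )
    width = (1.0 - sep * max(n - 1, 0)) / n
    return [(i * (width + sep), i * (width + sep) + width) for i in range(n)]


def _bar_span(t: float, y_b: float) -> tuple[float, float]:
    """Vertical extent of a bar with normalized value t about baseline y_b."""
    if t >= 0:
        return (y_b - t * y_b, y_b)
    return (y_b, y_b + (-t) * (1.0 - y_b))


def _apply_scale(v: float, scale: float) -> float:
    return 0.5 + (v - 0.5) * scale


def bar_layout(
    series: ResolvedSeries,
    separation: float = 0.0,
    ybase: str | float = "bottom",
    value_range: tuple[float, float] | None = None,
    scale: float = 1.0,
) -> list[BarRect]:
    """Lay out equal-width bars about the ybase baseline.

    Positive normalized values grow upward from the baseline, negative
    ones downward into the remaining box; missing ``value_range`` falls
    back to the series' own extremes (per-node autoscale).
    """
    if not series.values:
        raise MissingValueError("empty bar series")
    rng = value_range if value_range is not None else _series_range(series.values)
    y_b = _ybase_to_y(ybase)
    frames = _bar_frames(len(series.values), separation)
    bars = []
    for (x0, x1), v, color, label in zip(
        frames, series.values, series.colors.colors, series.labels
    ):
        t = _signed_norm(v, rng)
        y0, y1 = _bar_span(t, y_b)
        bars.append(
            BarRect(
                x0=_apply_scale(x0, scale),
                x1=_apply_scale(x1, scale),
                y0=_apply_scale(y0, scale),
                y1=_apply_scale(y1, scale),
                fill=color,
                label=label,
            )
        )
    return bars


def heatstrip_layout(
    series: ResolvedSeries,
    separation: float = 0.0,
    ramp: GradientRamp | None = None,
    value_range: tuple[float, float] | None = None,
    ybase: str | float = "bottom",
) -> list[BarRect]:
    """Bar geometry with gradient fills: ramp color at |t| shading to the
    ramp's zero color at the baseline.  Rectangles are identical to
    :func:`bar_layout` for the same inputs; only the fill differs."""
    if ramp is None:
        ramp = ramp_for_keyword("yellowblue")
    plain = bar_layout(series, separation, ybase, value_range, scale=1.0)
    rng = value_range if value_range is not None else _series_range(series.values)
    zero = ramp_zero_color(ramp)
    out = []
    for bar, v in zip(plain, series.values):
        t = _signed_norm(v, rng)
        tip = interpolate(ramp, t)
        fill = (
            VerticalGradientFill(top=tip, bottom=zero)
            if t >= 0
            else VerticalGradientFill(top=zero, bottom=tip)
        )
        out.append(BarRect(bar.x0, bar.x1, bar.y0, bar.y1, fill=fill, label=bar.label))
    return out


def line_layout(
    series: ResolvedSeries,
    linewidth: float = 1.0,
    value_range: tuple[float, float] | None = None,
    ybase: str | float = "bottom",
) -> Polyline:
    """Lay out a polyline: point i at x = i/(n-1), y from the normalized
    value about the ybase baseline."""
    n = len(series.values)
    if n < 2:
        raise TooFewPointsError(f"line chart needs >= 2 points, got {n}")
    rng = value_range if value_range is not None else _series_range(series.values)
    y_b = _ybase_to_y(ybase)
    points = []
    for i, v in enumerate(series.values):
        t = _signed_norm(v, rng)
        y = y_b - t * y_b if t >= 0 else y_b + (-t) * (1.0 - y_b)
        points.append((i / (n - 1), y))
    return Polyline(
        points=tuple(points),
        width=linewidth / REFERENCE_BOX,
        color=series.colors.colors[0],
        labels=series.labels,
    )


def stripe_layout(colors: Palette) -> list[BarRect]:
    """Split the unit box into n equal full-height vertical stripes."""
    n = len(colors)
    return [
        BarRect(x0=i / n, x1=(i + 1) / n, y0=0.0, y1=1.0, fill=c)
        for i, c in enumerate(colors.colors)
    ]


def gradient_frame(spec: GlyphSpec) -> LinearPaint | RadialPaint:
    """Build the paint definition for a lingrad/radgrad spec."""
    args = spec.chart_args
    if isinstance(args, LinGradArgs):
        if args.start == args.end:
            raise DegenerateAxisError(
                f"linear gradient start equals end ({args.start})"
            )
        return LinearPaint(start=args.start, end=args.end, stops=args.stoplist)
    if isinstance(args, RadGradArgs):
        return RadialPaint(center=args.center, radius=args.radius, stops=args.stoplist)
    raise ValueTypeError(f"{spec.prefix} is not a gradient spec")


# ---------------------------------------------------------------------------
# dispatch
# ---------------------------------------------------------------------------

def _heatstrip_ramp(colorlist: ColorListSpec) -> GradientRamp:
    if colorlist.mode == "gradient_keyword":
        return ramp_for_keyword(colorlist.gradient_keyword)
    if colorlist.mode == "updown":
        return updown_ramp(colorlist.updown)
    raise ValueTypeError(
        "heat strips need a gradient keyword or up/down colorlist"
    )


def _stripe_palette(colorlist: ColorListSpec, seed: int) -> Palette:
    if colorlist.mode == "explicit":
        return Palette(colors=colorlist.explicit, origin="explicit")
    if colorlist.mode == "updown":
        ud = colorlist.updown
        return Palette(colors=(ud.up, ud.zero, ud.down), origin="updown")
    # palette keyword: the stripe count is this package's convention (8)
    return generate_palette(colorlist.keyword, 8, seed)


def layout_glyph(spec: GlyphSpec, node: NodeRecord, seed: int = 0) -> list:
    """Lay out any glyph spec against a node record.

    Returns a list of geometry elements (Slices, BarRects, a Polyline,
    or a gradient paint) in unit-box coordinates, ready for scene
    assembly.  The per-spec ``scale`` is applied later, at composition.
    """
    common = spec.common
    args = spec.chart_args
    if spec.prefix in ("lingrad", "radgrad"):
        return [gradient_frame(spec)]
    if spec.prefix == "piechart":
        series = resolve_series(spec, node, seed)
        return pie_layout(series, args.arcstart, args.sortslices)
    if spec.prefix == "circoschart":
        rings = resolve_rings(spec, node, seed)
        return circos_layout(
            rings,
            firstarc=args.firstarc,
            firstarcwidth=args.firstarcwidth,
            arcwidth=args.arcwidth,
            arcstart=args.arcstart,
            sortslices=args.sortslices,
        )
    if spec.prefix == "barchart":
        series = resolve_series(spec, node, seed)
        return bar_layout(series, args.separation, common.ybase, common.range)
    if spec.prefix == "heatstripchart":
        series = resolve_series(spec, node, seed)
        ramp = _heatstrip_ramp(common.colorlist or _default_colorlist(spec.prefix))
        return heatstrip_layout(
            series, args.separation, ramp, common.range, common.ybase
        )
    if spec.prefix == "linechart":
        series = resolve_series(spec, node, seed)
        return [line_layout(series, args.linewidth, common.range, common.ybase)]
    if spec.prefix == "stripechart":
        palette = _stripe_palette(common.colorlist, seed)
        return stripe_layout(palette)
    raise ValueTypeError(f"no layout for prefix {spec.prefix!r}")
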