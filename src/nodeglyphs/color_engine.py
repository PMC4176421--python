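"""Palette generation and color interpolation.

Three concerns live here:

* turning a colorlist keyword (``contrasting``, ``modulated``, ``rainbow``,
  ``random``) into a palette of ``n`` opaque colors, one per data series
  element or slice;
* resolving up/down color triples for signed values;
* interpolating the named heat-strip ramps (``yellowblue`` etc.) and
  explicit gradient stop lists.

All interpolation happens in straight RGBA space with components rounded
half-up — the simplest convention a user can verify by hand.  Alpha
interpolates like any other component.  The exact palette formulas for
``contrasting`` (golden-angle hue stepping) and ``modulated``
(saturation/brightness alternating between 1.0 and 0.6 over rainbow
hues) are this package's own deterministic conventions; see
``docs/methods.md``.
"""

from __future__ import annotations

import colorsys
import math
from dataclasses import dataclass

import numpy as np

from .errors import (
    EmptyPaletteError,
    MissingValueError,
    RangeBoundError,
    UnknownKeywordError,
)
from .instruction_parser import (
    GRADIENT_KEYWORDS,
    RGBA,
    GradientStop,
    UpDownColors,
    parse_color,
)

GOLDEN_ANGLE_DEG = 137.50776405003785  # 360 / phi^2


@dataclass(frozen=True)
class Palette:
    colors: tuple[RGBA, ...]
    origin: str  # keyword | gradient_keyword | updown | explicit

    def __post_init__(self):
        if not self.colors:
            raise EmptyPaletteError("palette has no colors")

    def __len__(self) -> int:
        return len(self.colors)


@dataclass(frozen=True)
class GradientRamp:
    """Two- or three-anchor color ramp for signed values.

    ``anchors[0]`` colors the positive extreme, ``anchors[-1]`` the
    negative extreme; a three-anchor ramp pins its middle anchor at the
    normalized zero.
    """

    anchors: tuple[RGBA, ...]
    keyword: str

    def __post_init__(self):
        if len(self.anchors) not in (2, 3):
            raise RangeBoundError(
                f"ramp needs 2 or 3 anchors, got {len(self.anchors)}"
            )


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def _hsv(h_deg: float, s: float, v: float) -> RGBA:
    r, g, b = colorsys.hsv_to_rgb((h_deg % 360.0) / 360.0, s, v)
    return RGBA(_round_half_up(r * 255), _round_half_up(g * 255), _round_half_up(b * 255), 255)


def generate_palette(keyword: str, n: int, seed: int = 0) -> Palette:
    """Generate ``n`` opaque colors for a palette keyword.

    rainbow
        fully saturated, full-brightness hues at ``i/n`` of the wheel.
    contrasting
        hues stepped by the golden angle so consecutive entries sit on
        opposite sides of the wheel (maximal separation, order-free).
    modulated
        rainbow hues with saturation and brightness alternating between
        1.0 and 0.6.
    random
        hues drawn from a seeded uniform generator; reproducible.
    """
    if n == 0:
        raise EmptyPaletteError("cannot generate a palette of zero colors")
    if n < 0:
        raise EmptyPaletteError(f"palette size {n} is negative")
    if keyword == "rainbow":
        colors = tuple(_hsv(360.0 * i / n, 1.0, 1.0) for i in range(n))
    elif keyword == "contrasting":
        colors = tuple(_hsv(GOLDEN_ANGLE_DEG * i, 1.0, 1.0) for i in range(n))
    elif keyword == "modulated":
        colors = tuple(
            _hsv(360.0 * i / n, 1.0 if i % 2 == 0 else 0.6, 1.0 if i % 2 == 0 else 0.6)
            for i in range(n)
        )
    elif keyword == "random":
        rng = np.random.default_rng(seed)
        hues = rng.uniform(0.0, 360.0, size=n)
        colors = tuple(_hsv(h, 1.0, 1.0) for h in hues)
    else:
        raise UnknownKeywordError(
            f"unknown palette keyword {keyword!r}; expected contrasting, "
            "modulated, rainbow or random"
        )
    return Palette(colors=colors, origin="keyword")


def resolve_updown(value: float, colors: UpDownColors) -> RGBA:
    """Pick the up/down/zero color by the exact sign of ``value``."""
    if math.isnan(value):
        raise MissingValueError("cannot resolve an up/down color for NaN")
    if value > 0:
        return colors.up
    if value < 0:
        return colors.down
    return colors.zero


# anchor color names per gradient keyword; first name colors the
# positive extreme, last the negative extreme
_RAMP_NAMES = {
    "yellowcyan": ("yellow", "cyan"),
    "yellowblue": ("yellow", "blue"),
    "orangepurple": ("orange", "purple"),
    "bluegreenyellow": ("blue", "green", "yellow"),
    "purpleyellow": ("purple", "yellow"),
    "greenpurple": ("green", "purple"),
    "redyellow": ("red", "yellow"),
    "redgreen": ("red", "green"),
}
assert set(_RAMP_NAMES) == set(GRADIENT_KEYWORDS)


def ramp_for_keyword(keyword: str) -> GradientRamp:
    """Resolve a gradient keyword into its anchor ramp."""
    names = _RAMP_NAMES.get(keyword)
    if names is None:
        raise UnknownKeywordError(
            f"unknown gradient keyword {keyword!r}; valid keywords: "
            + ", ".join(GRADIENT_KEYWORDS)
        )
    return GradientRamp(anchors=tuple(parse_color(n) for n in names), keyword=keyword)


def _lerp(c0: RGBA, c1: RGBA, f: float) -> RGBA:
    return RGBA(
        _round_half_up(c0.r + (c1.r - c0.r) * f),
        _round_half_up(c0.g + (c1.g - c0.g) * f),
        _round_half_up(c0.b + (c1.b - c0.b) * f),
        _round_half_up(c0.a + (c1.a - c0.a) * f),
    )


def interpolate(ramp: GradientRamp, t: float) -> RGBA:
    """Color for a normalized value ``t`` in [-1, 1].

    Two-anchor ramps interpolate linearly from ``anchors[1]`` at t=-1 to
    ``anchors[0]`` at t=+1 (their midpoint at t=0); three-anchor ramps
    are piecewise linear with the middle anchor exactly at t=0.
    """
    if math.isnan(t):
        raise MissingValueError("cannot interpolate a ramp at NaN")
    if not -1.0 <= t <= 1.0:
        raise RangeBoundError(f"normalized value {t} outside [-1, 1]")
    if len(ramp.anchors) == 2:
        pos, neg = ramp.anchors
        # fraction 0 at t=-1 (neg anchor) .. 1 at t=+1 (pos anchor)
        return _lerp(neg, pos, (t + 1.0) / 2.0)
    pos, mid, neg = ramp.anchors
    if t >= 0:
        return _lerp(mid, pos, t)
    return _lerp(mid, neg, -t)


def ramp_zero_color(ramp: GradientRamp) -> RGBA:
    """The ramp color at normalized zero (heat-strip baseline color)."""
    return interpolate(ramp, 0.0)


def updown_ramp(colors: UpDownColors) -> GradientRamp:
    """View an up/down triple as a three-anchor ramp (zero in the middle)."""
    return GradientRamp(anchors=(colors.up, colors.zero, colors.down), keyword="updown")


def stops_to_paint(stops: tuple[GradientStop, ...], t: float) -> RGBA:
    """Piecewise-linear color of a sorted stop list at proportion ``t``.

    Positions before the first or after the last stop clamp to that
    stop's color, so a single-stop list is a constant paint.
    """
    if not stops:
        raise EmptyPaletteError("empty stop list")
    if t <= stops[0].position:
        return stops[0].color
    if t >= stops[-1].position:
        return stops[-1].color
    for lo, hi in zip(stops, stops[1:]):
        if lo.position <= t <= hi.position:
            span = hi.position - lo.position
            f = 0.0 if span == 0 else (t - lo.position) / span
            return _lerp(lo.color, hi.color, f)
    return stops[-1].color  # unreachable for sorted stops
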