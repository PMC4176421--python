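"""Parse and serialize the node-glyph instruction mini-language.

A glyph is fully specified by a short instruction string stored in a
node-table column, of the form::

    type: name=value name="quoted value" ...

where ``type`` is one of two gradient prefixes (``lingrad``, ``radgrad``)
or six chart prefixes (``barchart``, ``circoschart``, ``heatstripchart``,
``linechart``, ``piechart``, ``stripechart``).  Values may be bare tokens
or double-quoted strings (quoted values may contain spaces and ``=``).
The full grammar is documented in ``docs/grammar.md``.

Parsing is strict: unknown prefixes, unknown or misspelled argument
names, arguments a chart type forbids, out-of-range color components and
proportions all raise typed errors from :mod:`nodeglyphs.errors` rather
than being silently repaired — a typo'd instruction should never produce
a plausible-looking but wrong figure.

:func:`parse_instruction` is the main entry point; :func:`serialize_instruction`
emits a canonical form such that ``parse(serialize(s)) == s``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace

from matplotlib.colors import CSS4_COLORS

from .errors import (
    ArityError,
    ColorParseError,
    DuplicateArgumentError,
    ForbiddenArgumentError,
    InstructionSyntaxError,
    MissingArgumentError,
    RangeBoundError,
    UnknownArgumentError,
    UnknownTypeError,
    ValueTypeError,
)

GRADIENT_PREFIXES = ("lingrad", "radgrad")
CHART_PREFIXES = (
    "barchart",
    "circoschart",
    "heatstripchart",
    "linechart",
    "piechart",
    "stripechart",
)
PREFIXES = GRADIENT_PREFIXES + CHART_PREFIXES

PALETTE_KEYWORDS = ("contrasting", "modulated", "rainbow", "random")
GRADIENT_KEYWORDS = (
    "yellowcyan",
    "yellowblue",
    "orangepurple",
    "bluegreenyellow",
    "purpleyellow",
    "greenpurple",
    "redyellow",
    "redgreen",
)

LABEL_STYLES = ("italics", "bold", "bolditalic", "plain")
YBASE_KEYWORDS = ("top", "middle", "bottom")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RGBA:
    """A color with red, green, blue, alpha components, each in [0, 255]."""

    r: int
    g: int
    b: int
    a: int = 255

    def __post_init__(self):
        for name in ("r", "g", "b", "a"):
            v = getattr(self, name)
            if not isinstance(v, int) or not 0 <= v <= 255:
                raise RangeBoundError(
                    f"color component {name}={v!r} outside [0, 255]"
                )

    def to_hex(self) -> str:
        if self.a == 255:
            return f"#{self.r:02X}{self.g:02X}{self.b:02X}"
        return f"#{self.r:02X}{self.g:02X}{self.b:02X}{self.a:02X}"


BLACK = RGBA(0, 0, 0, 255)


@dataclass(frozen=True)
class GradientStop:
    color: RGBA
    position: float  # proportion along the gradient axis

    def __post_init__(self):
        if not 0.0 <= self.position <= 1.0:
            raise RangeBoundError(
                f"gradient stop position {self.position} outside [0, 1]"
            )


@dataclass(frozen=True)
class UpDownColors:
    """Colors for positive, negative, and zero values."""

    up: RGBA
    down: RGBA
    zero: RGBA = BLACK


@dataclass(frozen=True)
class ColorListSpec:
    """One of the four colorlist forms, tagged by ``mode``."""

    mode: str  # keyword | gradient_keyword | updown | explicit
    keyword: str | None = None
    gradient_keyword: str | None = None
    updown: UpDownColors | None = None
    explicit: tuple[RGBA, ...] | None = None

    def __post_init__(self):
        payloads = {
            "keyword": self.keyword,
            "gradient_keyword": self.gradient_keyword,
            "updown": self.updown,
            "explicit": self.explicit,
        }
        populated = [k for k, v in payloads.items() if v is not None]
        if populated != [self.mode]:
            raise ValueTypeError(
                f"colorlist mode {self.mode!r} inconsistent with payloads {populated}"
            )


@dataclass(frozen=True)
class RawInstruction:
    """Tokenized but not yet type-checked instruction."""

    prefix: str
    args: tuple[tuple[str, str], ...]  # ordered (name, unquoted value) pairs


@dataclass(frozen=True)
class CommonArgs:
    """Arguments shared across chart types (a subset applies per prefix)."""

    attributelist: tuple[str, ...] | None = None
    values: tuple[float, ...] | None = None
    labels: tuple[str, ...] | None = None
    labelcolor: RGBA | None = None
    labelfont: str | None = None
    labelsize: float | None = None
    labelstyle: str = "plain"
    range: tuple[float, float] | None = None
    scale: float = 1.0
    showlabels: bool = True
    ybase: str | float = "bottom"
    colorlist: ColorListSpec | None = None


# per-prefix chart argument records ------------------------------------------

@dataclass(frozen=True)
class BarArgs:
    separation: float = 0.0


@dataclass(frozen=True)
class CircosArgs:
    arcstart: float = 0.0
    arcwidth: float = 0.2
    firstarc: float = 0.2
    firstarcwidth: float = 0.4
    labelcircles: bool = False
    sortslices: bool = False


@dataclass(frozen=True)
class HeatstripArgs:
    separation: float = 0.0


@dataclass(frozen=True)
class LineArgs:
    linewidth: float = 1.0


@dataclass(frozen=True)
class PieArgs:
    arcstart: float = 0.0
    sortslices: bool = False


@dataclass(frozen=True)
class StripeArgs:
    pass


@dataclass(frozen=True)
class LinGradArgs:
    stoplist: tuple[GradientStop, ...]
    start: tuple[float, float] = (0.0, 0.0)
    end: tuple[float, float] = (1.0, 0.0)


@dataclass(frozen=True)
class RadGradArgs:
    stoplist: tuple[GradientStop, ...]
    center: tuple[float, float] = (0.5, 0.5)
    radius: float = 0.5


CHART_ARG_TYPES = {
    "barchart": BarArgs,
    "circoschart": CircosArgs,
    "heatstripchart": HeatstripArgs,
    "linechart": LineArgs,
    "piechart": PieArgs,
    "stripechart": StripeArgs,
    "lingrad": LinGradArgs,
    "radgrad": RadGradArgs,
}


@dataclass(frozen=True)
class GlyphSpec:
    """Fully parsed, validated form of one instruction string."""

    prefix: str
    common: CommonArgs
    chart_args: object  # one of the *Args records above, matching prefix


# ---------------------------------------------------------------------------
# tokenizer
# ---------------------------------------------------------------------------

_NAME_RE = re.compile(r"[A-Za-z][A-Za-z0-9_]*")


def tokenize_instruction(text: str) -> RawInstruction:
    """Split an instruction string into its prefix and raw argument pairs.

    Quoted values keep internal spaces and ``=``; surrounding quotes are
    stripped.  Raises :class:`UnknownTypeError`,
    :class:`DuplicateArgumentError` or :class:`InstructionSyntaxError`.
    """
    if not text or not text.strip():
        raise InstructionSyntaxError("empty instruction")
    head, sep, rest = text.partition(":")
    if not sep:
        raise InstructionSyntaxError("instruction lacks a ':' after its type prefix")
    prefix = head.strip().lower()
    if prefix not in PREFIXES:
        raise UnknownTypeError(
            f"unknown glyph type {prefix!r}; expected one of {', '.join(PREFIXES)}"
        )

    base = len(head) + 1  # offset of `rest` within `text`
    args: list[tuple[str, str]] = []
    seen: set[str] = set()
    i = 0
    n = len(rest)
    while i < n:
        if rest[i].isspace():
            i += 1
            continue
        m = _NAME_RE.match(rest, i)
        if not m:
            raise InstructionSyntaxError("expected an argument name", base + i)
        name = m.group(0).lower()
        i = m.end()
        if i >= n or rest[i] != "=":
            raise InstructionSyntaxError(f"expected '=' after {name!r}", base + i)
        i += 1
        if i < n and rest[i] == '"':
            close = rest.find('"', i + 1)
            if close == -1:
                raise InstructionSyntaxError("unterminated quote", base + i)
            value = rest[i + 1 : close]
            i = close + 1
        else:
            j = i
            while j < n and not rest[j].isspace():
                j += 1
            value = rest[i:j]
            i = j
        if name in seen:
            raise DuplicateArgumentError(f"argument {name!r} given more than once")
        seen.add(name)
        args.append((name, value))
    return RawInstruction(prefix=prefix, args=tuple(args))


# ---------------------------------------------------------------------------
# scalar parsers
# ---------------------------------------------------------------------------

_NUMBER_RE = re.compile(r"^[+-]?(\d+\.?\d*|\.\d+)$")
_HEX_RE = re.compile(r"^#([0-9a-fA-F]{6}|[0-9a-fA-F]{8})$")

# lowercase CSS/X11 name -> "#rrggbb"
_NAMED_COLORS = {name.lower(): hexval for name, hexval in CSS4_COLORS.items()}


def _parse_real(token: str, what: str) -> float:
    token = token.strip()
    if not _NUMBER_RE.match(token):
        raise ValueTypeError(f"{what}: {token!r} is not a plain numeric literal")
    return float(token)


def _parse_int_component(token: str, what: str) -> int:
    v = _parse_real(token, what)
    if v != int(v):
        raise ValueTypeError(f"{what}: {token!r} must be an integer")
    return int(v)


def _parse_bool(token: str, what: str) -> bool:
    t = token.strip().lower()
    if t == "true":
        return True
    if t == "false":
        return False
    raise ValueTypeError(f"{what}: {token!r} is not true/false")


def _parse_point(token: str, what: str) -> tuple[float, float]:
    parts = token.split(",")
    if len(parts) != 2:
        raise ArityError(f"{what}: expected 'x,y', got {token!r}")
    x = _parse_real(parts[0], what)
    y = _parse_real(parts[1], what)
    for v in (x, y):
        if not 0.0 <= v <= 1.0:
            raise RangeBoundError(f"{what}: coordinate {v} outside [0, 1]")
    return (x, y)


def parse_color(token: str) -> RGBA:
    """Parse a named color, ``#RRGGBB`` or ``#RRGGBBAA`` token.

    Named colors resolve through the standard CSS/X11 table; hex is
    case-insensitive; ``#RRGGBB`` gets alpha 255.
    """
    t = token.strip()
    if t.startswith("#"):
        if not _HEX_RE.match(t):
            raise ColorParseError(f"malformed hex color {token!r}")
        h = t[1:]
        r, g, b = int(h[0:2], 16), int(h[2:4], 16), int(h[4:6], 16)
        a = int(h[6:8], 16) if len(h) == 8 else 255
        return RGBA(r, g, b, a)
    hexval = _NAMED_COLORS.get(t.lower())
    if hexval is None:
        raise ColorParseError(f"unknown color name {token!r}")
    h = hexval.lstrip("#")
    return RGBA(int(h[0:2], 16), int(h[2:4], 16), int(h[4:6], 16), 255)


def parse_stoplist(text: str) -> tuple[GradientStop, ...]:
    """Parse ``r,g,b,a,stop|r,g,b,a,stop|...`` into sorted gradient stops.

    Components are validated against [0, 255] and positions against
    [0, 1]; the result is sorted ascending by position (stable).
    """
    stops: list[GradientStop] = []
    for group in text.split("|"):
        fields = group.split(",")
        if len(fields) != 5:
            raise ArityError(
                f"stoplist group {group!r} has {len(fields)} fields; expected 5 (r,g,b,a,stop)"
            )
        r, g, b, a = (
            _parse_int_component(fields[k], "stoplist component") for k in range(4)
        )
        pos = _parse_real(fields[4], "stoplist position")
        if not 0.0 <= pos <= 1.0:
            raise RangeBoundError(f"stoplist position {pos} outside [0, 1]")
        stops.append(GradientStop(color=RGBA(r, g, b, a), position=pos))
    if not stops:
        raise MissingArgumentError("stoplist is empty")
    stops.sort(key=lambda s: s.position)
    return tuple(stops)


def parse_colorlist(text: str) -> ColorListSpec:
    """Parse a colorlist value into one of its four forms.

    Matching order: palette keyword, gradient keyword, up/down colors,
    explicit comma-separated color list.  Mixing forms (a keyword among
    explicit colors) is a syntax error.
    """
    t = text.strip()
    low = t.lower()
    if low in PALETTE_KEYWORDS:
        return ColorListSpec(mode="keyword", keyword=low)
    if low in GRADIENT_KEYWORDS:
        return ColorListSpec(mode="gradient_keyword", gradient_keyword=low)
    if ":" in t:
        parts = {}
        for piece in t.split(","):
            key, sep, val = piece.partition(":")
            key = key.strip().lower()
            if not sep or key not in ("up", "down", "zero"):
                raise InstructionSyntaxError(
                    f"bad up/down colorlist component {piece!r}"
                )
            if key in parts:
                raise DuplicateArgumentError(f"{key!r} given twice in colorlist")
            parts[key] = parse_color(val)
        if "up" not in parts or "down" not in parts:
            raise MissingArgumentError("up/down colorlist needs both up: and down:")
        return ColorListSpec(
            mode="updown",
            updown=UpDownColors(
                up=parts["up"], down=parts["down"], zero=parts.get("zero", BLACK)
            ),
        )
    tokens = [p.strip() for p in t.split(",")]
    for tok in tokens:
        if tok.lower() in PALETTE_KEYWORDS or tok.lower() in GRADIENT_KEYWORDS:
            raise InstructionSyntaxError(
                f"colorlist mixes keyword {tok!r} with explicit colors"
            )
    return ColorListSpec(mode="explicit", explicit=tuple(parse_color(p) for p in tokens))


def _parse_label_list(text: str) -> tuple[str, ...]:
    return tuple(p.strip() for p in text.split(","))


def _parse_value_list(text: str) -> tuple[float, ...]:
    return tuple(_parse_real(p, "values entry") for p in text.split(","))


def _parse_range(text: str) -> tuple[float, float]:
    parts = text.split(",")
    if len(parts) != 2:
        raise ArityError(f"range: expected 'min,max', got {text!r}")
    lo = _parse_real(parts[0], "range min")
    hi = _parse_real(parts[1], "range max")
    if lo >= hi:
        raise RangeBoundError(f"range min {lo} must be below max {hi}")
    return (lo, hi)


def _parse_ybase(text: str) -> str | float:
    t = text.strip().lower()
    if t in YBASE_KEYWORDS:
        return t
    v = _parse_real(t, "ybase")
    if not 0.0 <= v <= 1.0:
        raise RangeBoundError(f"ybase proportion {v} outside [0, 1]")
    return v


# ---------------------------------------------------------------------------
# schema
# ---------------------------------------------------------------------------

# common argument name -> parser producing the CommonArgs field value
_COMMON_PARSERS = {
    "attributelist": lambda v: tuple(p.strip() for p in v.split(",")),
    "values": _parse_value_list,
    "labels": _parse_label_list,
    "labelcolor": parse_color,
    "labelfont": lambda v: v,
    "labelsize": lambda v: _parse_real(v, "labelsize"),
    "labelstyle": lambda v: v,
    "range": _parse_range,
    "scale": lambda v: _parse_real(v, "scale"),
    "showlabels": lambda v: _parse_bool(v, "showlabels"),
    "ybase": _parse_ybase,
    "colorlist": parse_colorlist,
}

_ALL_COMMON = frozenset(_COMMON_PARSERS)

# which common arguments each prefix accepts
_COMMON_ALLOWED = {
    "barchart": _ALL_COMMON,
    "heatstripchart": _ALL_COMMON,
    "linechart": _ALL_COMMON,
    "piechart": _ALL_COMMON - {"range", "scale", "ybase"},
    "circoschart": _ALL_COMMON - {"range", "scale", "ybase"},
    "stripechart": frozenset({"colorlist"}),
    "lingrad": frozenset(),
    "radgrad": frozenset(),
}

# per-prefix chart arguments: name -> parser
_CHART_PARSERS = {
    "barchart": {"separation": lambda v: _parse_real(v, "separation")},
    "heatstripchart": {"separation": lambda v: _parse_real(v, "separation")},
    "linechart": {"linewidth": lambda v: _parse_real(v, "linewidth")},
    "piechart": {
        "arcstart": lambda v: _parse_real(v, "arcstart"),
        "sortslices": lambda v: _parse_bool(v, "sortslices"),
    },
    "circoschart": {
        "arcstart": lambda v: _parse_real(v, "arcstart"),
        "arcwidth": lambda v: _parse_proportion(v, "arcwidth"),
        "firstarc": lambda v: _parse_proportion(v, "firstarc"),
        "firstarcwidth": lambda v: _parse_proportion(v, "firstarcwidth"),
        "labelcircles": lambda v: _parse_bool(v, "labelcircles"),
        "sortslices": lambda v: _parse_bool(v, "sortslices"),
    },
    "stripechart": {},
    "lingrad": {
        "start": lambda v: _parse_point(v, "start"),
        "end": lambda v: _parse_point(v, "end"),
        "stoplist": parse_stoplist,
    },
    "radgrad": {
        "center": lambda v: _parse_point(v, "center"),
        "radius": lambda v: _parse_proportion(v, "radius"),
        "stoplist": parse_stoplist,
    },
}

# every argument name known anywhere, for unknown-vs-forbidden distinction
_ALL_ARG_NAMES = _ALL_COMMON | {
    name for parsers in _CHART_PARSERS.values() for name in parsers
}


def _parse_proportion(token: str, what: str) -> float:
    v = _parse_real(token, what)
    if not 0.0 <= v <= 1.0:
        raise RangeBoundError(f"{what}: {v} outside [0, 1]")
    return v


def parse_instruction(text: str) -> GlyphSpec:
    """Parse and validate one instruction string into a :class:`GlyphSpec`.

    Applies the per-prefix schema: forbidden arguments are rejected with
    the prefix and argument named, required arguments (stoplist for
    gradients, colorlist for stripe charts) are enforced, defaults are
    filled, and labels default to the attributelist names.
    """
    raw = tokenize_instruction(text)
    allowed_common = _COMMON_ALLOWED[raw.prefix]
    chart_parsers = _CHART_PARSERS[raw.prefix]

    common_kwargs: dict = {}
    chart_kwargs: dict = {}
    for name, value in raw.args:
        if name in chart_parsers:
            chart_kwargs[name] = chart_parsers[name](value)
        elif name in allowed_common:
            common_kwargs[name] = _COMMON_PARSERS[name](value)
        elif name in _ALL_ARG_NAMES:
            raise ForbiddenArgumentError(
                f"{raw.prefix} does not accept argument {name!r}"
            )
        else:
            raise UnknownArgumentError(f"unknown argument {name!r}")

    if "labelstyle" in common_kwargs and common_kwargs["labelstyle"] not in LABEL_STYLES:
        raise ValueTypeError(
            f"labelstyle {common_kwargs['labelstyle']!r} not in {LABEL_STYLES}"
        )
    if "labelsize" in common_kwargs and common_kwargs["labelsize"] <= 0:
        raise RangeBoundError("labelsize must be positive")
    if "scale" in common_kwargs and common_kwargs["scale"] <= 0:
        raise RangeBoundError("scale must be positive")
    if "values" in common_kwargs and "attributelist" in common_kwargs:
        raise InstructionSyntaxError(
            "give either values or attributelist, not both"
        )
    if raw.prefix == "heatstripchart" and "colorlist" in common_kwargs:
        cl = common_kwargs["colorlist"]
        if cl.mode not in ("gradient_keyword", "updown"):
            raise ValueTypeError(
                "heatstripchart colorlist must be a gradient keyword or up/down colors"
            )

    common = CommonArgs(**common_kwargs)
    # labels default to attribute names
    if common.labels is None and common.attributelist is not None:
        common = replace(common, labels=common.attributelist)

    if raw.prefix in ("lingrad", "radgrad") and "stoplist" not in chart_kwargs:
        raise MissingArgumentError(f"{raw.prefix} requires a stoplist")
    if raw.prefix == "stripechart" and common.colorlist is None:
        raise MissingArgumentError(
            "stripechart requires a colorlist (it defines the stripes)"
        )

    chart_args = CHART_ARG_TYPES[raw.prefix](**chart_kwargs)
    return GlyphSpec(prefix=raw.prefix, common=common, chart_args=chart_args)


# ---------------------------------------------------------------------------
# canonical serialization
# ---------------------------------------------------------------------------

_COMMON_ORDER = (
    "attributelist",
    "values",
    "labels",
    "labelcolor",
    "labelfont",
    "labelsize",
    "labelstyle",
    "range",
    "scale",
    "showlabels",
    "ybase",
    "colorlist",
)

_CHART_ORDER = {
    "barchart": ("separation",),
    "heatstripchart": ("separation",),
    "linechart": ("linewidth",),
    "piechart": ("arcstart", "sortslices"),
    "circoschart": (
        "arcstart",
        "arcwidth",
        "firstarc",
        "firstarcwidth",
        "labelcircles",
        "sortslices",
    ),
    "stripechart": (),
    "lingrad": ("start", "end", "stoplist"),
    "radgrad": ("center", "radius", "stoplist"),
}


def _fmt_real(v: float) -> str:
    return str(float(v))


def _fmt_colorlist(cl: ColorListSpec) -> str:
    if cl.mode == "keyword":
        return cl.keyword
    if cl.mode == "gradient_keyword":
        return cl.gradient_keyword
    if cl.mode == "updown":
        ud = cl.updown
        return f"up:{ud.up.to_hex()},down:{ud.down.to_hex()},zero:{ud.zero.to_hex()}"
    return ",".join(c.to_hex() for c in cl.explicit)


def _fmt_common(name: str, value) -> str:
    if name in ("attributelist", "labels"):
        return ",".join(value)
    if name == "values":
        return ",".join(_fmt_real(v) for v in value)
    if name == "labelcolor":
        return value.to_hex()
    if name == "range":
        return f"{_fmt_real(value[0])},{_fmt_real(value[1])}"
    if name in ("scale", "labelsize"):
        return _fmt_real(value)
    if name == "showlabels":
        return "true" if value else "false"
    if name == "ybase":
        return value if isinstance(value, str) else _fmt_real(value)
    if name == "colorlist":
        return _fmt_colorlist(value)
    return str(value)


def _fmt_chart(name: str, value) -> str:
    if name in ("start", "end", "center"):
        return f"{_fmt_real(value[0])},{_fmt_real(value[1])}"
    if name == "stoplist":
        return "|".join(
            f"{s.color.r},{s.color.g},{s.color.b},{s.color.a},{_fmt_real(s.position)}"
            for s in value
        )
    if isinstance(value, bool):
        return "true" if value else "false"
    return _fmt_real(value)


def serialize_instruction(spec: GlyphSpec) -> str:
    """Emit the canonical text of a spec (fixed order, quoted values).

    Arguments equal to their defaults are omitted; ``parse_instruction``
    restores them, so ``parse(serialize(s)) == s`` and serialization is
    idempotent under re-parsing.
    """
    defaults_common = CommonArgs()
    parts: list[str] = []
    for name in _COMMON_ORDER:
        if name not in _COMMON_ALLOWED[spec.prefix]:
            continue
        value = getattr(spec.common, name)
        if value == getattr(defaults_common, name):
            continue
        if name == "labels" and value == spec.common.attributelist:
            continue  # re-derived at parse time
        parts.append(f'{name}="{_fmt_common(name, value)}"')
    chart_defaults = (
        None
        if spec.prefix in ("lingrad", "radgrad")
        else CHART_ARG_TYPES[spec.prefix]()
    )
    for name in _CHART_ORDER[spec.prefix]:
        value = getattr(spec.chart_args, name)
        if chart_defaults is not None and value == getattr(chart_defaults, name):
            continue
        if spec.prefix in ("lingrad", "radgrad"):
            fld = {f.name: f for f in LinGradArgs.__dataclass_fields__.values()} \
                if spec.prefix == "lingrad" else \
                {f.name: f for f in RadGradArgs.__dataclass_fields__.values()}
            default = fld[name].default
            if name != "stoplist" and value == default:
                continue
        parts.append(f'{name}="{_fmt_chart(name, value)}"')
    body = " ".join(parts)
    return f"{spec.prefix}: {body}" if body else f"{spec.prefix}:"
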