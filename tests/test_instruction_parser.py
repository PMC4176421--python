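"""Grammar, typed validation, and canonical serialization."""

import itertools

import pytest
from hypothesis import given, settings, strategies as st

from nodeglyphs import (
    RGBA,
    GlyphError,
    GradientStop,
    parse_color,
    parse_colorlist,
    parse_instruction,
    parse_stoplist,
    serialize_instruction,
    tokenize_instruction,
)
from nodeglyphs.errors import (
    ArityError,
    ColorParseError,
    DuplicateArgumentError,
    ForbiddenArgumentError,
    InstructionSyntaxError,
    MissingArgumentError,
    RangeBoundError,
    UnknownArgumentError,
    UnknownTypeError,
)
from nodeglyphs.instruction_parser import (
    BarArgs,
    CircosArgs,
    LinGradArgs,
    PieArgs,
)

from conftest import WORKED_HEATSTRIP


class TestTokenize:
    def test_basic_pairs(self):
        raw = tokenize_instruction('piechart: values="1,1,2" colorlist="rainbow"')
        assert raw.prefix == "piechart"
        assert raw.args == (("values", "1,1,2"), ("colorlist", "rainbow"))

    def test_worked_heatstrip_tokens(self):
        raw = tokenize_instruction(WORKED_HEATSTRIP)
        assert raw.prefix == "heatstripchart"
        assert dict(raw.args) == {
            "attributelist": "gal1RGexp,gal4RGexp,gal80Rexp",
            "colorlist": "yellowblue",
            "range": "-3.0,3.0",
        }

    def test_unknown_prefix_named_in_error(self):
        with pytest.raises(UnknownTypeError, match="donut"):
            tokenize_instruction('donut: values="1"')

    def test_quoted_value_keeps_spaces_and_equals(self):
        raw = tokenize_instruction('barchart: labels="a=1, b 2"')
        assert raw.args == (("labels", "a=1, b 2"),)

    def test_bare_value_runs_to_whitespace(self):
        raw = tokenize_instruction("piechart: arcstart=90 sortslices=true")
        assert dict(raw.args) == {"arcstart": "90", "sortslices": "true"}

    def test_duplicate_argument_rejected(self):
        with pytest.raises(DuplicateArgumentError):
            tokenize_instruction('piechart: values="1" values="2"')

    def test_unterminated_quote_reports_offset(self):
        with pytest.raises(InstructionSyntaxError) as err:
            tokenize_instruction('piechart: values="1,2')
        assert err.value.offset == len("piechart: values=")

    def test_prefix_case_folds_to_lowercase(self):
        assert tokenize_instruction('PieChart: values="1"').prefix == "piechart"

    def test_missing_colon_is_syntax_error(self):
        with pytest.raises(InstructionSyntaxError):
            tokenize_instruction("piechart values=1")


class TestParseColor:
    @pytest.mark.parametrize(
        "token,expected",
        [
            ("#FF0000", RGBA(255, 0, 0, 255)),
            ("#00000080", RGBA(0, 0, 0, 128)),
            ("#ff00Ff", RGBA(255, 0, 255, 255)),
            ("red", RGBA(255, 0, 0, 255)),
            ("Blue", RGBA(0, 0, 255, 255)),
        ],
    )
    def test_valid_tokens(self, token, expected):
        assert parse_color(token) == expected

    @pytest.mark.parametrize("token", ["blurple", "#12345", "#GG0000", ""])
    def test_invalid_tokens(self, token):
        with pytest.raises(ColorParseError):
            parse_color(token)


class TestParseStoplist:
    def test_two_stop_decode(self):
        stops = parse_stoplist("255,0,0,255,0|0,0,255,255,1")
        assert stops == (
            GradientStop(RGBA(255, 0, 0, 255), 0.0),
            GradientStop(RGBA(0, 0, 255, 255), 1.0),
        )

    def test_sorted_by_position(self):
        stops = parse_stoplist("255,255,0,255,0.5|255,0,0,255,0.0")
        assert [s.position for s in stops] == [0.0, 0.5]
        assert stops[0].color == RGBA(255, 0, 0, 255)

    def test_component_256_rejected(self):
        with pytest.raises(RangeBoundError):
            parse_stoplist("0,0,0,256,0")

    def test_position_above_one_rejected(self):
        with pytest.raises(RangeBoundError):
            parse_stoplist("0,0,0,255,1.5")

    def test_wrong_arity_rejected(self):
        with pytest.raises(ArityError):
            parse_stoplist("255,0,0,0.5")


class TestParseColorlist:
    def test_keyword(self):
        cl = parse_colorlist("rainbow")
        assert cl.mode == "keyword" and cl.keyword == "rainbow"

    def test_gradient_keyword(self):
        cl = parse_colorlist("yellowblue")
        assert cl.mode == "gradient_keyword" and cl.gradient_keyword == "yellowblue"

    def test_updown_with_default_zero(self):
        cl = parse_colorlist("up:red,down:blue")
        assert cl.mode == "updown"
        assert cl.updown.up == RGBA(255, 0, 0, 255)
        assert cl.updown.down == RGBA(0, 0, 255, 255)
        assert cl.updown.zero == RGBA(0, 0, 0, 255)

    def test_explicit_colors(self):
        cl = parse_colorlist("red,#00FF00,blue")
        assert cl.mode == "explicit" and len(cl.explicit) == 3

    def test_mixed_forms_rejected(self):
        with pytest.raises(InstructionSyntaxError):
            parse_colorlist("rainbow,red")


class TestParseInstruction:
    def test_lingrad_schema(self):
        spec = parse_instruction(
            'lingrad: start="0,0" end="1,0" stoplist="255,255,255,255,0|0,0,255,255,1"'
        )
        assert spec.prefix == "lingrad"
        assert isinstance(spec.chart_args, LinGradArgs)
        assert spec.chart_args.start == (0.0, 0.0)
        assert spec.chart_args.end == (1.0, 0.0)
        assert len(spec.chart_args.stoplist) == 2

    @pytest.mark.parametrize("arg", ['range="0,10"', "scale=2", "ybase=middle"])
    @pytest.mark.parametrize("prefix", ["piechart", "circoschart"])
    def test_pie_and_circos_forbid_scaling_args(self, prefix, arg):
        with pytest.raises(ForbiddenArgumentError):
            parse_instruction(f'{prefix}: values="1,2" {arg}')

    def test_circos_rings(self):
        spec = parse_instruction(
            'circoschart: attributelist="Circle1,Circle2" firstarc=0.4 arcwidth=0.3'
        )
        assert isinstance(spec.chart_args, CircosArgs)
        assert spec.common.attributelist == ("Circle1", "Circle2")
        assert spec.chart_args.firstarc == 0.4

    def test_stripe_accepts_only_colorlist(self):
        parse_instruction('stripechart: colorlist="red,green"')
        with pytest.raises(ForbiddenArgumentError):
            parse_instruction('stripechart: colorlist="red" showlabels=false')

    def test_stripe_requires_colorlist(self):
        with pytest.raises(MissingArgumentError):
            parse_instruction("stripechart:")

    def test_gradient_requires_stoplist(self):
        with pytest.raises(MissingArgumentError):
            parse_instruction('lingrad: start="0,0" end="1,1"')

    def test_unknown_argument_is_hard_error(self):
        with pytest.raises(UnknownArgumentError):
            parse_instruction('piechart: values="1" colourlist="rainbow"')

    def test_values_and_attributelist_together_rejected(self):
        with pytest.raises(InstructionSyntaxError):
            parse_instruction('barchart: values="1" attributelist="a"')

    def test_labels_default_to_attribute_names(self):
        spec = parse_instruction('barchart: attributelist="a,b,c"')
        assert spec.common.labels == ("a", "b", "c")

    def test_scientific_notation_rejected(self):
        with pytest.raises(GlyphError):
            parse_instruction('barchart: values="1e-3,2"')

    def test_heatstrip_rejects_plain_keyword_colorlist(self):
        with pytest.raises(GlyphError):
            parse_instruction('heatstripchart: values="1" colorlist="rainbow"')

    def test_argument_order_never_matters(self):
        args = ['values="1,2,3"', 'colorlist="rainbow"', "arcstart=45", "sortslices=true"]
        specs = {
            repr(parse_instruction("piechart: " + " ".join(p)))
            for p in itertools.permutations(args)
        }
        assert len(specs) == 1


class TestSerialize:
    def test_canonical_pie(self):
        spec = parse_instruction('piechart: values="1,1,2"')
        assert serialize_instruction(spec) == 'piechart: values="1.0,1.0,2.0"'

    def test_worked_heatstrip_round_trip(self):
        spec = parse_instruction(WORKED_HEATSTRIP)
        assert parse_instruction(serialize_instruction(spec)) == spec

    def test_serialization_is_idempotent(self):
        spec = parse_instruction(
            'circoschart: attributelist="Circle1,Circle2" firstarc=0.4 '
            'colorlist="up:red,down:blue" sortslices=true'
        )
        once = serialize_instruction(spec)
        assert serialize_instruction(parse_instruction(once)) == once


# --- property tests ---------------------------------------------------------

# grammar-friendly atoms: names without separators, numbers without exponents
_names = st.from_regex(r"[A-Za-z][A-Za-z0-9_]{0,8}", fullmatch=True)
_props = st.integers(0, 100).map(lambda k: k / 100)
_rgba = st.builds(
    RGBA,
    st.integers(0, 255),
    st.integers(0, 255),
    st.integers(0, 255),
    st.integers(0, 255),
)
_stops = st.lists(st.builds(GradientStop, _rgba, _props), min_size=1, max_size=4).map(
    lambda xs: tuple(sorted(xs, key=lambda s: s.position))
)
_colorlists = st.one_of(
    st.sampled_from(["contrasting", "modulated", "rainbow", "random"]),
    st.sampled_from(["yellowblue", "redyellow", "bluegreenyellow"]),
    st.just("up:red,down:blue,zero:gray"),
    st.lists(_rgba, min_size=1, max_size=4).map(
        lambda cs: ",".join(c.to_hex() for c in cs)
    ),
)
_values = st.lists(
    st.integers(-300, 300).map(lambda k: k / 10), min_size=1, max_size=6
).map(lambda vs: ",".join(str(v) for v in vs))


@st.composite
def instruction_strings(draw):
    prefix = draw(st.sampled_from(["barchart", "linechart", "piechart", "heatstripchart"]))
    parts = [f'values="{draw(_values)}"']
    if prefix == "heatstripchart":
        parts.append('colorlist="yellowblue"')
    else:
        parts.append(f'colorlist="{draw(_colorlists)}"')
    if prefix in ("barchart", "linechart"):
        if draw(st.booleans()):
            lo = draw(st.integers(-50, -1))
            hi = draw(st.integers(0, 50))
            parts.append(f'range="{lo}.0,{hi}.5"')
        if draw(st.booleans()):
            parts.append(f'ybase="{draw(_props)}"')
        if draw(st.booleans()):
            parts.append(f'scale="{draw(st.integers(1, 40))}.5"')
    if draw(st.booleans()):
        parts.append(f'showlabels={"true" if draw(st.booleans()) else "false"}')
    if draw(st.booleans()):
        parts.append(f'labels="{",".join(draw(st.lists(_names, min_size=1, max_size=3)))}"')
    return f"{prefix}: " + " ".join(parts)


@given(instruction_strings())
@settings(max_examples=300, deadline=None)
def test_parse_serialize_round_trip(text):
    """parse(serialize(s)) == s over generated chart instructions."""
    spec = parse_instruction(text)
    again = parse_instruction(serialize_instruction(spec))
    assert again == spec


@given(_stops)
@settings(max_examples=100, deadline=None)
def test_gradient_round_trip(stops):
    text = 'lingrad: start="0,0" end="0,1" stoplist="' + "|".join(
        f"{s.color.r},{s.color.g},{s.color.b},{s.color.a},{s.position}" for s in stops
    ) + '"'
    spec = parse_instruction(text)
    assert parse_instruction(serialize_instruction(spec)) == spec
    positions = [s.position for s in spec.chart_args.stoplist]
    assert positions == sorted(positions)


@given(st.text(max_size=60))
@settings(max_examples=300, deadline=None)
def test_parsing_is_total(text):
    """Arbitrary text either parses or raises exactly a typed GlyphError."""
    try:
        parse_instruction(text)
    except GlyphError:
        pass
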