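"""Typed error hierarchy.

Every failure mode in the instruction grammar, the color engine, the
geometry layer and the I/O layer raises a distinct subclass of
:class:`GlyphError`, so callers (and the CLI) can report *what kind* of
mistake a user made rather than a generic message.  Nothing in the
package clamps or silently repairs invalid input; out-of-range *data*
values are the single, documented exception (they clamp and log).
"""

from __future__ import annotations


class GlyphError(Exception):
    """Base class for all nodeglyphs errors."""


# --- instruction grammar ---------------------------------------------------

class InstructionSyntaxError(GlyphError):
    """Malformed instruction text (e.g. unterminated quote).

    Carries ``offset``, the 0-based character position of the problem.
    """

    def __init__(self, message: str, offset: int | None = None):
        super().__init__(message if offset is None else f"{message} (at offset {offset})")
        self.offset = offset


class UnknownTypeError(GlyphError):
    """Instruction prefix is not a registered gradient or chart type."""


class DuplicateArgumentError(GlyphError):
    """The same argument name appears twice in one instruction."""


class UnknownArgumentError(GlyphError):
    """Argument name not recognised for any glyph type."""


class ForbiddenArgumentError(GlyphError):
    """Argument is valid in general but not for this prefix."""


class MissingArgumentError(GlyphError):
    """A required argument (e.g. stoplist for gradients) is absent."""


class ValueTypeError(GlyphError):
    """Argument value cannot be parsed as its declared type."""


class ColorParseError(GlyphError):
    """Color token is neither a known name nor valid hex."""


class RangeBoundError(GlyphError):
    """A numeric component lies outside its permitted interval."""


class ArityError(GlyphError):
    """A delimited group has the wrong number of fields."""


# --- color engine ----------------------------------------------------------

class UnknownKeywordError(GlyphError):
    """Colorlist / gradient keyword not in the registered set."""


class EmptyPaletteError(GlyphError):
    """A palette of zero colors was requested."""


class MissingValueError(GlyphError):
    """NaN handed to an operation that needs a definite sign."""


# --- geometry --------------------------------------------------------------

class MissingAttributeError(GlyphError):
    """A node lacks a column named by attributelist."""


class NegativeSliceError(GlyphError):
    """Pie/circos value below zero."""


class DegeneratePieError(GlyphError):
    """All pie values are zero; no slice layout exists."""


class LayoutOverflowError(GlyphError):
    """Geometry (bars + separation, circos rings) exceeds the unit box."""


class TooFewPointsError(GlyphError):
    """Line chart needs at least two points."""


class DegenerateAxisError(GlyphError):
    """Linear gradient with coincident start and end."""


# --- composition / rendering ----------------------------------------------

class SlotOverflowError(GlyphError):
    """More than nine glyphs composed on one node."""


class DuplicateSlotError(GlyphError):
    """Two glyphs assigned the same slot on one node."""


class CapabilityError(GlyphError):
    """An optional capability (rasterizer) is unavailable."""


# --- I/O -------------------------------------------------------------------

class NetworkParseError(GlyphError):
    """Malformed GraphML/SIF input."""


class DuplicateIdError(GlyphError):
    """Node table contains the same node id twice."""


class RowArityError(GlyphError):
    """Node table row has the wrong number of cells."""


class ConfigError(GlyphError):
    """Slot-mapping config is invalid."""
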