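# Methods

`nodeglyphs` draws small data-driven charts ("glyphs") on network nodes.
Each glyph is specified by a one-line instruction string kept in a
node-table column — `type: name=value ...` — so the figure specification
travels with the data. The package parses those strings, resolves the
referenced table columns, lays the chart out in a node-local coordinate
system, composes up to nine glyphs per node, and emits SVG. This note
records the model, the conventions the package fixes where the format
itself leaves them open, and what the bundled synthetic fixtures do and
do not exercise.

## The instruction language

Eight glyph types are registered: two gradients (`lingrad`, `radgrad`)
and six charts (`barchart`, `circoschart`, `heatstripchart`,
`linechart`, `piechart`, `stripechart`). The grammar is specified in
`grammar.md`. Parsing is deliberately strict:

* unknown prefixes and unknown argument names are hard errors, never
  warnings — a silent typo (`colourlist`) would otherwise produce a
  plausible but wrong figure;
* color components outside [0, 255] and proportions outside [0, 1]
  raise typed errors rather than clamping — only *data* values clamp
  (see normalization below);
* `values` and `attributelist` are mutually exclusive;
* `piechart`/`circoschart` reject `range`, `scale` and `ybase` (their
  geometry is purely proportional), and `stripechart` accepts only
  `colorlist`;
* prefixes are case-folded to lowercase; the canonical serialized form
  is always lowercase.

Numeric literals are plain integers or decimals; exponent notation is
rejected so that the canonical serialization (`serialize_instruction`)
round-trips exactly: `parse(serialize(s)) == s` for every valid spec,
and serialization is idempotent under re-parsing. Named colors resolve
through the standard CSS/X11 table; `#RRGGBB` hex implies alpha 255.
An up/down colorlist without an explicit `zero:` entry defaults the
zero color to opaque black.

## Color

All interpolation is componentwise-linear in RGBA space with half-up
rounding, alpha included. RGBA interpolation is the simplest convention
a user can verify by hand from the stop values; no perceptual
(CIELAB/HSV) path is offered in this version.

Palette keywords (defaults a scientist can reproduce exactly):

| keyword | definition | default |
|---|---|---|
| `rainbow` | n hues at `i/n` around the HSV wheel, S = V = 1 | — |
| `contrasting` | hues stepped by the golden angle (≈137.508°) from 0°, S = V = 1 | chart default when no colorlist is given |
| `modulated` | rainbow hues with S and V alternating between 1.0 and 0.6 | — |
| `random` | n uniform hues from a seeded generator (reproducible across runs and platforms) | — |

The exact palette formulas of `contrasting` and `modulated` are this
package's own deterministic conventions: the keyword names constrain
the intent (maximal separation; alternating modulation) but not a
formula, so we fixed order-free, seedless definitions and document them
here. Heat strips, which need a signed ramp rather than a categorical
palette, default to `up:red,down:blue,zero:black` when no colorlist is
given.

Gradient keywords (`yellowblue`, `redyellow`, …) expand to 2- or
3-anchor ramps over a normalized value t ∈ [−1, 1]: the **first** named
color sits at t = +1 (positive extreme), the last at t = −1, and
3-anchor ramps (`bluegreenyellow`) pin the middle color exactly at
t = 0. A 2-anchor ramp's zero color is the midpoint of its anchors
(`yellowblue` → (128,128,128)). The first-color-positive orientation is
a fixed convention of this package; users who want the opposite can use
an up/down colorlist.

## Geometry

All chart layout happens in the **unit box**: x, y ∈ [0, 1], origin
top-left, y increasing downward. Composition later maps the unit box
onto the node's bounding box, so geometry is resolution-independent.

**Value normalization** (the `range` argument, "consistent scaling
across all nodes"): when the range (min, max) straddles zero,
t = v / max(|min|, |max|), so 0 always lands on the chart baseline and
t is signed in [−1, 1]; otherwise [min, max] maps affinely onto [0, 1].
When `range` is absent the per-node series extremes are used instead
(per-node autoscale); a constant series widens its range by ±1 so t is
defined. Data values outside the range **clamp** to the boundary with a
logged warning — a single outlier should not abort a figure. NaN values
produce zero-extent elements, also logged.

**Angles**: `arcstart = 0` points at 12 o'clock and slices advance
clockwise. Pie slice extents are `360·vᵢ/Σv`; `sortslices` orders
slices largest-first, stable on ties. Negative values and all-zero
series are errors for pie/circos.

**Circos rings**: radial arguments (`firstarc`, `firstarcwidth`,
`arcwidth`) are read as node-*diameter* fractions and halved into
radius units (max 0.5), because "proportion of the entire node" most
naturally means the full width. Ring 0 spans
[firstarc/2, firstarc/2 + firstarcwidth/2]; each later ring adds
arcwidth/2. Rings that would exceed the unit box raise an overflow
error. Circle labels, when requested, sit at ring mid-radius — the
original convention is unrecoverable, so this package fixes one.

**Bars and heat strips**: n equal-width bars fill the x-axis with
`separation` between them. `separation` and `linewidth` are given in
reference units of a 100×100 node box and divided by 100 — the format
states no units, and whole-number separations against a 100-unit box
match how users write them. The baseline sits at y = 0 (`ybase=top`),
0.5 (`middle`), 1 (`bottom`, the default) or any given proportion;
positive t grows upward from the baseline, negative t downward into the
remaining space (`ybase` relocates the baseline only; it never flips
direction). A heat strip reuses bar geometry exactly — only the fill
differs: a vertical gradient from the ramp color at t (tip) to the
ramp's zero color (baseline). Note that with the default bottom
baseline, negative values have no room to grow and render as zero-height
bars; signed data reads best with `ybase=middle`.

**Lines**: point i at x = i/(n−1), y from the same baseline mapping;
at least two points required.

**Stripes**: n equal vertical stripes in palette order. An explicit
colorlist gives n; an up/down list gives three stripes (up, zero,
down); a palette keyword defaults to eight stripes (the keyword alone
does not determine a count — a documented convention).

**Gradients** fill the node shape itself. A linear gradient runs along
the axis from `start` to `end` (unit-box proportions; coincident points
are a degenerate-axis error); a radial gradient has a proportional
center and radius. Stop lists are sorted by position at parse time, and
positions outside the stop range clamp to the nearest stop's color.

## Composition and rendering

A node composes 1–9 glyph scenes, one per *slot*. Slots form a 3×3
grid: slot 1 at the node centre, slots 2–9 stepping clockwise through
the compass points (N, NE, E, SE, S, SW, W, NW) at one node-size unit
offset. Later slots draw above earlier ones; a tenth scene or a
duplicated slot is an error. Each scene is scaled by its spec's
`scale` about its own centre exactly once, at composition (the layout
functions accept a scale parameter for standalone use, but the pipeline
passes 1.0 there to avoid double application).

SVG output is deterministic: identical inputs yield byte-identical
documents, and gradient ids derive from node id and element index so
diffs of rendered files are meaningful. Chart primitives precede label
text (labels draw on top); bar labels sit above the tip when there is
headroom and below the bar otherwise; slice labels sit at mid-angle,
mid-radius. Unresolvable label fonts fall back to a default sans face
with a logged warning. Raster preview (`render_raster`) needs the
optional `cairosvg` package and raises a typed capability error with an
install hint when it is absent.

## Synthetic fixtures

`generate_fixture` builds the two demo datasets:

* **gallery** — nodes carry integer columns `a`–`d` (uniform on
  1–10), list columns `Values` (5 reals in [−3, 3]), `Circle1`/`Circle2`
  (4 positive reals each), and eight instruction columns, one per glyph
  type, so a single render exercises the whole language;
* **expression** — a small connected protein-interaction-style network
  whose nodes carry three expression-log-ratio-like columns
  (`gal1RGexp`, `gal4RGexp`, `gal80Rexp`), drawn from a seeded normal
  (σ = 1.2) clipped to [−3, 3], plus one heat-strip instruction column
  using the fixed range (−3, 3) for cross-node comparability.

Both are bit-reproducible for a fixed seed. They emulate the *shape* of
real Cytoscape exports (scalar and `|`-delimited list columns, raw
instruction text), not real biology: values are independent draws, the
topology is a spanning path with a few extra edges, and there are no
missing values or mixed-type columns, so passing tests demonstrate
correctness of parsing/layout/rendering, not robustness to dirty
real-world tables (missing cells are, however, covered separately by
the NaN handling above).

Default problem sizes (9-node gallery, 20-node expression network,
≤1000-case property sweeps) keep the full suite and the acceptance
script in the tens of seconds while exercising every code path.

## Known limitations

* No GUI and no PDF/EPS export; SVG (plus optional PNG preview) only.
* Interpolation is linear RGBA, not perceptually uniform.
* Node shapes are rectangle and ellipse only; gradient clipping beyond
  those shapes is out of scope.
* One instruction per column: instructions spread across multiple
  columns are not supported.
* The `contrasting`/`modulated` palettes and the slot-offset grid are
  this package's own conventions; figures are reproducible within the
  package but not pixel-compatible with other implementations of the
  same instruction language (fonts and renderers differ regardless).
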