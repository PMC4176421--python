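# nodeglyphs

Data-driven charts and gradient paints ("glyphs") on network nodes,
rendered to resolution-independent SVG.

Network figures in systems biology routinely need more than one value
per node: expression log-ratios across conditions, domain coverage,
cluster membership, sequence-coverage profiles. Coloring a node encodes
one number; a small chart drawn *on* the node encodes several.
`nodeglyphs` implements that idea as a standalone library and CLI: each
glyph is specified by a compact instruction string held in a node-table
column, for example

```
heatstripchart: attributelist="gal1RGexp,gal4RGexp,gal80Rexp" colorlist="yellowblue" range="-3.0,3.0"
```

so the figure specification lives next to the data and survives export,
diffing and version control. Eight glyph types are supported — linear
and radial gradients (`lingrad`, `radgrad`) and six charts (`barchart`,
`circoschart`, `heatstripchart`, `linechart`, `piechart`,
`stripechart`) — and up to nine glyphs compose on a single node via
positional slots. The complete grammar is in
[docs/grammar.md](docs/grammar.md); the model, conventions and
limitations are in [docs/methods.md](docs/methods.md).

## The model in brief

Chart values come from a literal `values` list or from node-table
columns named in `attributelist`. Each value v is normalized against a
range (min, max): t = v / max(|min|, |max|) when the range straddles
zero (so 0 sits on the chart baseline, t ∈ [−1, 1]), affinely onto
[0, 1] otherwise; a shared `range` gives consistent scaling across all
nodes. Geometry is computed in a node-local unit box and mapped onto
each node's bounding box at composition, so output scales to any
resolution. Pie/donut slice extents are 360·vᵢ/Σv; heat strips are
up/down bars filled with a color ramp (e.g. `yellowblue`: yellow at
t = +1, blue at t = −1, their midpoint at 0). Parsing is strict — typos
and out-of-range color components are typed errors, never silent
repairs.

## Worked example

Three yeast expression columns drive a heat strip with a fixed ±3
range and a mid-node baseline:

```python
from nodeglyphs import NodeRecord, parse_instruction, normalize_value, layout_glyph

instruction = (
    'heatstripchart: attributelist="gal1RGexp,gal4RGexp,gal80Rexp" '
    'colorlist="yellowblue" range="-3.0,3.0" ybase="middle"'
)
spec = parse_instruction(instruction)
node = NodeRecord("YBR020W", scalars={"gal1RGexp": -2.4, "gal4RGexp": 0.3, "gal80Rexp": 1.8})
for col, bar in zip(spec.common.attributelist, layout_glyph(spec, node)):
    v = node.scalars[col]
    t = normalize_value(v, spec.common.range)
    tip = bar.fill.top if t >= 0 else bar.fill.bottom
    print(f"{col}: value={v:+.1f}  t={t:+.2f}  bar y=[{bar.y0:.2f}, {bar.y1:.2f}]  tip={tip.to_hex()}")
```

prints

```
gal1RGexp: value=-2.4  t=-0.80  bar y=[0.50, 0.90]  tip=#1A1AE6
gal4RGexp: value=+0.3  t=+0.10  bar y=[0.45, 0.50]  tip=#8C8C73
gal80Rexp: value=+1.8  t=+0.60  bar y=[0.20, 0.50]  tip=#CCCC33
```

Each line is one bar: the −2.4 value normalizes to t = −0.8, so its bar
hangs below the 0.5 baseline and its tip is 80% of the way from the
gray ramp-midpoint to pure blue (`#1A1AE6`); the +1.8 value rises above
the baseline toward yellow (`#CCCC33`). A value of ±3.0 would reach
pure blue `#0000FF` / pure yellow `#FFFF00` exactly.

## Command line

```sh
# render a network: instruction columns are assigned to glyph slots in a YAML config
nodeglyphs render --network net.graphml --table nodes.tsv --config slots.yaml --out figure.svg

# lint one instruction column (per-row status, first error)
nodeglyphs validate --table nodes.tsv --column chart

# write the built-in example figures (seeded, reproducible)
nodeglyphs demo --out demo/ --seed 1
```

A minimal `slots.yaml`:

```yaml
mapping:
  chart: 1        # column "chart" draws at the node centre (slot 1)
canvas: {width: 800, height: 600}
```

`demo` writes `gallery.svg` (one network whose nodes carry all eight
glyph types) and `expression.svg` (heat strips of three expression
columns on a small protein-interaction-style network), together with
the generated node tables.

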