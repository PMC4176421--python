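"""Network, node-table and config I/O, plus seeded demo fixtures.

Networks come in as GraphML (attributes imported as scalar columns) or
SIF (topology only, so a node table is mandatory).  Node tables are
delimited text with the node id in the first column; cells containing
the list delimiter (default ``|``) parse as list-of-real columns,
numeric cells as scalar reals, everything else — including glyph
instruction strings — as text.

The fixture generator builds the two demo datasets the package ships
with: a *gallery* network whose nodes carry integer columns a–d, list
columns Values/Circle1/Circle2 and one instruction column per glyph
type, and an *expression* network with three expression-like columns in
[-3, 3] driving a single heat-strip instruction.  Both are
bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
import yaml

from .errors import (
    ConfigError,
    DuplicateIdError,
    DuplicateSlotError,
    NetworkParseError,
    RowArityError,
)
from .glyph_geometry import NodeRecord

DEFAULT_NODE_SIZE = (60.0, 40.0)

EXPRESSION_INSTRUCTION = (
    'heatstripchart: attributelist="gal1RGexp,gal4RGexp,gal80Rexp" '
    'colorlist="yellowblue" range="-3.0,3.0"'
)


@dataclass
class Network:
    nodes: list[NodeRecord]
    edges: list[tuple[str, str, str | None]] = field(default_factory=list)
    layout: dict = field(default_factory=dict)  # id -> (x, y, w, h)

    def node_ids(self) -> list[str]:
        return [n.node_id for n in self.nodes]

    def with_table(self, records: dict[str, NodeRecord]) -> "Network":
        """Merge table columns into this network's node records."""
        merged = []
        for node in self.nodes:
            extra = records.get(node.node_id)
            if extra is None:
                merged.append(node)
                continue
            merged.append(
                NodeRecord(
                    node_id=node.node_id,
                    scalars={**node.scalars, **extra.scalars},
                    lists={**node.lists, **extra.lists},
                )
            )
        return replace(self, nodes=merged)


@dataclass(frozen=True)
class SlotMapping:
    entries: tuple[tuple[str, int], ...]  # (instruction column, slot 1-9)

    def __post_init__(self):
        slots = [s for _, s in self.entries]
        if len(set(slots)) != len(slots):
            raise DuplicateSlotError("config maps two columns to the same slot")
        for col, s in self.entries:
            if not 1 <= s <= 9:
                raise ConfigError(f"column {col!r} mapped to slot {s}, outside 1..9")


@dataclass(frozen=True)
class RenderConfig:
    mapping: SlotMapping
    canvas: tuple[float, float] = (800.0, 600.0)
    node_shape: str = "ellipse"
    node_size: tuple[float, float] = DEFAULT_NODE_SIZE
    seed: int = 0


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_network(path: str, fmt: str | None = None) -> Network:
    """Read a GraphML or SIF network.

    GraphML data keys become scalar columns; SIF gives topology only.
    The format is inferred from the extension when not given.
    """
    if fmt is None:
        fmt = "sif" if str(path).lower().endswith(".sif") else "graphml"
    if fmt == "graphml":
        try:
            g = nx.read_graphml(path)
        except Exception as exc:
            raise NetworkParseError(f"cannot parse GraphML {path}: {exc}") from exc
        nodes = []
        layout = {}
        for nid, data in sorted(g.nodes(data=True)):
            scalars = {}
            for key, val in data.items():
                if key in ("x", "y", "width", "height"):
                    continue
                scalars[key] = val
            nodes.append(NodeRecord(node_id=str(nid), scalars=scalars))
            if "x" in data and "y" in data:
                layout[str(nid)] = (
                    float(data["x"]),
                    float(data["y"]),
                    float(data.get("width", DEFAULT_NODE_SIZE[0])),
                    float(data.get("height", DEFAULT_NODE_SIZE[1])),
                )
        edges = [(str(u), str(v), None) for u, v in sorted(g.edges())]
        return Network(nodes=nodes, edges=edges, layout=layout)
    if fmt == "sif":
        return _read_sif(path)
    raise NetworkParseError(f"unknown network format {fmt!r}")


def _read_sif(path: str) -> Network:
    """SIF: whitespace-delimited `source interaction target [target...]`
    lines; a bare id on a line declares an isolated node."""
    ids: dict[str, None] = {}
    edges: list[tuple[str, str, str | None]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) == 1:
                ids.setdefault(parts[0])
                continue
            if len(parts) == 2:
                raise NetworkParseError(
                    f"{path}:{lineno}: SIF line has a source and interaction "
                    "but no target"
                )
            src, interaction, *targets = parts
            ids.setdefault(src)
            for tgt in targets:
                ids.setdefault(tgt)
                edges.append((src, tgt, interaction))
    nodes = [NodeRecord(node_id=i) for i in ids]
    return Network(nodes=nodes, edges=edges)


def _parse_cell(cell: str, list_delimiter: str):
    """Classify a cell as list-of-real, scalar real, or text."""
    if list_delimiter in cell:
        try:
            return ("list", [float(p) for p in cell.split(list_delimiter)])
        except ValueError:
            return ("text", cell)
    try:
        return ("scalar", float(cell))
    except ValueError:
        return ("text", cell)


def read_node_table(
    path: str, delimiter: str = "\t", list_delimiter: str = "|"
) -> dict[str, NodeRecord]:
    """Read a delimited node table into NodeRecords keyed by node id.

    The first column is the node id and a header row is required.
    Raises :class:`DuplicateIdError` on repeated ids and
    :class:`RowArityError` on ragged rows.
    """
    records: dict[str, NodeRecord] = {}
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter=delimiter)
        try:
            header = next(reader)
        except StopIteration:
            raise RowArityError(f"{path}: empty table") from None
        ncol = len(header)
        for rowno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != ncol:
                raise RowArityError(
                    f"{path}:{rowno}: {len(row)} cells, header has {ncol}"
                )
            nid = row[0]
            if nid in records:
                raise DuplicateIdError(f"{path}:{rowno}: duplicate node id {nid!r}")
            scalars: dict = {}
            lists: dict = {}
            for col, cell in zip(header[1:], row[1:]):
                if cell == "":
                    continue
                kind, value = _parse_cell(cell, list_delimiter)
                if kind == "list":
                    lists[col] = value
                else:
                    scalars[col] = value
            records[nid] = NodeRecord(node_id=nid, scalars=scalars, lists=lists)
    return records


def write_node_table(
    records: dict[str, NodeRecord],
    path: str,
    delimiter: str = "\t",
    list_delimiter: str = "|",
) -> None:
    """Write NodeRecords as a delimited table (inverse of read_node_table)."""
    columns: list[str] = []
    for rec in records.values():
        for col in list(rec.scalars) + list(rec.lists):
            if col not in columns:
                columns.append(col)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter, lineterminator="\n")
        writer.writerow(["id"] + columns)
        for nid, rec in records.items():
            row = [nid]
            for col in columns:
                if col in rec.scalars:
                    v = rec.scalars[col]
                    row.append(repr(v) if isinstance(v, float) else str(v))
                elif col in rec.lists:
                    row.append(list_delimiter.join(repr(float(x)) for x in rec.lists[col]))
                else:
                    row.append("")
            writer.writerow(row)


# ---------------------------------------------------------------------------
# layout
# ---------------------------------------------------------------------------

def auto_layout(
    network: Network,
    canvas: tuple[float, float] = (800.0, 600.0),
    node_size: tuple[float, float] = DEFAULT_NODE_SIZE,
) -> Network:
    """Fill missing node positions with a deterministic circular layout."""
    missing = [nid for nid in network.node_ids() if nid not in network.layout]
    if not missing:
        return network
    w, h = canvas
    nw, nh = node_size
    cx, cy = w / 2.0, h / 2.0
    radius = 0.5 * min(w, h) - max(nw, nh)
    layout = dict(network.layout)
    n = len(missing)
    for i, nid in enumerate(sorted(missing)):
        ang = 2.0 * math.pi * i / max(n, 1)
        layout[nid] = (
            cx + radius * math.cos(ang) - nw / 2.0,
            cy + radius * math.sin(ang) - nh / 2.0,
            nw,
            nh,
        )
    return replace(network, layout=layout)


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

GALLERY_INSTRUCTIONS = {
    "glyph_lingrad": (
        'lingrad: start="0.0,0.0" end="1.0,0.0" '
        'stoplist="255,255,255,255,0|0,0,255,255,1"'
    ),
    "glyph_radgrad": (
        'radgrad: center="0.5,0.5" radius="0.5" '
        'stoplist="255,255,0,255,0|255,0,0,255,1"'
    ),
    "glyph_pie": 'piechart: attributelist="a,b,c,d" colorlist="contrasting"',
    "glyph_bar": 'barchart: attributelist="a,b,c,d" colorlist="modulated" separation="2"',
    "glyph_line": 'linechart: attributelist="a,b,c,d" linewidth="2" ybase="middle"',
    "glyph_heatstrip": 'heatstripchart: attributelist="a,b,c,d" colorlist="yellowblue"',
    "glyph_circos": (
        'circoschart: attributelist="Circle1,Circle2" firstarc="0.3" '
        'firstarcwidth="0.2" arcwidth="0.2" colorlist="rainbow"'
    ),
    "glyph_stripe": 'stripechart: colorlist="red,green,blue"',
}


def generate_fixture(kind: str, n_nodes: int = 9, seed: int = 0):
    """Generate a demo (Network, node-record table) pair.

    ``gallery`` nodes carry integer columns a–d, list columns Values,
    Circle1, Circle2, and the eight instruction columns above, so every
    glyph type is exercised.  ``expression`` builds a small connected
    network with three expression-like columns drawn from a seeded
    normal, clipped to [-3, 3], and one heat-strip instruction column.
    """
    if n_nodes < 1:
        raise ConfigError("fixtures need at least one node")
    rng = np.random.default_rng(seed)
    if kind == "gallery":
        records: dict[str, NodeRecord] = {}
        for i in range(n_nodes):
            nid = f"g{i + 1}"
            scalars = {
                "a": int(rng.integers(1, 11)),
                "b": int(rng.integers(1, 11)),
                "c": int(rng.integers(1, 11)),
                "d": int(rng.integers(1, 11)),
            }
            scalars.update(GALLERY_INSTRUCTIONS)
            lists = {
                "Values": [round(float(v), 3) for v in rng.uniform(-3, 3, size=5)],
                "Circle1": [round(float(v), 3) for v in rng.uniform(0.5, 5, size=4)],
                "Circle2": [round(float(v), 3) for v in rng.uniform(0.5, 5, size=4)],
            }
            records[nid] = NodeRecord(node_id=nid, scalars=scalars, lists=lists)
        ids = list(records)
        edges = [(ids[i], ids[(i + 1) % len(ids)], "pp") for i in range(len(ids) - 1)]
        network = Network(nodes=list(records.values()), edges=edges)
        return network, records
    if kind == "expression":
        records = {}
        for i in range(n_nodes):
            nid = f"YDL{i + 1:03d}W"
            vals = np.clip(rng.normal(0.0, 1.2, size=3), -3.0, 3.0)
            scalars = {
                "gal1RGexp": round(float(vals[0]), 3),
                "gal4RGexp": round(float(vals[1]), 3),
                "gal80Rexp": round(float(vals[2]), 3),
                "heatstrip": EXPRESSION_INSTRUCTION,
            }
            records[nid] = NodeRecord(node_id=nid, scalars=scalars)
        ids = list(records)
        # a spanning path keeps the network connected; extra random edges on top
        edges = [(ids[i], ids[i + 1], "pp") for i in range(len(ids) - 1)]
        if n_nodes > 3:
            extra = rng.integers(0, n_nodes, size=(max(n_nodes // 3, 1), 2))
            for u, v in extra:
                if u != v:
                    edges.append((ids[int(u)], ids[int(v)], "pp"))
        network = Network(nodes=list(records.values()), edges=edges)
        return network, records
    raise ConfigError(f"unknown fixture kind {kind!r}; expected gallery or expression")


# ---------------------------------------------------------------------------
# config
# ---------------------------------------------------------------------------

_CONFIG_KEYS = {"mapping", "canvas", "node_shape", "node_size", "seed"}


def load_config(path: str) -> RenderConfig:
    """Load a YAML slot-mapping config.

    Required: ``mapping``, a map of instruction column name to slot
    (1-9).  Optional: ``canvas: {width, height}``, ``node_shape``
    (rect|ellipse), ``node_size: {width, height}``, ``seed``.
    """
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    unknown = set(data) - _CONFIG_KEYS
    if unknown:
        raise ConfigError(f"{path}: unknown config keys {sorted(unknown)}")
    mapping = data.get("mapping")
    if not mapping or not isinstance(mapping, dict):
        raise ConfigError(f"{path}: 'mapping' must be a non-empty column->slot map")
    entries = tuple((str(col), int(slot)) for col, slot in mapping.items())
    slot_mapping = SlotMapping(entries=entries)
    kwargs: dict = {"mapping": slot_mapping}
    if "canvas" in data:
        c = data["canvas"]
        kwargs["canvas"] = (float(c["width"]), float(c["height"]))
    if "node_shape" in data:
        shape = data["node_shape"]
        if shape not in ("rect", "ellipse"):
            raise ConfigError(f"{path}: node_shape must be rect or ellipse")
        kwargs["node_shape"] = shape
    if "node_size" in data:
        s = data["node_size"]
        kwargs["node_size"] = (float(s["width"]), float(s["height"]))
    if "seed" in data:
        kwargs["seed"] = int(data["seed"])
    return RenderConfig(**kwargs)
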