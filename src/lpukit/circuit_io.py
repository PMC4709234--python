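"""Readers and writers for declarative circuit documents.

LPU specs travel as GEXF property graphs (via networkx): component nodes
carry a ``model`` attribute naming a registry entry plus flat numeric
parameter attributes; dedicated port nodes carry ``model='Port'``,
``port`` (the identifier in canonical bracket form), ``io`` and
``transmission``, and are linked to the component they expose by a single
edge (component -> port for outputs, port -> component for inputs).

Connectivity patterns travel as a two-section CSV file: an attribute table
with header ``identifier,interface,io,transmission`` followed by a blank
line and a connection table with header ``source,destination``.  Identifiers
are written in canonical bracket form.  Both document kinds round-trip
losslessly, and reader errors carry a locator (node id or row number).

Recordings are written as HDF5 (one dataset per LPU/kind, port names in
attributes) or as wide CSV tables via pandas.
"""

from __future__ import annotations

import csv
import io as _io
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .errors import PatternError
from .lpu import LPUSpec, PortDecl
from .models import default_registry
from .pattern import Pattern
from .selectors import PortIdentifier

__all__ = [
    "read_lpu_gexf", "write_lpu_gexf",
    "read_pattern_csv", "write_pattern_csv",
    "read_pattern_gexf", "write_pattern_gexf",
    "record_to_frame", "write_record",
]

_PORT_MODEL = "Port"
_ATTR_HEADER = ["identifier", "interface", "io", "transmission"]
_CONN_HEADER = ["source", "destination"]


# ---------------------------------------------------------------------------
# LPU documents (GEXF)

def write_lpu_gexf(spec: LPUSpec, path) -> None:
    g = nx.DiGraph(name=spec.id)
    for node, attrs in spec.components.nodes(data=True):
        g.add_node(str(node), **attrs)
    for u, v in spec.components.edges:
        g.add_edge(str(u), str(v))
    binding_of = {ident: comp for ident, comp in spec.port_bindings.items()}
    for decl in spec.interface:
        pnode = f"port:{decl.identifier}"
        g.add_node(
            pnode,
            model=_PORT_MODEL,
            port=str(decl.identifier),
            io=decl.io,
            transmission=decl.transmission,
        )
        comp = binding_of.get(decl.identifier)
        if comp is not None:
            if decl.io == "out":
                g.add_edge(str(comp), pnode)
            else:
                g.add_edge(pnode, str(comp))
    nx.write_gexf(g, path, version="1.2draft")


def read_lpu_gexf(source, registry=None) -> LPUSpec:
    registry = registry or default_registry()
    g = nx.read_gexf(source, node_type=str)
    lpu_id = g.graph.get("name") or Path(str(source)).stem
    components = nx.DiGraph()
    interface: list[PortDecl] = []
    bindings: dict[PortIdentifier, str] = {}
    port_nodes: list[str] = []  # file order defines interface (mapper) order
    for node, attrs in g.nodes(data=True):
        attrs = {
            k: v for k, v in attrs.items() if k not in ("label", "id", "pid")
        }
        model = attrs.get("model")
        if model is None:
            raise PatternError(f"node {node!r}: missing model attribute")
        if model == _PORT_MODEL:
            port_nodes.append(node)
            continue
        if model not in registry:
            raise PatternError(f"node {node!r}: unknown model {model!r}")
        components.add_node(node, **attrs)
    port_node_set = set(port_nodes)
    for node in port_nodes:
        attrs = g.nodes[node]
        try:
            ident = PortIdentifier.coerce(attrs["port"])
        except (KeyError, ValueError) as exc:
            raise PatternError(f"node {node!r}: bad port identifier: {exc}") from exc
        io = attrs.get("io")
        transmission = attrs.get("transmission")
        interface.append(PortDecl(ident, io, transmission))
        if io == "out":
            comps = [u for u in g.predecessors(node) if u not in port_node_set]
        else:
            comps = [v for v in g.successors(node) if v not in port_node_set]
        if len(comps) != 1:
            raise PatternError(
                f"node {node!r}: port must bind exactly one component, "
                f"found {len(comps)}"
            )
        bindings[ident] = comps[0]
    for u, v in g.edges:
        if u in port_node_set or v in port_node_set:
            continue
        components.add_edge(u, v)
    return LPUSpec(
        id=lpu_id,
        interface=tuple(interface),
        components=components,
        port_bindings=bindings,
    )


# ---------------------------------------------------------------------------
# Pattern documents (CSV)

def write_pattern_csv(pattern: Pattern, sink) -> None:
    close = False
    if isinstance(sink, (str, Path)):
        sink = open(sink, "w", newline="")
        close = True
    try:
        w = csv.writer(sink)
        w.writerow(_ATTR_HEADER)
        for attrs in pattern.ports:
            w.writerow(
                [
                    str(attrs.identifier),
                    attrs.interface,
                    attrs.io if attrs.io is not None else "",
                    attrs.transmission if attrs.transmission is not None else "",
                ]
            )
        w.writerow([])
        w.writerow(_CONN_HEADER)
        for src, dst in pattern.connections:
            w.writerow([str(src), str(dst)])
    finally:
        if close:
            sink.close()


def read_pattern_csv(source) -> Pattern:
    if isinstance(source, (str, Path)):
        text = Path(source).read_text()
    else:
        text = source.read()
    rows = list(csv.reader(_io.StringIO(text)))
    attr_rows: list[tuple[int, list[str]]] = []
    conn_rows: list[tuple[int, list[str]]] = []
    section = None
    for lineno, row in enumerate(rows, start=1):
        if not row or all(not c.strip() for c in row):
            continue
        cells = [c.strip() for c in row]
        if cells == _ATTR_HEADER:
            section = "attrs"
            continue
        if cells == _CONN_HEADER:
            section = "conns"
            continue
        if section == "attrs":
            attr_rows.append((lineno, cells))
        elif section == "conns":
            conn_rows.append((lineno, cells))
        else:
            raise PatternError(f"row {lineno}: data before any section header")
    if not attr_rows:
        raise PatternError("no attribute table found")

    def fail(lineno, exc):
        raise PatternError(f"row {lineno}: {exc}") from exc

    parsed = []
    for lineno, cells in attr_rows:
        if len(cells) != 4:
            fail(lineno, ValueError(f"expected 4 columns, got {len(cells)}"))
        try:
            ident = PortIdentifier.coerce(cells[0])
            interface = int(cells[1])
        except (ValueError, KeyError) as exc:
            fail(lineno, exc)
        parsed.append((lineno, ident, interface, cells[2] or None, cells[3] or None))
    from .selectors import Selector

    sel0 = Selector.from_identifiers(
        [i for _, i, lab, _, _ in parsed if lab == 0]
    )
    sel1 = Selector.from_identifiers(
        [i for _, i, lab, _, _ in parsed if lab == 1]
    )
    pattern = Pattern(sel0, sel1)
    for lineno, ident, interface, io, transmission in parsed:
        if io is None and transmission is None:
            continue
        try:
            pattern.set_attributes([ident], interface, io, transmission)
        except (PatternError, KeyError, ValueError) as exc:
            fail(lineno, exc)
    for lineno, cells in conn_rows:
        if len(cells) != 2:
            fail(lineno, ValueError(f"expected 2 columns, got {len(cells)}"))
        try:
            pattern.add_connection(cells[0], cells[1])
        except (PatternError, KeyError, ValueError) as exc:
            fail(lineno, exc)
    return pattern


# ---------------------------------------------------------------------------
# Pattern documents (GEXF)

def write_pattern_gexf(pattern: Pattern, path) -> None:
    g = nx.DiGraph()
    for attrs in pattern.ports:
        g.add_node(
            str(attrs.identifier),
            interface=attrs.interface,
            io=attrs.io or "",
            transmission=attrs.transmission or "",
        )
    for src, dst in pattern.connections:
        g.add_edge(str(src), str(dst))
    nx.write_gexf(g, path, version="1.2draft")


def read_pattern_gexf(source) -> Pattern:
    g = nx.read_gexf(source, node_type=str)
    from .selectors import Selector

    by_label: dict[int, list[str]] = {0: [], 1: []}
    for node, attrs in g.nodes(data=True):
        try:
            by_label[int(attrs["interface"])].append(node)
        except (KeyError, ValueError) as exc:
            raise PatternError(f"node {node!r}: bad interface label: {exc}") from exc
    pattern = Pattern(
        Selector.from_identifiers(by_label[0]),
        Selector.from_identifiers(by_label[1]),
    )
    for node, attrs in g.nodes(data=True):
        io, tr = attrs.get("io") or None, attrs.get("transmission") or None
        if io and tr:
            pattern.set_attributes([node], int(attrs["interface"]), io, tr)
    for src, dst in g.edges:
        try:
            pattern.add_connection(src, dst)
        except (PatternError, KeyError) as exc:
            raise PatternError(f"edge {src} -> {dst}: {exc}") from exc
    return pattern


# ---------------------------------------------------------------------------
# Recordings

def record_to_frame(record, lpu_id: str, kind: str, sel=None) -> pd.DataFrame:
    """Wide table: one row per step, one column per port identifier."""
    data = record.get(lpu_id, kind, sel)
    if sel is None:
        order = record.orders[(lpu_id, kind)]
    else:
        from .selectors import Selector

        s = Selector.coerce(sel)
        order = (
            s.expand_against(record.orders[(lpu_id, kind)])
            if s.has_wildcard
            else s.expand()
        )
    frame = pd.DataFrame(data, columns=[str(i) for i in order])
    frame.index.name = "step"
    return frame


def write_record(record, path, selections=None) -> None:
    """Write recordings to ``path``: HDF5 for ``.h5``/``.hdf5``, otherwise
    one wide CSV per (lpu, kind) with the suffix ``_<lpu>_<kind>``.

    ``selections`` optionally restricts output to {lpu_id: selector}.
    """
    path = Path(path)
    keys = [
        (lpu, kind)
        for (lpu, kind) in record.buffers
        if selections is None or lpu in selections
    ]
    if path.suffix in (".h5", ".hdf5"):
        import h5py

        with h5py.File(path, "w") as f:
            f.attrs["dt"] = record.dt
            f.attrs["steps"] = record.steps
            for lpu, kind in keys:
                sel = selections.get(lpu) if selections else None
                data = record.get(lpu, kind, sel)
                if data.shape[1] == 0:
                    continue
                ds = f.create_dataset(f"{lpu}/{kind}", data=data)
                if sel is None:
                    order = record.orders[(lpu, kind)]
                else:
                    from .selectors import Selector

                    s = Selector.coerce(sel)
                    order = (
                        s.expand_against(record.orders[(lpu, kind)])
                        if s.has_wildcard
                        else s.expand()
                    )
                ds.attrs["ports"] = np.array([str(i) for i in order], dtype="S")
    else:
        for lpu, kind in keys:
            sel = selections.get(lpu) if selections else None
            frame = record_to_frame(record, lpu, kind, sel)
            if frame.shape[1] == 0:
                continue
            out = path.with_name(f"{path.stem}_{lpu}_{kind}{path.suffix or '.csv'}")
            frame.to_csv(out)
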