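"""Reading and writing RSA tables and network artifacts.

RSA tables are plain delimited text (TSV by default): first column holds
the taxon label, remaining columns are numeric abundances per time point.
Raw counts are accepted and converted to compositions (each column is
renormalized to sum to 1).  Networks round-trip through an edge-list TSV
(with a sibling ``<path>.nodes.tsv`` for node attributes) or GraphML.
"""

from __future__ import annotations

import logging
from pathlib import Path

import networkx as nx
import pandas as pd

from .containers import DirectedWeightedNet, RsaSeries

__all__ = ["read_rsa_table", "write_rsa_table", "write_network", "read_network"]

log = logging.getLogger(__name__)

_EDGE_COLS = ["source", "target", "te", "sign", "lag", "mi", "df"]
_NODE_COLS = ["node", "entropy", "ote", "ite", "keep", "k", "k_f"]


def read_rsa_table(path: str | Path, delimiter: str = "\t",
                   individual_id: str | None = None) -> RsaSeries:
    """Read a taxa-by-time abundance table into an :class:`RsaSeries`.

    Columns are renormalized to sum to 1; the renormalization factor is
    logged per column.  Negative values and duplicate taxon labels are
    rejected with a cell/row report.
    """
    path = Path(path)
    frame = pd.read_csv(path, sep=delimiter, index_col=0)
    frame.index = frame.index.astype(str)
    try:
        frame = frame.astype(float)
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric abundance value ({exc})") from exc
    colsums = frame.to_numpy(dtype=float).sum(axis=0)
    for col, s in zip(frame.columns, colsums):
        if s > 0 and abs(s - 1.0) > 1e-6:
            log.info("%s: column %r renormalized by factor %.6g", path.name, col, 1.0 / s)
    return RsaSeries.from_frame(individual_id or path.stem, frame)


def write_rsa_table(series: RsaSeries, path: str | Path, delimiter: str = "\t") -> Path:
    path = Path(path)
    frame = series.data.copy()
    frame.index.name = "taxon"
    frame.to_csv(path, sep=delimiter, float_format="%.12g")
    return path


def _nodes_path(path: Path) -> Path:
    return path.with_name(path.name + ".nodes.tsv")


def write_network(net: DirectedWeightedNet, path: str | Path,
                  format: str = "edge-list") -> Path:
    """Write a directed TE network as edge-list TSV or GraphML.

    The edge list carries source, target, TE magnitude, sign, lag, MI and
    functional distance; the node table carries Shannon entropy, OTE, ITE
    and degrees.  ``read_network`` inverts both formats losslessly.
    """
    path = Path(path)
    g = net.graph
    if format == "edge-list":
        rows = []
        for u, v, d in sorted(g.edges(data=True)):
            rows.append([u, v, "%.12g" % d["te"], str(int(d["sign"])),
                         str(int(d["lag"])), "%.12g" % d["mi"], "%.12g" % d["df"]])
        lines = ["\t".join(_EDGE_COLS)] + ["\t".join(r) for r in rows]
        path.write_text("\n".join(lines) + "\n")
        und = g.to_undirected()
        nrows = []
        for n in sorted(g.nodes):
            d = g.nodes[n]
            nrows.append([
                n, "%.12g" % d.get("entropy", 0.0), "%.12g" % d.get("ote", 0.0),
                "%.12g" % d.get("ite", 0.0), str(int(d.get("keep", 1))),
                str(und.degree(n)), str(g.in_degree(n) + g.out_degree(n)),
            ])
        nlines = ["\t".join(_NODE_COLS)] + ["\t".join(r) for r in nrows]
        _nodes_path(path).write_text("\n".join(nlines) + "\n")
    elif format == "graphml":
        h = nx.DiGraph(kind=net.kind)
        for n, d in g.nodes(data=True):
            h.add_node(n, **{k: float(v) if k != "keep" else int(v)
                             for k, v in d.items()})
        for u, v, d in g.edges(data=True):
            h.add_edge(u, v, te=float(d["te"]), sign=int(d["sign"]),
                       lag=int(d["lag"]), mi=float(d["mi"]), df=float(d["df"]))
        nx.write_graphml(h, path)
    else:
        raise ValueError(f"unknown network format: {format!r}")
    return path


def read_network(path: str | Path, format: str = "edge-list",
                 kind: str = "MENet") -> DirectedWeightedNet:
    """Read a network written by :func:`write_network`."""
    path = Path(path)
    if format == "edge-list":
        g = nx.DiGraph()
        nodes = pd.read_csv(_nodes_path(path), sep="\t", dtype={"node": str})
        for _, r in nodes.iterrows():
            g.add_node(str(r["node"]), entropy=float(r["entropy"]),
                       ote=float(r["ote"]), ite=float(r["ite"]), keep=int(r["keep"]))
        edges = pd.read_csv(path, sep="\t", dtype={"source": str, "target": str})
        for _, r in edges.iterrows():
            g.add_edge(str(r["source"]), str(r["target"]), te=float(r["te"]),
                       sign=int(r["sign"]), lag=int(r["lag"]), mi=float(r["mi"]),
                       df=float(r["df"]))
        return DirectedWeightedNet(graph=g, kind=kind)
    if format == "graphml":
        h = nx.read_graphml(path)
        g = nx.DiGraph()
        for n, d in h.nodes(data=True):
            g.add_node(str(n), entropy=float(d.get("entropy", 0.0)),
                       ote=float(d.get("ote", 0.0)), ite=float(d.get("ite", 0.0)),
                       keep=int(d.get("keep", 1)))
        for u, v, d in h.edges(data=True):
            g.add_edge(str(u), str(v), te=float(d["te"]), sign=int(d["sign"]),
                       lag=int(d["lag"]), mi=float(d["mi"]), df=float(d["df"]))
        return DirectedWeightedNet(graph=g, kind=str(h.graph.get("kind", kind)))
    raise ValueError(f"unknown network format: {format!r}")
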