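"""Typed interaction networks and lncRNA-mediated feedforward loop (lnc-FFL) enumeration.

An lnc-FFL is the three-node regulatory motif in which a gene regulates both
an miRNA and an lncRNA while the miRNA also regulates the lncRNA.  The motif
is assembled from three typed interaction layers:

* ``gene-miRNA``   — gene regulates miRNA
* ``gene-lncRNA``  — gene regulates lncRNA
* ``miRNA-lncRNA`` — miRNA regulates lncRNA

Identifiers are matched case-insensitively after whitespace trimming (public
symbol tables mix capitalisations of the same symbol), but the first-seen
original casing is preserved in all outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence, TextIO

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

LAYERS = ("gene-miRNA", "gene-lncRNA", "miRNA-lncRNA")

#: node types implied by each layer, (source_type, target_type)
LAYER_TYPES = {
    "gene-miRNA": ("gene", "miRNA"),
    "gene-lncRNA": ("gene", "lncRNA"),
    "miRNA-lncRNA": ("miRNA", "lncRNA"),
}


class EdgeListError(ValueError):
    """Malformed or internally inconsistent interaction edge input."""


@dataclass(frozen=True, order=True)
class InteractionEdge:
    """One directed, typed regulatory interaction."""

    source: str
    target: str
    layer: str
    evidence: str = field(default="", compare=False)

    def __post_init__(self):
        if self.layer not in LAYER_TYPES:
            raise EdgeListError(
                f"unknown layer {self.layer!r}; expected one of {LAYERS}"
            )
        if _key(self.source) == _key(self.target):
            raise EdgeListError(
                f"self-edge {self.source!r} -> {self.target!r} is not allowed"
            )


@dataclass(frozen=True, order=True)
class LncFFL:
    """One (gene, miRNA, lncRNA) feedforward-loop triplet."""

    gene: str
    mirna: str
    lncrna: str

    def key(self) -> tuple[str, str, str]:
        return (_key(self.gene), _key(self.mirna), _key(self.lncrna))

    @property
    def nodes(self) -> tuple[str, str, str]:
        return (self.gene, self.mirna, self.lncrna)


@dataclass
class FFLNetwork:
    """An edge set together with its enumerated lnc-FFLs.

    ``nodes`` maps identifier -> node type and is restricted to FFL
    participants; ``edges`` keeps only edges supporting at least one FFL.
    """

    nodes: dict[str, str]
    edges: list[InteractionEdge]
    ffls: list[LncFFL]

    @property
    def n_ffls(self) -> int:
        return len(self.ffls)

    def node_type_counts(self) -> dict[str, int]:
        counts = {"gene": 0, "miRNA": 0, "lncRNA": 0}
        for t in self.nodes.values():
            counts[t] += 1
        return counts

    def undirected_graph(self) -> nx.Graph:
        """Undirected simple projection (multi-edges collapsed)."""
        g = nx.Graph()
        keymap = {_key(n): n for n in self.nodes}
        for ident, t in self.nodes.items():
            g.add_node(ident, type=t)
        for e in self.edges:
            s = keymap.get(_key(e.source), e.source.strip())
            t = keymap.get(_key(e.target), e.target.strip())
            g.add_edge(s, t)
        return g

    def ffl_membership(self) -> dict[str, int]:
        """Number of FFLs each node participates in."""
        counts = {n: 0 for n in self.nodes}
        for f in self.ffls:
            for n in f.nodes:
                counts[n] += 1
        return counts


def _key(ident: str) -> str:
    return ident.strip().casefold()


def read_edge_lists(
    sources: Sequence[str | Path | TextIO],
    layers: Sequence[str] | None = None,
    sep: str | None = None,
) -> list[InteractionEdge]:
    """Read interaction edges from delimited text files.

    Each source is TSV/CSV with a header.  Required columns: ``source`` and
    ``target``.  The layer comes from a ``layer`` column when present,
    otherwise from the corresponding entry of ``layers`` (one per source).
    Duplicate (source, target, layer) rows collapse to one edge; identifier
    whitespace is trimmed; matching is case-insensitive while the first-seen
    casing is preserved.

    Raises
    ------
    EdgeListError
        On a malformed row (named by file and line), an unknown layer, or a
        node used with contradictory types across layers.
    """
    if layers is not None and len(layers) != len(sources):
        raise EdgeListError("one layer per source is required when layers is given")

    seen: dict[tuple[str, str, str], InteractionEdge] = {}
    casing: dict[str, str] = {}
    for i, src in enumerate(sources):
        name = getattr(src, "name", None) or str(src)
        try:
            df = pd.read_csv(src, sep=sep, engine="python" if sep is None else "c")
        except Exception as exc:  # pragma: no cover - pandas message varies
            raise EdgeListError(f"{name}: cannot parse edge list ({exc})") from exc
        if df.empty:
            logger.warning("edge list %s is empty", name)
            continue
        cols = {c.strip().lower(): c for c in df.columns}
        if "source" not in cols or "target" not in cols:
            raise EdgeListError(f"{name}: missing 'source'/'target' columns")
        for row_no, row in enumerate(df.itertuples(index=False), start=2):
            rec = dict(zip(df.columns, row))
            s, t = rec[cols["source"]], rec[cols["target"]]
            if pd.isna(s) or pd.isna(t):
                raise EdgeListError(f"{name}, line {row_no}: empty source or target")
            layer = rec[cols["layer"]] if "layer" in cols else (
                layers[i] if layers is not None else None
            )
            if layer is None or pd.isna(layer):
                raise EdgeListError(f"{name}, line {row_no}: no layer given")
            layer = str(layer).strip()
            if layer not in LAYER_TYPES:
                raise EdgeListError(
                    f"{name}, line {row_no}: unknown layer {layer!r}"
                )
            evidence = ""
            if "evidence" in cols and not pd.isna(rec[cols["evidence"]]):
                evidence = str(rec[cols["evidence"]]).strip()
            s, t = str(s).strip(), str(t).strip()
            if _key(s) == _key(t):
                raise EdgeListError(f"{name}, line {row_no}: self-edge {s!r}")
            for ident in (s, t):
                casing.setdefault(_key(ident), ident)
            edge = InteractionEdge(
                casing[_key(s)], casing[_key(t)], layer, evidence
            )
            seen.setdefault((edge.layer, _key(s), _key(t)), edge)

    edges = sorted(seen.values())
    _validate_types(edges)
    return edges


def _validate_types(edges: Iterable[InteractionEdge]) -> dict[str, str]:
    """Infer node types from layers; contradictory usage is an input error."""
    types: dict[str, str] = {}
    casing: dict[str, str] = {}
    bad: list[str] = []
    for e in edges:
        st, tt = LAYER_TYPES[e.layer]
        for ident, t in ((e.source, st), (e.target, tt)):
            k = _key(ident)
            casing.setdefault(k, ident)
            prev = types.setdefault(k, t)
            if prev != t:
                bad.append(f"{casing[k]} used as {prev} and {t} ({e.layer})")
    if bad:
        raise EdgeListError(
            "contradictory node types: " + "; ".join(sorted(set(bad)))
        )
    return {casing[k]: t for k, t in types.items()}


def enumerate_ffls(edges: Iterable[InteractionEdge]) -> FFLNetwork:
    """Enumerate every lnc-FFL closed under the three-edge motif pattern.

    A triplet (g, m, l) is an FFL iff the edges g->m (gene-miRNA),
    g->l (gene-lncRNA) and m->l (miRNA-lncRNA) all exist.  The returned
    network keeps only nodes and edges participating in at least one FFL;
    FFLs are ordered lexicographically by (gene, miRNA, lncRNA).
    """
    edges = list(edges)
    types = _validate_types(edges)
    casing = {_key(n): n for n in types}

    gm: dict[str, set[str]] = {}  # gene key -> miRNA keys
    gl: dict[str, set[str]] = {}  # gene key -> lncRNA keys
    ml: dict[str, set[str]] = {}  # miRNA key -> lncRNA keys
    edge_index: dict[tuple[str, str, str], InteractionEdge] = {}
    for e in edges:
        sk, tk = _key(e.source), _key(e.target)
        edge_index[(e.layer, sk, tk)] = e
        if e.layer == "gene-miRNA":
            gm.setdefault(sk, set()).add(tk)
        elif e.layer == "gene-lncRNA":
            gl.setdefault(sk, set()).add(tk)
        else:
            ml.setdefault(sk, set()).add(tk)

    ffls: list[LncFFL] = []
    for g in gm.keys() & gl.keys():
        for m in gm[g]:
            if m not in ml:
                continue
            for l in gl[g] & ml[m]:
                ffls.append(LncFFL(casing[g], casing[m], casing[l]))
    ffls.sort()

    kept_edges: dict[tuple[str, str, str], InteractionEdge] = {}
    nodes: dict[str, str] = {}
    for f in ffls:
        gk, mk, lk = f.key()
        for node, t in ((f.gene, "gene"), (f.mirna, "miRNA"), (f.lncrna, "lncRNA")):
            nodes[node] = t
        for ek in (
            ("gene-miRNA", gk, mk),
            ("gene-lncRNA", gk, lk),
            ("miRNA-lncRNA", mk, lk),
        ):
            kept_edges[ek] = edge_index[ek]
    return FFLNetwork(nodes=nodes, edges=sorted(kept_edges.values()), ffls=ffls)


def restrict_to_ffls(network: FFLNetwork, ffls: Iterable[LncFFL]) -> FFLNetwork:
    """Sub-network induced by a subset of a network's FFLs."""
    wanted = {f.key() for f in ffls}
    kept = sorted(f for f in network.ffls if f.key() in wanted)
    edge_index = {(e.layer, _key(e.source), _key(e.target)): e for e in network.edges}
    nodes: dict[str, str] = {}
    kept_edges: dict[tuple[str, str, str], InteractionEdge] = {}
    for f in kept:
        gk, mk, lk = f.key()
        for n, t in zip(f.nodes, ("gene", "miRNA", "lncRNA")):
            nodes[n] = t
        for ek in (
            ("gene-miRNA", gk, mk),
            ("gene-lncRNA", gk, lk),
            ("miRNA-lncRNA", mk, lk),
        ):
            kept_edges[ek] = edge_index[ek]
    return FFLNetwork(nodes=nodes, edges=sorted(kept_edges.values()), ffls=kept)


def degree_distribution(network: FFLNetwork) -> pd.DataFrame:
    """Degree histogram on the undirected simple projection.

    Returns a DataFrame with columns ``degree`` and ``n_nodes``, sorted by
    degree; the node counts sum to the network's node count.
    """
    if not network.nodes:
        raise ValueError("degree distribution of an empty network is undefined")
    g = network.undirected_graph()
    degs = pd.Series(dict(g.degree()), dtype=int)
    tab = degs.value_counts().sort_index()
    return pd.DataFrame({"degree": tab.index.to_numpy(), "n_nodes": tab.to_numpy()})


def scale_free_fit(dist: pd.DataFrame) -> tuple[float, float, float]:
    """OLS fit of log10(node count) on log10(degree).

    Summarises how closely the degree distribution follows a power law
    n_k ~ k^slope.  Returns (slope, intercept, r_squared); when the log
    counts have zero variance the fit carries no information and R² is
    reported as 0 by convention.
    """
    d = dist[(dist["degree"] > 0) & (dist["n_nodes"] > 0)]
    if d["degree"].nunique() < 3:
        raise ValueError("scale-free fit needs >= 3 distinct positive degrees")
    x = np.log10(d["degree"].to_numpy(dtype=float))
    y = np.log10(d["n_nodes"].to_numpy(dtype=float))
    if np.allclose(y, y[0]):
        return 0.0, float(y[0]), 0.0
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)


def node_table(network: FFLNetwork) -> pd.DataFrame:
    """Per-node export: id, type, undirected degree, FFL membership count."""
    g = network.undirected_graph()
    member = network.ffl_membership()
    rows = [
        {"id": n, "type": t, "degree": g.degree(n), "n_ffls": member[n]}
        for n, t in sorted(network.nodes.items())
    ]
    return pd.DataFrame(rows, columns=["id", "type", "degree", "n_ffls"])


def edge_table(network: FFLNetwork) -> pd.DataFrame:
    rows = [
        {"source": e.source, "target": e.target, "layer": e.layer, "evidence": e.evidence}
        for e in network.edges
    ]
    return pd.DataFrame(rows, columns=["source", "target", "layer", "evidence"])


def ffl_table(ffls: Iterable[LncFFL]) -> pd.DataFrame:
    rows = [{"gene": f.gene, "miRNA": f.mirna, "lncRNA": f.lncrna} for f in ffls]
    return pd.DataFrame(rows, columns=["gene", "miRNA", "lncRNA"])


def write_network(network: FFLNetwork, out_dir: str | Path, prefix: str = "network") -> None:
    """Write node/edge/FFL TSV tables under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    node_table(network).to_csv(out / f"{prefix}_nodes.tsv", sep="\t", index=False)
    edge_table(network).to_csv(out / f"{prefix}_edges.tsv", sep="\t", index=False)
    ffl_table(network.ffls).to_csv(out / f"{prefix}_ffls.tsv", sep="\t", index=False)
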