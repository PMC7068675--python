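"""Module extraction from dysregulated FFL networks.

Three module kinds:

* ``key``     — the highest-degree node with all its neighbours;
* ``core``    — densely connected regions found by greedy
  cohesiveness maximisation (ClusterONE-style re-implementation; the
  published defaults — penalty 2, minimum size 4, overlap-merge threshold
  0.8 — are mirrored but bit-identity with the original Java tool is not
  claimed);
* ``complex`` — unions of FFL and ceRNA triplets that share nodes (a ceRNA
  triplet is a gene and an lncRNA competing for the same miRNA; it has the
  same three identifiers as an FFL but a different regulatory reading, so
  it carries an explicit kind tag).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd

from .network import FFLNetwork, LncFFL, _key

logger = logging.getLogger(__name__)


@dataclass(frozen=True, order=True)
class CeRNATriplet:
    """A (gene, miRNA, lncRNA) competing-endogenous-RNA triplet."""

    gene: str
    mirna: str
    lncrna: str

    def __post_init__(self):
        keys = {_key(self.gene), _key(self.mirna), _key(self.lncrna)}
        if len(keys) != 3:
            raise ValueError(f"ceRNA triplet members must be distinct: {self}")

    @property
    def nodes(self) -> tuple[str, str, str]:
        return (self.gene, self.mirna, self.lncrna)


@dataclass
class NetworkModule:
    nodes: dict[str, str]  # identifier -> node type
    edges: list[tuple[str, str]]
    kind: str  # key | core | complex
    cohesiveness: float | None = None
    hub: str | None = None
    members: list[str] = field(default_factory=list)  # triplet tags (complex only)

    def __len__(self) -> int:
        return len(self.nodes)


def _as_graph(network: FFLNetwork | nx.Graph) -> tuple[nx.Graph, dict[str, str]]:
    if isinstance(network, nx.Graph):
        types = {n: network.nodes[n].get("type", "") for n in network.nodes()}
        return network, types
    return network.undirected_graph(), dict(network.nodes)


def key_module(network: FFLNetwork | nx.Graph) -> NetworkModule:
    """Hub of maximum undirected degree plus all neighbours, induced edges.

    Equal-degree ties break to the lexicographically smallest identifier;
    all tied hubs are reported in the log.
    """
    g, types = _as_graph(network)
    if not g.number_of_nodes():
        raise ValueError("key module of an empty network is undefined")
    degrees = dict(g.degree())
    top = max(degrees.values())
    tied = sorted(n for n, d in degrees.items() if d == top)
    if len(tied) > 1:
        logger.info("hub tie at degree %d: %s; using %s", top, tied, tied[0])
    hub = tied[0]
    members = {hub} | set(g.neighbors(hub))
    sub = g.subgraph(members)
    return NetworkModule(
        nodes={n: types[n] for n in sorted(members)},
        edges=sorted(tuple(sorted(e)) for e in sub.edges()),
        kind="key",
        hub=hub,
    )


# ---------------------------------------------------------------------------
# greedy cohesiveness clustering

def _cohesiveness(g: nx.Graph, S: set, penalty: float) -> float:
    w_in = sum(1 for u, v in g.edges(S) if u in S and v in S)
    w_bound = sum(1 for u, v in g.edges(S) if (u in S) != (v in S))
    denom = w_in + w_bound + penalty * len(S)
    return w_in / denom if denom > 0 else 0.0


def _grow_cluster(g: nx.Graph, seed: str, penalty: float) -> set:
    S = {seed}
    f = _cohesiveness(g, S, penalty)
    while True:
        best_f, best_move = f, None
        boundary = {u for n in S for u in g.neighbors(n)} - S
        for u in sorted(boundary):
            cand = S | {u}
            fc = _cohesiveness(g, cand, penalty)
            if fc > best_f:
                best_f, best_move = fc, ("add", u)
        if len(S) > 1:
            for u in sorted(S):
                cand = S - {u}
                fc = _cohesiveness(g, cand, penalty)
                if fc > best_f:
                    best_f, best_move = fc, ("del", u)
        if best_move is None:
            return S
        op, u = best_move
        S = S | {u} if op == "add" else S - {u}
        f = best_f


def core_modules(
    network: FFLNetwork | nx.Graph,
    min_size: int = 4,
    density_penalty: float = 2.0,
    merge_threshold: float = 0.8,
) -> list[NetworkModule]:
    """ClusterONE-style dense regions of the undirected projection.

    Every unvisited node (lexicographic order) seeds a cluster that is grown
    greedily: the add/remove move maximising the cohesiveness
    ``f(S) = w_in / (w_in + w_bound + penalty * |S|)`` is applied until no
    move improves it.  Overlapping clusters with Jaccard >= ``merge_threshold``
    are merged; clusters below ``min_size`` are dropped.  Deterministic.
    """
    g, types = _as_graph(network)
    if not g.number_of_nodes():
        raise ValueError("core modules of an empty network are undefined")
    visited: set = set()
    clusters: list[set] = []
    for seed in sorted(g.nodes()):
        if seed in visited:
            continue
        S = _grow_cluster(g, seed, density_penalty)
        visited |= S
        if S not in clusters:
            clusters.append(S)

    # merge highly overlapping clusters
    merged = True
    while merged:
        merged = False
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                a, b = clusters[i], clusters[j]
                if len(a & b) / len(a | b) >= merge_threshold:
                    clusters[i] = a | b
                    del clusters[j]
                    merged = True
                    break
            if merged:
                break

    out = []
    for S in clusters:
        if len(S) < min_size:
            continue
        sub = g.subgraph(S)
        out.append(
            NetworkModule(
                nodes={n: types[n] for n in sorted(S)},
                edges=sorted(tuple(sorted(e)) for e in sub.edges()),
                kind="core",
                cohesiveness=_cohesiveness(g, S, density_penalty),
            )
        )
    out.sort(key=lambda m: (-(m.cohesiveness or 0.0), sorted(m.nodes)))
    return out


# ---------------------------------------------------------------------------
# FFL + ceRNA complex modules

def _triplet_edges(t, kind: str) -> list[tuple[str, str]]:
    g, m, l = t.gene, t.mirna, t.lncrna
    if kind == "ffl":
        return [tuple(sorted((g, m))), tuple(sorted((g, l))), tuple(sorted((m, l)))]
    # ceRNA: the miRNA bridges the gene and the lncRNA
    return [tuple(sorted((g, m))), tuple(sorted((m, l)))]


def merge_with_cernas(
    ffls: Sequence[LncFFL],
    cernas: Sequence[CeRNATriplet],
    min_shared: int = 2,
) -> list[NetworkModule]:
    """Complex modules from FFL and ceRNA triplets sharing nodes.

    An FFL and a ceRNA merge when they share at least ``min_shared``
    molecules (default 2); merged components are the connected components of
    the FFL-ceRNA share graph (transitive), and each module is the union of
    its member triplets' nodes and edges.  Triplets have 3 nodes, so
    ``min_shared >= 4`` can never merge.
    """
    if min_shared < 1:
        raise ValueError("min_shared must be >= 1")
    share = nx.Graph()
    items = [("ffl", i, f) for i, f in enumerate(ffls)] + [
        ("cerna", i, c) for i, c in enumerate(cernas)
    ]
    for tag, i, t in items:
        share.add_node((tag, i))
    for ftag, fi, f in items:
        if ftag != "ffl":
            continue
        fkeys = {_key(n) for n in f.nodes}
        for ctag, ci, c in items:
            if ctag != "cerna":
                continue
            if len(fkeys & {_key(n) for n in c.nodes}) >= min_shared:
                share.add_edge(("ffl", fi), ("cerna", ci))

    modules = []
    for comp in nx.connected_components(share):
        if len(comp) < 2:  # unmerged triplets are not complex modules
            continue
        nodes: dict[str, str] = {}
        edges: set[tuple[str, str]] = set()
        members = []
        for tag, i in sorted(comp):
            t = ffls[i] if tag == "ffl" else cernas[i]
            members.append(f"{tag}:{t.gene}/{t.mirna}/{t.lncrna}")
            for n, ty in zip(t.nodes, ("gene", "miRNA", "lncRNA")):
                nodes.setdefault(n, ty)
            edges.update(_triplet_edges(t, tag))
        modules.append(
            NetworkModule(
                nodes=dict(sorted(nodes.items())),
                edges=sorted(edges),
                kind="complex",
                members=sorted(members),
            )
        )
    modules.sort(key=lambda m: sorted(m.nodes))
    return modules


def read_cerna_triplets(path: str | Path) -> list[CeRNATriplet]:
    """Read ceRNA triplets from a TSV with columns gene, miRNA, lncRNA."""
    df = pd.read_csv(path, sep="\t")
    cols = {c.strip().lower(): c for c in df.columns}
    for need in ("gene", "mirna", "lncrna"):
        if need not in cols:
            raise ValueError(f"{path}: ceRNA table needs a {need!r} column")
    return [
        CeRNATriplet(
            str(r[cols["gene"]]).strip(),
            str(r[cols["mirna"]]).strip(),
            str(r[cols["lncrna"]]).strip(),
        )
        for _, r in df.iterrows()
    ]


def modules_table(modules: Iterable[NetworkModule]) -> pd.DataFrame:
    """Long-format export: one row per (module, node)."""
    rows = []
    for i, m in enumerate(modules):
        for n, t in m.nodes.items():
            rows.append(
                {
                    "module_id": i,
                    "node": n,
                    "type": t,
                    "kind": m.kind,
                    "cohesiveness": m.cohesiveness if m.cohesiveness is not None else "",
                }
            )
    return pd.DataFrame(rows, columns=["module_id", "node", "type", "kind", "cohesiveness"])
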