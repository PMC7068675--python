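"""Drug overlay: join drug-target associations onto dysregulated FFLs.

Drugs are joined to genes and miRNAs only (lncRNAs carry no drug
annotations in the source schemas this mirrors).  Categories are input
data, never inferred.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd

from .network import LncFFL, _key

logger = logging.getLogger(__name__)


@dataclass(frozen=True, order=True)
class DrugAssociation:
    drug: str
    target: str
    target_type: str  # gene | miRNA
    category: str = ""

    def __post_init__(self):
        if self.target_type not in ("gene", "miRNA"):
            raise ValueError(
                f"target_type must be 'gene' or 'miRNA', got {self.target_type!r}"
            )


def read_associations(path: str | Path) -> list[DrugAssociation]:
    """Read a drug association TSV: drug, target, target_type[, category]."""
    df = pd.read_csv(path, sep="\t")
    cols = {c.strip().lower(): c for c in df.columns}
    for need in ("drug", "target", "target_type"):
        if need not in cols:
            raise ValueError(f"{path}: missing column {need!r}")
    out = []
    for _, r in df.iterrows():
        cat = ""
        if "category" in cols and not pd.isna(r[cols["category"]]):
            cat = str(r[cols["category"]]).strip()
        out.append(
            DrugAssociation(
                str(r[cols["drug"]]).strip(),
                str(r[cols["target"]]).strip(),
                str(r[cols["target_type"]]).strip(),
                cat,
            )
        )
    return out


def build_drug_network(
    dysregulated: Sequence[LncFFL], associations: Sequence[DrugAssociation]
) -> tuple[nx.Graph, pd.DataFrame]:
    """Bipartite drug <-> molecule network over dysregulated FFLs.

    A drug enters the network iff it targets at least one gene or miRNA of a
    dysregulated FFL, so no drug node is ever an orphan.  Returns the graph
    (node attribute ``bipartite`` in {"drug", "molecule"}; drug nodes also
    carry their category set) and a per-hit table
    (drug, category, target, target_type, gene, miRNA, lncRNA).
    """
    by_gene: dict[str, list[LncFFL]] = {}
    by_mirna: dict[str, list[LncFFL]] = {}
    for f in dysregulated:
        by_gene.setdefault(_key(f.gene), []).append(f)
        by_mirna.setdefault(_key(f.mirna), []).append(f)

    g = nx.Graph()
    rows = []
    categories: dict[str, set[str]] = {}
    for a in sorted(set(associations)):
        lookup = by_gene if a.target_type == "gene" else by_mirna
        hits = lookup.get(_key(a.target), [])
        if not hits:
            continue
        categories.setdefault(a.drug, set())
        if a.category:
            categories[a.drug].add(a.category)
        for f in hits:
            target = f.gene if a.target_type == "gene" else f.mirna
            g.add_node(a.drug, bipartite="drug")
            g.add_node(target, bipartite="molecule", type=a.target_type)
            g.add_edge(a.drug, target)
            rows.append(
                {
                    "drug": a.drug,
                    "category": a.category,
                    "target": target,
                    "target_type": a.target_type,
                    "gene": f.gene,
                    "miRNA": f.mirna,
                    "lncRNA": f.lncrna,
                }
            )
    for d, cats in categories.items():
        g.nodes[d]["categories"] = frozenset(cats)
    if not rows:
        logger.warning("no drug targets any molecule of a dysregulated FFL")
    table = pd.DataFrame(
        rows,
        columns=["drug", "category", "target", "target_type", "gene", "miRNA", "lncRNA"],
    ).drop_duplicates().reset_index(drop=True)
    return g, table


def drug_nodes(network: nx.Graph) -> list[str]:
    return sorted(
        n for n, d in network.nodes(data=True) if d.get("bipartite") == "drug"
    )


def category_fraction(
    network: nx.Graph, categories_of_interest: Iterable[str]
) -> float:
    """Fraction of network drugs carrying >= 1 category of interest.

    Raises on an empty drug network (the fraction is undefined).
    """
    drugs = drug_nodes(network)
    if not drugs:
        raise ValueError("category fraction of an empty drug network is undefined")
    wanted = {c.strip().casefold() for c in categories_of_interest}
    n_hit = sum(
        1
        for d in drugs
        if {c.casefold() for c in network.nodes[d].get("categories", ())} & wanted
    )
    return n_hit / len(drugs)


def summary(network: nx.Graph) -> dict:
    """Counts and per-category drug fractions for the JSON summary export."""
    drugs = drug_nodes(network)
    molecules = [
        n for n, d in network.nodes(data=True) if d.get("bipartite") == "molecule"
    ]
    by_cat: dict[str, int] = {}
    for d in drugs:
        for c in network.nodes[d].get("categories", ()):
            by_cat[c] = by_cat.get(c, 0) + 1
    return {
        "n_drugs": len(drugs),
        "n_targets": len(molecules),
        "fraction_by_category": {
            c: n / len(drugs) for c, n in sorted(by_cat.items())
        }
        if drugs
        else {},
    }
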