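"""Gene-set restricted FFL subnetworks and set relations between FFL lists.

Membership is decided on the gene vertex only: the glycometabolism and
hormone lists this mirrors are protein-coding gene lists, so miRNA and
lncRNA identifiers are never tested against them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .network import FFLNetwork, LncFFL, _key, restrict_to_ffls

logger = logging.getLogger(__name__)


@dataclass
class GeneSet:
    name: str
    members: frozenset[str]  # normalised (trimmed, casefolded) identifiers

    def __post_init__(self):
        if not self.members:
            raise ValueError(f"gene set {self.name!r} is empty")
        object.__setattr__(
            self, "members", frozenset(_key(m) for m in self.members)
        )

    def __contains__(self, ident: str) -> bool:
        return _key(ident) in self.members


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Read GMT gene sets (name, description, members per tab-separated line)."""
    sets = []
    for line_no, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"{path}, line {line_no}: GMT needs name, description, members")
        sets.append(GeneSet(parts[0].strip(), frozenset(p for p in parts[2:] if p.strip())))
    return sets


def read_gene_list(path: str | Path, name: str | None = None) -> GeneSet:
    """Read a single-column gene list (one identifier per line)."""
    members = frozenset(
        line.strip() for line in Path(path).read_text().splitlines() if line.strip()
    )
    return GeneSet(name or Path(path).stem, members)


def extract_subnetwork(network: FFLNetwork, gene_set: GeneSet) -> FFLNetwork:
    """Restrict a network to the FFLs whose gene belongs to ``gene_set``.

    An empty intersection yields an empty network with a warning.  The
    operation is idempotent and monotone in the gene set.
    """
    ffls = sorted(f for f in network.ffls if f.gene in gene_set)
    if not ffls:
        logger.warning("gene set %r shares no genes with the network", gene_set.name)
        return FFLNetwork(nodes={}, edges=[], ffls=[])
    return restrict_to_ffls(network, ffls)


def ffl_set_relations(
    set_a: Sequence[LncFFL], set_b: Sequence[LncFFL]
) -> tuple[list[LncFFL], list[LncFFL], list[LncFFL]]:
    """Venn partition (common, only_a, only_b) of two FFL lists.

    FFLs compare by the full (gene, miRNA, lncRNA) triplet identity.
    """
    ka = {f.key(): f for f in set_a}
    kb = {f.key(): f for f in set_b}
    common = sorted(ka[k] for k in ka.keys() & kb.keys())
    only_a = sorted(ka[k] for k in ka.keys() - kb.keys())
    only_b = sorted(kb[k] for k in kb.keys() - ka.keys())
    return common, only_a, only_b
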