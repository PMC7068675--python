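from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from lncffl.expression import ExpressionBundle
from lncffl.network import LAYER_TYPES, InteractionEdge, LncFFL

DATA = Path(__file__).parent / "data"


@pytest.fixture
def edges_fixture_path() -> Path:
    return DATA / "edges_12.tsv"


def brute_force_ffls(edges) -> set[tuple[str, str, str]]:
    """O(|G|*|M|*|L|) triple-loop enumeration; the independent oracle."""
    gm, gl, ml = set(), set(), set()
    genes, mirnas, lncrnas = set(), set(), set()
    for e in edges:
        st, tt = LAYER_TYPES[e.layer]
        pair = (e.source.strip().casefold(), e.target.strip().casefold())
        for ident, t in ((pair[0], st), (pair[1], tt)):
            {"gene": genes, "miRNA": mirnas, "lncRNA": lncrnas}[t].add(ident)
        {"gene-miRNA": gm, "gene-lncRNA": gl, "miRNA-lncRNA": ml}[e.layer].add(pair)
    out = set()
    for g in genes:
        for m in mirnas:
            for l in lncrnas:
                if (g, m) in gm and (g, l) in gl and (m, l) in ml:
                    out.add((g, m, l))
    return out


def motif_edges(gene: str, mirna: str, lncrna: str) -> list[InteractionEdge]:
    return [
        InteractionEdge(gene, mirna, "gene-miRNA"),
        InteractionEdge(gene, lncrna, "gene-lncRNA"),
        InteractionEdge(mirna, lncrna, "miRNA-lncRNA"),
    ]


def make_bundle(
    gene_rows: dict[str, list[float]],
    mirna_rows: dict[str, list[float]],
    lncrna_rows: dict[str, list[float]],
    n_case: int,
) -> ExpressionBundle:
    """Bundle from explicit per-feature value lists (case samples first)."""
    n = len(next(iter(gene_rows.values())))
    samples = [f"s{i:02d}" for i in range(n)]
    groups = pd.Series(
        ["case"] * n_case + ["control"] * (n - n_case), index=samples, name="group"
    )

    def df(rows):
        return pd.DataFrame(
            {s: [v[i] for v in rows.values()] for i, s in enumerate(samples)},
            index=list(rows.keys()),
        ).astype(float)

    return ExpressionBundle(
        gene=df(gene_rows), mirna=df(mirna_rows), lncrna=df(lncrna_rows), groups=groups
    )


@pytest.fixture
def single_ffl() -> LncFFL:
    return LncFFL("G1", "M1", "L1")
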