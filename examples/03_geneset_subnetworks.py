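"""Gene-set subnetworks and the overlap of their dysregulated FFL sets.

Generates the two-gene-set scenario (a glycometabolism-like and a
hormone-like list over one FFL network with 30 planted dysregulated
triplets), extracts each gene set's subnetwork and partitions the planted
dysregulated FFLs into common and set-specific groups.
"""

import tempfile
from pathlib import Path

import pandas as pd

import lncffl

with tempfile.TemporaryDirectory() as td:
    fx = Path(td)
    lncffl.generate_fixtures(fx, "paper-shaped", seed=0)
    edges = lncffl.read_edge_lists([fx / "edges.tsv"])
    net = lncffl.enumerate_ffls(edges)
    glyco, hormone = lncffl.read_gmt(fx / "genesets.gmt")

    sub_g = lncffl.extract_subnetwork(net, glyco)
    sub_h = lncffl.extract_subnetwork(net, hormone)
    print(f"{glyco.name}: {sub_g.n_ffls} FFLs; {hormone.name}: {sub_h.n_ffls} FFLs")

    truth = pd.read_csv(fx / "truth.tsv", sep="\t")
    planted = [lncffl.LncFFL(r.gene, r.miRNA, r.lncRNA)
               for r in truth[truth.planted].itertuples()]
    dys_g = [f for f in planted if f.gene in glyco]
    dys_h = [f for f in planted if f.gene in hormone]
    common, only_g, only_h = lncffl.ffl_set_relations(dys_g, dys_h)
    print(
        f"dysregulated: {len(dys_g)} {glyco.name}, {len(dys_h)} {hormone.name}; "
        f"{len(common)} common, {len(only_g)}/{len(only_h)} set-specific"
    )
    print(
        "# FFLs are assigned to a gene set through their gene vertex only;\n"
        "# the Venn partition shows how much dysregulation the two\n"
        "# biological themes share."
    )
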