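"""Synthetic interaction networks and expression bundles with planted signal.

The generator stands in for the study design the pipeline targets: a small
matched case/control cohort (8 + 8 whole-blood samples by default) profiled
for genes, miRNAs and lncRNAs, plus the interaction, gene-set, ceRNA and
drug tables the downstream stages consume.

Expression follows a per-triplet latent-factor Gaussian model: each
(gene, miRNA, lncRNA) triplet draws, within each group, from a trivariate
normal whose 3x3 correlation matrix carries the per-edge targets, factored
by eigendecomposition (so exactly-singular targets such as r = +/-1 are
allowed; genuinely infeasible targets raise, naming the triplet).  Planted
dysregulated triplets additionally receive per-molecule case-group mean
shifts in units of the noise SD.  Non-planted triplets use identical
correlations and means in both groups.  Values are continuous
(post-normalisation scale), not read counts.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .expression import ExpressionBundle, write_bundle
from .network import FFLNetwork, InteractionEdge, LncFFL, enumerate_ffls

logger = logging.getLogger(__name__)

#: correlation targets per edge, ordered (lnc-miR, lnc-gene, miR-gene)
EdgeRhos = tuple[float, float, float]

#: default planted rewiring: strong positive co-expression in controls; in
#: cases the lncRNA's two edges flip sign fully while the gene-miRNA edge is
#: weakened to the positive-definiteness boundary (with two edges at -0.8 a
#: trivariate correlation matrix requires the third edge > ~0.28).
DEFAULT_RHO_CONTROL: EdgeRhos = (0.8, 0.8, 0.8)
DEFAULT_RHO_CASE: EdgeRhos = (-0.8, -0.8, 0.35)
DEFAULT_MEAN_SHIFT = 2.0


@dataclass(frozen=True)
class PlantedEffect:
    """How one planted triplet is dysregulated in the case group."""

    mean_shift: tuple[float, float, float] = (
        DEFAULT_MEAN_SHIFT,
    ) * 3  # (gene, miRNA, lncRNA), in noise-SD units
    rho_control: EdgeRhos = DEFAULT_RHO_CONTROL
    rho_case: EdgeRhos = DEFAULT_RHO_CASE


@dataclass
class SyntheticTruth:
    """Planted-signal ledger: which triplets are dysregulated and how."""

    planted: dict[LncFFL, PlantedEffect] = field(default_factory=dict)
    background_rho: float = 0.3
    n_case: int = 8
    n_control: int = 8
    noise_sd: float = 1.0
    baseline_mean: float = 10.0
    seed: int = 0

    @property
    def planted_ffls(self) -> list[LncFFL]:
        return sorted(self.planted)

    def to_manifest(self) -> dict:
        return {
            "n_case": self.n_case,
            "n_control": self.n_control,
            "background_rho": self.background_rho,
            "noise_sd": self.noise_sd,
            "baseline_mean": self.baseline_mean,
            "seed": self.seed,
            "rng": "numpy PCG64 (numpy.random.default_rng)",
            "planted": [
                {
                    "gene": f.gene,
                    "miRNA": f.mirna,
                    "lncRNA": f.lncrna,
                    "mean_shift": list(e.mean_shift),
                    "rho_control": list(e.rho_control),
                    "rho_case": list(e.rho_case),
                }
                for f, e in sorted(self.planted.items())
            ],
        }


def generate_network(
    n_genes: int,
    n_mirnas: int,
    n_lncrnas: int,
    edge_probs: float | tuple[float, float, float],
    seed: int | None = None,
) -> tuple[list[InteractionEdge], FFLNetwork]:
    """Random tripartite directed graph; per-layer Bernoulli edges.

    ``edge_probs`` is one probability for all three layers or a triple
    (gene-miRNA, gene-lncRNA, miRNA-lncRNA).  Reproducible by seed.
    """
    if isinstance(edge_probs, (int, float)):
        edge_probs = (float(edge_probs),) * 3
    if any(not 0 <= p <= 1 for p in edge_probs):
        raise ValueError(f"edge probabilities must be in [0, 1]: {edge_probs}")
    rng = np.random.default_rng(seed)
    genes = [f"G{i:04d}" for i in range(n_genes)]
    mirnas = [f"miR-{i:04d}" for i in range(n_mirnas)]
    lncrnas = [f"LNC{i:04d}" for i in range(n_lncrnas)]
    edges: list[InteractionEdge] = []
    for (srcs, tgts, layer), p in zip(
        (
            (genes, mirnas, "gene-miRNA"),
            (genes, lncrnas, "gene-lncRNA"),
            (mirnas, lncrnas, "miRNA-lncRNA"),
        ),
        edge_probs,
    ):
        mask = rng.random((len(srcs), len(tgts))) < p
        for i, j in np.argwhere(mask):
            edges.append(InteractionEdge(srcs[i], tgts[j], layer))
    edges.sort()
    network = enumerate_ffls(edges)
    logger.info(
        "generated tripartite graph: %d edges, %d FFLs", len(edges), network.n_ffls
    )
    return edges, network


def triplet_network(n_triplets: int) -> tuple[list[InteractionEdge], FFLNetwork]:
    """A network of ``n_triplets`` node-disjoint FFLs (one motif each).

    Disjoint triplets keep planted effects independent, which makes the
    generator's per-triplet correlation targets exact.
    """
    edges = []
    for i in range(n_triplets):
        g, m, l = f"G{i:04d}", f"miR-{i:04d}", f"LNC{i:04d}"
        edges += [
            InteractionEdge(g, m, "gene-miRNA"),
            InteractionEdge(g, l, "gene-lncRNA"),
            InteractionEdge(m, l, "miRNA-lncRNA"),
        ]
    edges.sort()
    return edges, enumerate_ffls(edges)


def _corr_matrix(rhos: EdgeRhos, context: str) -> np.ndarray:
    """3x3 correlation over (gene, miRNA, lncRNA) from per-edge targets."""
    r_lm, r_lg, r_mg = rhos
    c = np.array(
        [
            [1.0, r_mg, r_lg],
            [r_mg, 1.0, r_lm],
            [r_lg, r_lm, 1.0],
        ]
    )
    w = np.linalg.eigvalsh(c)
    if w.min() < -1e-9:
        raise ValueError(
            f"{context}: correlation targets {rhos} are infeasible "
            "(implied 3x3 matrix is not positive semidefinite)"
        )
    return c

def _factor(c: np.ndarray) -> np.ndarray:
    w, v = np.linalg.eigh(c)
    return v @ np.diag(np.sqrt(np.clip(w, 0.0, None)))


def generate_bundle(
    network: FFLNetwork, truth: SyntheticTruth
) -> tuple[ExpressionBundle, pd.DataFrame]:
    """Draw a matched case/control bundle over a network's molecules.

    Molecules shared between triplets keep the values of the lexicographically
    first triplet that generated them (a warning is logged); node-disjoint
    networks from :func:`triplet_network` avoid this entirely.  Returns the
    bundle and a truth table (one row per FFL, ``planted`` flag).
    """
    missing = [f for f in truth.planted if f.key() not in {x.key() for x in network.ffls}]
    if missing:
        raise ValueError(f"planted FFLs not present in the network: {missing[:3]}")
    rng = np.random.default_rng(truth.seed)
    n_case, n_ctrl = truth.n_case, truth.n_control
    sample_ids = [f"case_{i+1:02d}" for i in range(n_case)] + [
        f"control_{i+1:02d}" for i in range(n_ctrl)
    ]
    groups = pd.Series(
        ["case"] * n_case + ["control"] * n_ctrl, index=sample_ids, name="group"
    )

    values: dict[str, np.ndarray] = {}
    shared = 0
    rows = []
    for f in sorted(network.ffls, key=lambda x: x.key()):
        effect = truth.planted.get(f)
        if effect is None:
            rho_ctrl = rho_case = (truth.background_rho,) * 3
            shift = (0.0, 0.0, 0.0)
        else:
            rho_ctrl, rho_case = effect.rho_control, effect.rho_case
            shift = effect.mean_shift
        label = f"{f.gene}/{f.mirna}/{f.lncrna}"
        f_case = _factor(_corr_matrix(rho_case, label))
        f_ctrl = _factor(_corr_matrix(rho_ctrl, label))
        # columns: molecules in (gene, miRNA, lncRNA) order
        x_case = rng.standard_normal((n_case, 3)) @ f_case.T
        x_ctrl = rng.standard_normal((n_ctrl, 3)) @ f_ctrl.T
        x_case = x_case * truth.noise_sd + truth.baseline_mean
        x_ctrl = x_ctrl * truth.noise_sd + truth.baseline_mean
        x_case += np.asarray(shift) * truth.noise_sd
        for j, mol in enumerate(f.nodes):
            if mol in values:
                shared += 1
                continue
            values[mol] = np.concatenate([x_case[:, j], x_ctrl[:, j]])
        rows.append(
            {
                "gene": f.gene,
                "miRNA": f.mirna,
                "lncRNA": f.lncrna,
                "planted": effect is not None,
            }
        )
    if shared:
        logger.warning(
            "%d molecules shared between triplets kept their first draw", shared
        )

    def matrix(kind: str) -> pd.DataFrame:
        feats = sorted(n for n, t in network.nodes.items() if t == kind)
        return pd.DataFrame(
            [values[n] for n in feats], index=pd.Index(feats, name="feature_id"),
            columns=sample_ids,
        )

    bundle = ExpressionBundle(
        gene=matrix("gene"), mirna=matrix("miRNA"), lncrna=matrix("lncRNA"),
        groups=groups,
    )
    truth_table = pd.DataFrame(rows, columns=["gene", "miRNA", "lncRNA", "planted"])
    return bundle, truth_table


def make_truth(
    network: FFLNetwork,
    n_planted: int,
    seed: int,
    effect: PlantedEffect | None = None,
    **kwargs,
) -> SyntheticTruth:
    """Plant ``n_planted`` dysregulated FFLs chosen at random from a network."""
    if n_planted > network.n_ffls:
        raise ValueError("cannot plant more FFLs than the network contains")
    rng = np.random.default_rng(seed)
    idx = rng.choice(network.n_ffls, size=n_planted, replace=False)
    effect = effect or PlantedEffect()
    planted = {network.ffls[i]: effect for i in sorted(idx)}
    return SyntheticTruth(planted=planted, seed=seed, **kwargs)


# ---------------------------------------------------------------------------
# fixture scenarios

SCENARIOS = ("null", "planted", "paper-shaped")


def generate_fixtures(out_dir: str | Path, scenario: str, seed: int) -> dict:
    """Write a complete, self-consistent input set for one scenario.

    * ``null``         — 200 disjoint triplets, no planted signal.
    * ``planted``      — 200 triplets, 10 planted dysregulated.
    * ``paper-shaped`` — 200 triplets, 30 planted; two overlapping gene sets
      ("glycometabolism", "hormone") arranged so the planted dysregulated
      sets they select have sizes 11 and 29 with a 10-triplet intersection;
      11 ceRNA triplets each sharing two molecules with a planted FFL; a
      29-drug association table with 21 hormonal/anti-inflammatory drugs.

    Emits edges, the three matrices, the design, gene sets (GMT), ceRNA and
    drug TSVs, a truth table, and ``manifest.json``.  Byte-identical for a
    given seed.
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; expected one of {SCENARIOS}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    n_triplets = 200
    edges, network = triplet_network(n_triplets)

    if scenario == "null":
        truth = SyntheticTruth(seed=seed)
    elif scenario == "planted":
        truth = make_truth(network, n_planted=10, seed=seed)
    else:
        truth = make_truth(network, n_planted=30, seed=seed)

    bundle, truth_table = generate_bundle(network, truth)
    pd.DataFrame(
        [
            {"source": e.source, "target": e.target, "layer": e.layer}
            for e in edges
        ]
    ).to_csv(out / "edges.tsv", sep="\t", index=False)
    write_bundle(
        bundle,
        out / "gene.tsv",
        out / "mirna.tsv",
        out / "lncrna.tsv",
        out / "design.tsv",
    )
    truth_table.to_csv(out / "truth.tsv", sep="\t", index=False)

    planted = truth.planted_ffls
    manifest = {"scenario": scenario, **truth.to_manifest()}

    if scenario == "paper-shaped":
        rng = np.random.default_rng(seed + 1)
        # dysregulated set sizes 11 (glyco) and 29 (hormone), intersection 10:
        # planted[0] is glyco-only, planted[1:10+1] are common, the rest
        # hormone-only.  Both sets also carry non-planted background genes.
        glyco_ffls = planted[:11]
        hormone_ffls = planted[1:30]
        non_planted_genes = sorted(
            set(f.gene for f in network.ffls) - set(f.gene for f in planted)
        )
        bg = rng.permutation(non_planted_genes)
        glyco = sorted(f.gene for f in glyco_ffls) + sorted(bg[:30])
        hormone = sorted(f.gene for f in hormone_ffls) + sorted(bg[30:70])
        with open(out / "genesets.gmt", "w") as fh:
            fh.write("glycometabolism\tsynthetic glycometabolism gene set\t")
            fh.write("\t".join(glyco) + "\n")
            fh.write("hormone\tsynthetic hormone gene set\t")
            fh.write("\t".join(hormone) + "\n")

        # ceRNA triplets: same gene and miRNA as a planted FFL, new lncRNA
        cerna_rows = [
            {"gene": f.gene, "miRNA": f.mirna, "lncRNA": f"ceLNC{i:03d}"}
            for i, f in enumerate(planted[:11])
        ]
        pd.DataFrame(cerna_rows).to_csv(out / "cerna.tsv", sep="\t", index=False)

        # 29 drugs, 21 in the categories of interest (21/29 = 72.41%)
        drug_rows = []
        cats = ["hormonal"] * 11 + ["anti-inflammatory"] * 10 + ["other"] * 8
        for i, cat in enumerate(cats):
            f = planted[i % len(planted)]
            target, ttype = (
                (f.gene, "gene") if i % 2 == 0 else (f.mirna, "miRNA")
            )
            drug_rows.append(
                {
                    "drug": f"drug{i:03d}",
                    "target": target,
                    "target_type": ttype,
                    "category": cat,
                }
            )
        pd.DataFrame(drug_rows).to_csv(out / "drugs.tsv", sep="\t", index=False)
        manifest["gene_sets"] = {"glycometabolism": len(glyco), "hormone": len(hormone)}
        manifest["n_cernas"] = len(cerna_rows)
        manifest["n_drugs"] = len(drug_rows)

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
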