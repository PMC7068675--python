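"""End-to-end orchestration: build -> subnetworks -> score -> modules -> drugs.

Each stage writes its outputs before the next begins, so a failed run keeps
partial results, and every later stage can be re-run from the saved outputs
of the earlier ones.  A ``manifest.json`` in the run directory echoes the
full configuration, the seed, wall time and per-stage row counts; identical
config + seed gives byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import drugs as drugs_mod
from . import genesets as genesets_mod
from . import modules as modules_mod
from . import network as network_mod
from . import scoring as scoring_mod
from .expression import read_bundle

logger = logging.getLogger(__name__)

FLOAT_FORMAT = "%.12g"


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """All pipeline inputs, outputs and tuning parameters.

    Paths may be None for optional stages (gene sets, ceRNAs, drugs).
    """

    edges: str | None = None
    gene: str | None = None
    mirna: str | None = None
    lncrna: str | None = None
    design: str | None = None
    genesets: str | None = None  # GMT with >= 1 sets
    cernas: str | None = None
    drug_associations: str | None = None
    out_dir: str = "lncffl_run"

    permutations: int = 1000
    seed: int = 42
    alpha: float = 0.05
    tau: float = 0.3
    log2p1: bool = False
    equal_var: bool = True

    min_module_size: int = 4
    density_penalty: float = 2.0
    merge_threshold: float = 0.8
    min_shared: int = 2
    categories_of_interest: list[str] = field(
        default_factory=lambda: ["hormonal", "anti-inflammatory"]
    )
    group_aliases: dict[str, str] = field(default_factory=dict)
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)

    def validate(self) -> None:
        required = {"edges": self.edges, "gene": self.gene, "mirna": self.mirna,
                    "lncrna": self.lncrna, "design": self.design}
        missing = [k for k, v in required.items() if v is None]
        if missing:
            raise ValueError(f"config is missing required input paths: {missing}")
        for k, v in {**required, "genesets": self.genesets, "cernas": self.cernas,
                     "drug_associations": self.drug_associations}.items():
            if v is not None and not Path(v).exists():
                raise ValueError(f"config path for {k!r} does not exist: {v}")
        if self.permutations < 100:
            raise ValueError("permutations must be >= 100")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def run_pipeline(config: RunConfig) -> dict:
    """Run every configured stage; returns the manifest dict."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.monotonic()
    manifest: dict = {
        "config": dataclasses.asdict(config),
        "stages": {},
    }

    def stage(name):
        logger.info("stage %s", name)
        manifest["stages"][name] = {}
        return manifest["stages"][name]

    # --- build -----------------------------------------------------------
    try:
        rec = stage("build")
        edges = network_mod.read_edge_lists([config.edges])
        net = network_mod.enumerate_ffls(edges)
        network_mod.write_network(net, out, prefix="global")
        rec["n_edges"] = len(net.edges)
        rec["n_ffls"] = net.n_ffls
        rec["node_counts"] = net.node_type_counts()
        if net.n_ffls:
            dist = network_mod.degree_distribution(net)
            _write(dist, out / "degree_distribution.tsv")
            if dist["degree"].nunique() >= 3:
                slope, intercept, r2 = network_mod.scale_free_fit(dist)
                rec["scale_free_fit"] = {
                    "slope": slope, "intercept": intercept, "r_squared": r2
                }
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage build failed: {exc}") from exc

    # --- score / permute -------------------------------------------------
    try:
        rec = stage("score")
        bundle = read_bundle(
            config.gene, config.mirna, config.lncrna, config.design,
            group_aliases=config.group_aliases,
        )
        if config.log2p1:
            bundle = bundle.log2p1()
        scores = scoring_mod.permutation_test(
            bundle, net.ffls,
            n_permutations=config.permutations, seed=config.seed,
            alpha=config.alpha, tau=config.tau, equal_var=config.equal_var,
        )
        _write(scores, out / "scores.tsv")
        dys = scoring_mod.dysregulated_ffls(scores)
        dys_net = network_mod.restrict_to_ffls(net, dys)
        network_mod.write_network(dys_net, out, prefix="dysregulated")
        rec["n_scored"] = len(scores)
        rec["n_dysregulated"] = len(dys)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage score failed: {exc}") from exc

    # --- gene-set subnetworks -------------------------------------------
    if config.genesets:
        try:
            rec = stage("subnet")
            sets = genesets_mod.read_gmt(config.genesets)
            dys_sets = {}
            for gs in sets:
                sub = genesets_mod.extract_subnetwork(net, gs)
                network_mod.write_network(sub, out, prefix=f"subnet_{gs.name}")
                dys_sets[gs.name] = [f for f in dys if f.gene in gs]
                rec[gs.name] = {
                    "n_ffls": sub.n_ffls,
                    "n_dysregulated": len(dys_sets[gs.name]),
                }
            if len(sets) >= 2:
                a, b = sets[0].name, sets[1].name
                common, only_a, only_b = genesets_mod.ffl_set_relations(
                    dys_sets[a], dys_sets[b]
                )
                for tag, group in (
                    ("common", common), (f"only_{a}", only_a), (f"only_{b}", only_b)
                ):
                    _write(network_mod.ffl_table(group), out / f"venn_{tag}.tsv")
                rec["venn"] = {
                    "common": len(common), f"only_{a}": len(only_a),
                    f"only_{b}": len(only_b),
                }
                logger.info(
                    "dysregulated FFL overlap: %d common, %d only %s, %d only %s",
                    len(common), len(only_a), a, len(only_b), b,
                )
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(f"stage subnet failed: {exc}") from exc

    # --- modules ---------------------------------------------------------
    try:
        rec = stage("modules")
        if dys_net.n_ffls:
            key = modules_mod.key_module(dys_net)
            _write(modules_mod.modules_table([key]), out / "key_module.tsv")
            rec["key_module"] = {"hub": key.hub, "n_nodes": len(key)}
            cores = modules_mod.core_modules(
                dys_net,
                min_size=config.min_module_size,
                density_penalty=config.density_penalty,
                merge_threshold=config.merge_threshold,
            )
            _write(modules_mod.modules_table(cores), out / "core_modules.tsv")
            rec["n_core_modules"] = len(cores)
            if config.cernas:
                cernas = modules_mod.read_cerna_triplets(config.cernas)
                complexes = modules_mod.merge_with_cernas(
                    dys, cernas, min_shared=config.min_shared
                )
                _write(
                    modules_mod.modules_table(complexes), out / "complex_modules.tsv"
                )
                rec["n_complex_modules"] = len(complexes)
        else:
            logger.warning("no dysregulated FFLs; module extraction skipped")
            rec["skipped"] = "no dysregulated FFLs"
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage modules failed: {exc}") from exc

    # --- drugs -----------------------------------------------------------
    if config.drug_associations:
        try:
            rec = stage("drugs")
            assoc = drugs_mod.read_associations(config.drug_associations)
            g, hits = drugs_mod.build_drug_network(dys, assoc)
            _write(hits, out / "drug_hits.tsv")
            summ = drugs_mod.summary(g)
            if drugs_mod.drug_nodes(g):
                summ["fraction_of_interest"] = drugs_mod.category_fraction(
                    g, config.categories_of_interest
                )
            with open(out / "drug_summary.json", "w") as fh:
                json.dump(summ, fh, indent=2, sort_keys=True)
                fh.write("\n")
            rec.update(
                {"n_drugs": summ["n_drugs"], "n_targets": summ["n_targets"]}
            )
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(f"stage drugs failed: {exc}") from exc

    manifest["wall_time_s"] = round(time.monotonic() - t0, 3)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    return manifest
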