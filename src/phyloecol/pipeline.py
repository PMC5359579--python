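"""End-to-end pipeline orchestration with provenance capture.

Stages run in a fixed order (qc -> otu -> sad -> alpha -> psv -> beta ->
indval -> mrt -> net); each stage writes plain TSV/JSON artifacts into the
output directory and the run ends with a machine-readable manifest
(thresholds, per-stage child seeds, input digests).  A single top-level
seed deterministically derives every stage's seed, so single stages can be
re-run reproducibly and two runs with the same config are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from . import __version__
from . import beta as beta_mod
from . import mrt as mrt_mod
from . import network as net_mod
from . import otu as otu_mod
from .alpha import diversity_summary
from .indval import indval as _indval
from .psv import psv_null
from .io import (OtuTable, SampleMetadata, read_fasta_alignment, read_metadata,
                 read_newick, read_otu_table, validate_sites, write_metadata,
                 write_newick, write_otu_table, filter_sequences)
from .synth import SynthSpec, generate_dataset

logger = logging.getLogger(__name__)

ALL_STAGES = ("qc", "otu", "sad", "alpha", "psv", "beta", "indval", "mrt", "net")

_FLOAT = "%.10g"


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    """Inputs, thresholds and stage toggles for one pipeline run."""

    out_dir: str = "phyloecol_out"
    seed: int = 0
    stages: tuple = ALL_STAGES
    # inputs: either file paths or a synthetic spec
    fasta: str | None = None
    tree: str | None = None
    otu_table: str | None = None
    lineage: str | None = None
    metadata: str | None = None
    synth: SynthSpec | None = None
    # thresholds (documented defaults follow the clone-library workflow)
    min_len: int = 700
    identity: float = 0.97
    identity_network: float = 0.90
    rho_min: float = 0.6
    p_max: float = 0.01
    min_total: int = 5
    n_perm: int = 1000
    n_subsamples: int = 1000
    n_rand: int = 999
    alpha: float = 0.05

    def __post_init__(self) -> None:
        for name, lo, hi in (("identity", 0, 1), ("identity_network", 0, 1),
                             ("rho_min", -1, 1), ("p_max", 0, 1),
                             ("alpha", 0, 1)):
            v = getattr(self, name)
            if not lo < v < hi:
                raise ValueError(f"{name}={v} outside ({lo}, {hi})")
        for name in ("n_perm", "n_subsamples", "n_rand"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")

    def child_seed(self, stage: str) -> int:
        k = ALL_STAGES.index(stage)
        return int(np.random.SeedSequence([self.seed, 1000 + k])
                   .generate_state(1)[0] % (2**31))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.synth is not None:
            d["synth"] = dataclasses.asdict(self.synth)
            for key in ("sites_per_habitat",):
                d["synth"][key] = dict(d["synth"][key])
        d["stages"] = list(self.stages)
        return d


def _write(df: pd.DataFrame, path: Path, **kw) -> None:
    df.to_csv(path, sep="\t", float_format=_FLOAT, **kw)


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> Path:
    """Execute the configured stages; returns the artifact directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages = [s for s in ALL_STAGES if s in config.stages]
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "stage_seeds": {s: config.child_seed(s) for s in stages},
        "inputs": {},
        "stages_run": stages,
    }

    tree = lineage = metadata = table = None
    seqs = None
    if config.synth is not None:
        logger.info("generating synthetic dataset (seed=%s)", config.synth.seed)
        tree, lineage, metadata, table = generate_dataset(config.synth)
        inputs = out / "inputs"
        inputs.mkdir(exist_ok=True)
        write_newick(tree, inputs / "tree.nwk")
        write_metadata(metadata, inputs / "metadata.tsv")
        write_otu_table(table, inputs / "otu_table.tsv",
                        inputs / "lineage.tsv")
        for f in sorted(inputs.iterdir()):
            manifest["inputs"][f.name] = _digest(f)
    else:
        for name in ("tree", "metadata"):
            p = getattr(config, name)
            if p is not None and not Path(p).exists():
                raise PipelineError(f"{name} path does not exist: {p}")
        if config.metadata is None:
            raise PipelineError("metadata path (or --synth) is required")
        metadata = read_metadata(config.metadata)
        manifest["inputs"]["metadata"] = _digest(Path(config.metadata))
        if config.tree is not None:
            tree = read_newick(config.tree)
            manifest["inputs"]["tree"] = _digest(Path(config.tree))
        if config.fasta is not None:
            seqs = read_fasta_alignment(config.fasta)
            manifest["inputs"]["fasta"] = _digest(Path(config.fasta))
        if config.otu_table is not None:
            table = read_otu_table(config.otu_table, config.lineage,
                                   metadata=metadata)
            manifest["inputs"]["otu_table"] = _digest(Path(config.otu_table))

    failed = None
    try:
        if "qc" in stages and seqs is not None:
            seqs, report = filter_sequences(seqs, config.min_len)
            pd.Series(dataclasses.asdict(report)).to_frame("count").to_csv(
                out / "qc_report.tsv", sep="\t")
        if "otu" in stages and seqs is not None:
            dm = otu_mod.pairwise_pdistance(seqs)
            table, assignment = otu_mod.cluster_otus(
                dm, config.identity, dict(zip(seqs.ids, seqs.site_ids)))
            validate_sites(table, metadata)
            write_otu_table(table, out / "otu_table.tsv", out / "lineage.tsv")
            assignment.to_frame().to_csv(out / "otu_assignment.tsv", sep="\t",
                                         index_label="sequence_id")
        if table is None and set(stages) - {"qc", "otu"}:
            raise PipelineError("no OTU table available (supply --otu-table, "
                                "--fasta or --synth)")
        if "sad" in stages:
            sad = otu_mod.sad_regression(table, metadata)
            _write(sad.per_lineage, out / "sad_per_lineage.tsv",
                   index_label="lineage")
            pd.Series({"slope": sad.slope, "intercept": sad.intercept,
                       "r2": sad.r2, "p": sad.p}).to_frame("value").to_csv(
                out / "sad_regression.tsv", sep="\t", float_format=_FLOAT)
        if "alpha" in stages:
            res = diversity_summary(
                table, tree, metadata, n_subsamples=config.n_subsamples,
                seed=config.child_seed("alpha"))
            _write(res.table, out / "alpha_diversity.tsv",
                   index_label="habitat")
        if "psv" in stages:
            res = psv_null(table, tree, metadata, model="both",
                                   n_rand=config.n_rand,
                                   seed=config.child_seed("psv"))
            full = pd.concat([res.per_habitat,
                              res.pooled.to_frame("pooled_mean").T])
            _write(full, out / "psv.tsv", index_label="habitat")
        if "beta" in stages:
            dm = beta_mod.weighted_unifrac(table, tree)
            _write(pd.DataFrame(dm.data, index=list(dm.ids),
                                columns=list(dm.ids)),
                   out / "unifrac.tsv", index_label="site_id")
            ord_res = beta_mod.pcoa(dm)
            coords = ord_res.coords.copy()
            _write(coords, out / "pcoa_coords.tsv", index_label="site_id")
            pd.Series(ord_res.explained,
                      index=coords.columns).to_frame("explained").to_csv(
                out / "pcoa_explained.tsv", sep="\t", float_format=_FLOAT)
            perm_rows = [beta_mod.permanova(
                dm, metadata.habitat.reindex(list(dm.ids)).rename("habitat"),
                n_perm=config.n_perm, seed=config.child_seed("beta")).table]
            covs = metadata.covariates().reindex(list(dm.ids))
            for col in covs.columns:
                if covs[col].notna().all() and covs[col].nunique() >= 3:
                    perm_rows.append(beta_mod.permanova(
                        dm, covs[col], n_perm=config.n_perm,
                        seed=config.child_seed("beta")).table)
            _write(pd.concat(perm_rows), out / "permanova.tsv",
                   index_label="factor")
        if "indval" in stages:
            res = _indval(table, metadata, n_perm=config.n_perm,
                                    alpha=config.alpha,
                                    seed=config.child_seed("indval"))
            _write(res.table, out / "indval.tsv", index_label="group")
        if "mrt" in stages:
            tree_fit = mrt_mod.mrt_fit(table, metadata,
                                       seed=config.child_seed("mrt"))
            tree_fit.to_json(out / "mrt_tree.json")
            _write(mrt_mod.mrt_leaf_summary(tree_fit, metadata),
                   out / "mrt_leaves.tsv")
            _write(tree_fit.cv_table, out / "mrt_cv.tsv", index=False)
        if "net" in stages:
            corr = net_mod.spearman_matrix(table, min_total=config.min_total)
            G = net_mod.build_network(corr, rho_min=config.rho_min,
                                      p_max=config.p_max, table=table)
            if G.number_of_edges() > 0:
                part, q = net_mod.louvain(G, seed=config.child_seed("net"))
                topo = net_mod.topology(G)
                nodes = topo.nodes.copy()
                nodes["module"] = pd.Series(part)
                nodes["lineage"] = pd.Series(
                    {v: G.nodes[v].get("lineage", "U") for v in G})
                _write(nodes, out / "network_nodes.tsv", index_label="otu_id")
                edges = pd.DataFrame(
                    [(u, v, d["rho"], d["p"]) for u, v, d in
                     sorted(G.edges(data=True))],
                    columns=["otu_i", "otu_j", "rho", "p"])
                _write(edges, out / "network_edges.tsv", index=False)
                graph = topo.graph.copy()
                graph["modularity"] = q
                graph["n_modules"] = len(set(part.values()))
                graph.to_frame("value").to_csv(out / "network_summary.tsv",
                                               sep="\t", float_format=_FLOAT)
                for v in G:
                    G.nodes[v]["module"] = part[v]
                nx.write_graphml(G, out / "network.graphml")
                fisher = net_mod.module_habitat_fisher(part, table, metadata)
                _write(fisher, out / "network_module_fisher.tsv", index=False)
            else:
                logger.warning("no edges pass the thresholds; network outputs "
                               "limited to the empty edge list")
                (out / "network_edges.tsv").write_text(
                    "otu_i\totu_j\trho\tp\n")
    except Exception as exc:
        failed = exc
        manifest["failed_stage"] = _failing_stage(exc)
        raise
    finally:
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
        if failed is not None:
            logger.error("pipeline failed: %s", failed)
    return out


def _failing_stage(exc: Exception) -> str:
    import traceback
    for frame in reversed(traceback.extract_tb(exc.__traceback__)):
        if "pipeline" in frame.filename:
            return f"line {frame.lineno}"
    return "unknown"
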