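"""Phylogenetic species variability (PSV) and community null models.

PSV summarises how phylogenetic relatedness of the taxa in a community
dilutes their expected trait variance under Brownian evolution: 1 for a
star phylogeny (unrelated taxa, overdispersion) and approaching 0 as taxa
become closely related (clustering).  Writing C for the phylogenetic
correlation matrix of the n present taxa,

    PSV = (n * tr(C) - sum(C)) / (n * (n - 1)).

Significance of clustering is assessed against two randomisations:

* null 1 -- shuffle tip labels across the whole phylogeny, keeping the
  community memberships fixed;
* null 2 -- redraw each community's taxa uniformly at random from the full
  taxon pool, preserving observed richness.

Both are one-sided tests for "more clustered (lower PSV) than chance".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import TreeNode

from ._tree import BranchMatrix, branch_matrix, shared_depth_matrix
from .io import OtuTable, SampleMetadata


@dataclass
class PsvResult:
    per_habitat: pd.DataFrame  # psv_observed, null1_mean, null2_mean, p1, p2, n_otus
    pooled: pd.Series          # same fields for the across-habitat mean
    n_randomizations: int


def phylo_corr(tree: TreeNode | BranchMatrix) -> tuple[list[str], np.ndarray]:
    """Phylogenetic correlation matrix C over all tips.

    C_ij is the shared root-to-tip branch length of i and j divided by the
    arithmetic mean of their root-to-tip depths; for an ultrametric tree
    this is the standard correlation under Brownian motion, and the
    diagonal is exactly 1.  For non-ultrametric trees it is an
    approximation (documented as such).
    """
    bm = tree if isinstance(tree, BranchMatrix) else branch_matrix(tree)
    V = shared_depth_matrix(bm)
    d = bm.depths
    if np.any(d <= 0):
        raise ValueError("tips at zero depth; PSV undefined")
    mean_depth = (d[:, None] + d[None, :]) / 2.0
    C = V / mean_depth
    np.fill_diagonal(C, 1.0)
    return bm.tip_ids, C


def psv_from_corr(C_sub: np.ndarray) -> float:
    n = C_sub.shape[0]
    if n < 2:
        raise ValueError("PSV requires at least 2 taxa")
    return float((n * np.trace(C_sub) - C_sub.sum()) / (n * (n - 1)))


def psv(tips_present, tree: TreeNode | BranchMatrix) -> float:
    """PSV of a single community given the full tree."""
    bm = tree if isinstance(tree, BranchMatrix) else branch_matrix(tree)
    ids, C = phylo_corr(bm)
    idx = bm.tip_indexer(list(tips_present))
    if len(idx) < 2:
        raise ValueError("PSV requires at least 2 taxa present")
    return psv_from_corr(C[np.ix_(idx, idx)])


def psv_null(table: OtuTable, tree: TreeNode | BranchMatrix,
             metadata: SampleMetadata, model: str = "null2",
             n_rand: int = 999, seed=None) -> PsvResult:
    """Observed PSV per habitat versus a null model.

    p = (1 + #{null PSV <= observed}) / (1 + n_rand), the one-sided test
    that the community is more phylogenetically clustered than chance.
    ``model`` is ``"null1"``, ``"null2"`` or ``"both"``.  The pooled row
    compares the across-habitat mean of observed PSVs with the mean null
    PSV of each randomisation round.
    """
    if n_rand < 1:
        raise ValueError("n_rand must be >= 1")
    bm = tree if isinstance(tree, BranchMatrix) else branch_matrix(tree)
    ids, C = phylo_corr(bm)
    pool_idx = bm.tip_indexer(table.otus)
    hab = metadata.habitat.reindex(table.counts.index)
    habitats = list(dict.fromkeys(hab))
    present_idx: dict[str, np.ndarray] = {}
    for h in habitats:
        pooled = table.counts.loc[hab.index[hab == h]].sum(axis=0)
        otus = pooled.index[pooled > 0]
        if len(otus) < 2:
            continue
        present_idx[h] = bm.tip_indexer(otus)
    if not present_idx:
        raise ValueError("no habitat has >= 2 OTUs; PSV undefined")
    observed = {h: psv_from_corr(C[np.ix_(i, i)]) for h, i in present_idx.items()}
    models = ("null1", "null2") if model == "both" else (model,)
    for m in models:
        if m not in ("null1", "null2"):
            raise ValueError(f"unknown null model {m!r}")
    rng = np.random.default_rng(seed)
    nulls = {m: {h: np.empty(n_rand) for h in present_idx} for m in models}
    n_pool = len(pool_idx)
    for r in range(n_rand):
        if "null1" in models:
            # shuffle tip labels across the whole phylogeny: a random
            # relabelling of tree positions for the pooled taxon set
            perm = rng.permutation(len(bm.tip_ids))
            for h, idx in present_idx.items():
                pidx = perm[idx]
                nulls["null1"][h][r] = psv_from_corr(C[np.ix_(pidx, pidx)])
        if "null2" in models:
            for h, idx in present_idx.items():
                draw = pool_idx[rng.choice(n_pool, size=len(idx), replace=False)]
                nulls["null2"][h][r] = psv_from_corr(C[np.ix_(draw, draw)])
    rows = {}
    for h in present_idx:
        row = {"psv_observed": observed[h], "n_otus": len(present_idx[h])}
        for m in models:
            k = m[-1]
            null_h = nulls[m][h]
            row[f"{m}_mean"] = float(null_h.mean())
            row[f"p{k}"] = float((1 + np.sum(null_h <= observed[h])) / (1 + n_rand))
        rows[h] = row
    per_habitat = pd.DataFrame(rows).T
    obs_mean = float(np.mean(list(observed.values())))
    pooled = {"psv_observed": obs_mean, "n_otus": int(sum(len(i) for i in present_idx.values()))}
    for m in models:
        k = m[-1]
        null_means = np.mean(np.stack([nulls[m][h] for h in present_idx]), axis=0)
        pooled[f"{m}_mean"] = float(null_means.mean())
        pooled[f"p{k}"] = float((1 + np.sum(null_means <= obs_mean)) / (1 + n_rand))
    return PsvResult(per_habitat, pd.Series(pooled), n_rand)
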