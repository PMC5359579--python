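"""Alpha diversity: Shannon-Wiener entropy and Faith phylogenetic diversity.

Faith PD is the total branch length of the minimal subtree connecting a
community's OTUs to the root.  Because clone libraries differ wildly in
depth, :func:`rarefied_pd` repeats the PD calculation over random
subsamples of clones drawn without replacement, the standard correction
for unequal library sizes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import TreeNode

from ._tree import BranchMatrix, branch_matrix
from .io import OtuTable, SampleMetadata


@dataclass
class DiversityResult:
    """Per-group diversity summary (one row per habitat or site)."""

    table: pd.DataFrame  # n_sites, n_clones, shannon, pd, pd_rarefied_mean, pd_rarefied_sd


def shannon(counts, base: float | None = None) -> float:
    """Shannon-Wiener index H' = -sum p_i ln p_i (natural log by default)."""
    c = np.asarray(counts, dtype=float)
    if c.size == 0 or c.sum() <= 0:
        raise ValueError("shannon requires at least one positive count")
    if (c < 0).any():
        raise ValueError("negative counts")
    p = c[c > 0] / c.sum()
    h = float(-(p * np.log(p)).sum())
    if base is not None:
        h /= np.log(base)
    return max(h, 0.0)


def faith_pd(tips_present, tree: TreeNode | BranchMatrix,
             include_root: bool = True) -> float:
    """Faith PD: branch length of the subtree spanning ``tips_present``.

    With ``include_root`` (the classic definition) the path up to the root
    is counted; otherwise branches above the MRCA of the present tips are
    dropped.
    """
    bm = tree if isinstance(tree, BranchMatrix) else branch_matrix(tree)
    tips = list(tips_present)
    if not tips:
        raise ValueError("faith_pd requires a non-empty tip set")
    idx = bm.tip_indexer(tips)
    present = np.zeros(len(bm.tip_ids), dtype=bool)
    present[idx] = True
    on_path = bm.incidence[:, present].any(axis=1)
    if not include_root:
        # drop branches whose descendant set contains every present tip
        covers_all = (bm.incidence[:, present].sum(axis=1) == present.sum())
        on_path &= ~covers_all
    return float(bm.lengths[on_path].sum())


def rarefied_pd(table: OtuTable, tree: TreeNode | BranchMatrix,
                sites, depth: int, n_subsamples: int = 1000,
                seed=None) -> tuple[float, float]:
    """Mean and sd of PD over random clone subsamples.

    Clones of the given sites are pooled; each subsample draws ``depth``
    clones without replacement and scores the PD of the OTUs hit.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    bm = tree if isinstance(tree, BranchMatrix) else branch_matrix(tree)
    pooled = table.counts.loc[list(sites)].sum(axis=0)
    pooled = pooled[pooled > 0]
    total = int(pooled.sum())
    if depth > total:
        raise ValueError(f"depth {depth} exceeds clone total {total}")
    otu_idx = bm.tip_indexer(pooled.index)
    clones = np.repeat(otu_idx, pooled.to_numpy())
    rng = np.random.default_rng(seed)
    n_tips = len(bm.tip_ids)
    inc = bm.incidence
    values = np.empty(n_subsamples)
    for k in range(n_subsamples):
        draw = rng.choice(clones, size=depth, replace=False)
        present = np.zeros(n_tips, dtype=bool)
        present[draw] = True
        values[k] = bm.lengths[inc[:, present].any(axis=1)].sum()
    return float(values.mean()), float(values.std(ddof=0))


def diversity_summary(table: OtuTable, tree: TreeNode, metadata: SampleMetadata,
                      depth: int | None = None, n_subsamples: int = 1000,
                      seed=None, exclude_single_otu_sites: bool = False
                      ) -> DiversityResult:
    """Per-habitat Shannon and PD with the rarefaction correction.

    ``depth`` defaults to the smallest habitat clone total.  Sites whose
    library contains a single OTU can optionally be excluded from the
    habitat means.
    """
    bm = branch_matrix(tree)
    counts = table.counts
    if exclude_single_otu_sites:
        keep = counts.index[(counts > 0).sum(axis=1) > 1]
        counts = counts.loc[keep]
    hab = metadata.habitat.reindex(counts.index)
    rows = {}
    pooled_by_hab = counts.groupby(hab).sum()
    totals = pooled_by_hab.sum(axis=1)
    if depth is None:
        depth = int(totals.min())
    rng = np.random.default_rng(seed)
    for habitat, pooled in pooled_by_hab.iterrows():
        present = pooled.index[pooled > 0]
        sites = hab.index[hab == habitat]
        mean, sd = rarefied_pd(OtuTable(counts.loc[sites]), bm, sites,
                               depth=min(depth, int(pooled.sum())),
                               n_subsamples=n_subsamples,
                               seed=rng.integers(2**31))
        rows[habitat] = {
            "n_sites": len(sites),
            "n_clones": int(pooled.sum()),
            "shannon": shannon(pooled.to_numpy()),
            "pd": faith_pd(present, bm),
            "pd_rarefied_mean": mean,
            "pd_rarefied_sd": sd,
        }
    return DiversityResult(pd.DataFrame(rows).T)
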