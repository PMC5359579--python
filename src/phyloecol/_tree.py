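"""Matrix views of a rooted phylogeny shared by PD, PSV and UniFrac."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skbio import TreeNode


@dataclass
class BranchMatrix:
    """Branch incidence structure of a rooted tree.

    ``lengths[k]`` is the branch length above internal/tip node ``k`` (the
    root itself has no branch and is excluded); ``incidence[k, j]`` is True
    when tip ``j`` descends through branch ``k``.  ``tip_ids`` fixes the tip
    column order; ``depths[j]`` is the root-to-tip path length of tip ``j``.
    """

    tip_ids: list[str]
    lengths: np.ndarray      # (n_branches,)
    incidence: np.ndarray    # (n_branches, n_tips) bool
    depths: np.ndarray       # (n_tips,)

    @property
    def total_length(self) -> float:
        return float(self.lengths.sum())

    def tip_indexer(self, ids) -> np.ndarray:
        pos = {t: i for i, t in enumerate(self.tip_ids)}
        try:
            return np.array([pos[i] for i in ids], dtype=int)
        except KeyError as exc:
            raise KeyError(f"tip {exc.args[0]!r} not found in tree") from None


def branch_matrix(tree: TreeNode) -> BranchMatrix:
    tips = list(tree.tips())
    tip_ids = [t.name for t in tips]
    pos = {id(t): i for i, t in enumerate(tips)}
    n = len(tips)
    lengths, rows = [], []
    # postorder accumulation of each branch's descendant tip set
    below: dict[int, np.ndarray] = {}
    for node in tree.postorder(include_self=True):
        if node.is_tip():
            mask = np.zeros(n, dtype=bool)
            mask[pos[id(node)]] = True
        else:
            mask = np.zeros(n, dtype=bool)
            for child in node.children:
                mask |= below[id(child)]
        below[id(node)] = mask
        if node is not tree:
            lengths.append(float(node.length or 0.0))
            rows.append(mask)
    lengths_arr = np.array(lengths)
    inc = np.array(rows, dtype=bool) if rows else np.zeros((0, n), dtype=bool)
    depths = lengths_arr @ inc if len(lengths_arr) else np.zeros(n)
    return BranchMatrix(tip_ids, lengths_arr, inc, depths)


def shared_depth_matrix(bm: BranchMatrix) -> np.ndarray:
    """V[i, j] = root-to-MRCA shared branch length of tips i and j."""
    incf = bm.incidence.astype(float)
    return np.einsum("k,ki,kj->ij", bm.lengths, incf, incf)
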