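"""Multivariate regression trees (MRT) for community-environment analysis.

Greedy binary recursive partitioning of a multi-group abundance matrix on
environmental covariates: every split chooses the (covariate, threshold)
pair minimising the total within-child sum of squared Euclidean deviations
from the child mean vectors.  Candidate thresholds are midpoints between
consecutive sorted covariate values; sites with a missing value for the
splitting covariate follow the majority child.  Tree size is selected by
k-fold cross-validated relative error with the 1-SE rule.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import OtuTable, SampleMetadata


@dataclass(eq=False)
class _Node:
    idx: np.ndarray                  # site row indices at this node
    mean: np.ndarray
    ss: float
    covariate: str | None = None
    threshold: float | None = None
    missing_to: str = "left"
    left: "_Node | None" = None
    right: "_Node | None" = None
    rank: int | None = None          # order in which this node was split

    @property
    def is_leaf(self) -> bool:
        return self.covariate is None


@dataclass
class MrtTree:
    root: _Node
    sites: list[str]
    groups: list[str]
    covariate_names: list[str]
    ss_total: float
    size: int                        # selected number of leaves
    cv_table: pd.DataFrame | None    # per size: rel_error, cv_error, cv_se
    _x: pd.DataFrame = field(repr=False, default=None)

    def leaves(self, size: int | None = None) -> list[_Node]:
        size = self.size if size is None else size
        out = []

        def walk(node):
            if node.is_leaf or node.rank is None or node.rank > size - 2:
                out.append(node)
            else:
                walk(node.left)
                walk(node.right)

        walk(self.root)
        return out

    def predict_leaf(self, x_row: pd.Series, size: int | None = None) -> _Node:
        size = self.size if size is None else size
        node = self.root
        while not node.is_leaf and node.rank is not None and node.rank <= size - 2:
            v = x_row.get(node.covariate, np.nan)
            if pd.isna(v):
                node = node.left if node.missing_to == "left" else node.right
            else:
                node = node.left if v <= node.threshold else node.right
        return node

    def within_ss(self, size: int | None = None) -> float:
        return float(sum(l.ss for l in self.leaves(size)))

    def explained_variance(self, size: int | None = None) -> float:
        if self.ss_total <= 0:
            return 0.0
        return 1.0 - self.within_ss(size) / self.ss_total

    def root_split(self) -> tuple[str, float] | None:
        if self.root.is_leaf or self.size < 2:
            return None
        return self.root.covariate, float(self.root.threshold)

    def to_dict(self) -> dict:
        def ser(node, size):
            if node.is_leaf or node.rank is None or node.rank > size - 2:
                return {"leaf": True, "n_sites": len(node.idx),
                        "sites": [self.sites[i] for i in node.idx],
                        "mean": [float(v) for v in node.mean],
                        "ss": node.ss}
            return {"leaf": False, "covariate": node.covariate,
                    "threshold": float(node.threshold),
                    "left": ser(node.left, size), "right": ser(node.right, size)}

        return {"groups": self.groups, "size": self.size,
                "ss_total": self.ss_total,
                "explained_variance": self.explained_variance(),
                "tree": ser(self.root, self.size)}

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)


def _node_stats(Y: np.ndarray, idx: np.ndarray) -> tuple[np.ndarray, float]:
    sub = Y[idx]
    mean = sub.mean(axis=0)
    return mean, float(((sub - mean) ** 2).sum())


def _best_split(Y, X, idx, min_leaf, covariates):
    """Exhaustive search over covariates and midpoint thresholds.

    Returns (decrease, covariate, threshold, left_idx, right_idx,
    missing_to) or None.  Ties resolve to the earliest covariate and the
    lowest threshold (strict improvement required to switch).
    """
    _, parent_ss = _node_stats(Y, idx)
    sq = (Y[idx] ** 2).sum(axis=1)
    best = None
    for cov in covariates:
        vals = X[cov].to_numpy(float)[idx]
        miss = np.isnan(vals)
        obs_idx = idx[~miss]
        miss_idx = idx[miss]
        v = vals[~miss]
        if len(obs_idx) < 2:
            continue
        order = np.argsort(v, kind="stable")
        v_sorted = v[order]
        rows = obs_idx[order]
        ys = Y[rows]
        cum_y = np.cumsum(ys, axis=0)
        cum_sq = np.cumsum((ys ** 2).sum(axis=1))
        tot_y, tot_sq = cum_y[-1], cum_sq[-1]
        miss_y = Y[miss_idx].sum(axis=0) if len(miss_idx) else 0.0
        miss_sq = float((Y[miss_idx] ** 2).sum()) if len(miss_idx) else 0.0
        n_miss = len(miss_idx)
        for k in range(len(v_sorted) - 1):
            if v_sorted[k] == v_sorted[k + 1]:
                continue
            thr = (v_sorted[k] + v_sorted[k + 1]) / 2.0
            nl, nr = k + 1, len(v_sorted) - k - 1
            # missing rows follow the larger child (ties -> left)
            missing_to = "left" if nl >= nr else "right"
            ly, lsq, ln = cum_y[k].copy(), float(cum_sq[k]), nl
            ry, rsq, rn = tot_y - cum_y[k], float(tot_sq - cum_sq[k]), nr
            if n_miss:
                if missing_to == "left":
                    ly, lsq, ln = ly + miss_y, lsq + miss_sq, ln + n_miss
                else:
                    ry, rsq, rn = ry + miss_y, rsq + miss_sq, rn + n_miss
            if ln < min_leaf or rn < min_leaf:
                continue
            child_ss = (lsq - (ly ** 2).sum() / ln) + (rsq - (ry ** 2).sum() / rn)
            dec = parent_ss - child_ss
            if best is None or dec > best[0] + 1e-12:
                left_rows = rows[: k + 1]
                right_rows = rows[k + 1:]
                if n_miss:
                    if missing_to == "left":
                        left_rows = np.concatenate([left_rows, miss_idx])
                    else:
                        right_rows = np.concatenate([right_rows, miss_idx])
                best = (dec, cov, thr, np.sort(left_rows),
                        np.sort(right_rows), missing_to)
    return best


def _grow(Y, X, min_leaf, max_leaves, covariates):
    """Best-first growth; returns root with split ranks 0,1,... assigned."""
    idx0 = np.arange(len(Y))
    mean, ss = _node_stats(Y, idx0)
    root = _Node(idx0, mean, ss)
    frontier = [root]
    rank = 0
    while rank < max_leaves - 1:
        candidates = []
        for node in frontier:
            if getattr(node, "_cand", "unset") == "unset":
                node._cand = _best_split(Y, X, node.idx, min_leaf, covariates)
            if node._cand is not None:
                candidates.append(node)
        if not candidates:
            break
        node = max(candidates, key=lambda nd: nd._cand[0])
        dec, cov, thr, li, ri, mto = node._cand
        ml, sl = _node_stats(Y, li)
        mr, sr = _node_stats(Y, ri)
        node.covariate, node.threshold, node.missing_to = cov, thr, mto
        node.left = _Node(li, ml, sl)
        node.right = _Node(ri, mr, sr)
        node.rank = rank
        rank += 1
        frontier.remove(node)
        frontier.extend([node.left, node.right])
    return root


def mrt_fit(y, x, covariates=None, min_leaf: int = 2,
            max_leaves: int | None = None, cv_folds: int = 10,
            seed=None, size: int | None = None) -> MrtTree:
    """Fit a multivariate regression tree.

    ``y`` is a site x group abundance DataFrame (or :class:`OtuTable`,
    aggregated to lineages); ``x`` a covariate DataFrame or
    :class:`SampleMetadata`.  Unless ``size`` is forced, the number of
    leaves is chosen by ``cv_folds``-fold cross-validated relative error
    with the 1-SE rule (fold assignment seeded).
    """
    if isinstance(y, OtuTable):
        counts = y.lineage_table()
        y = counts.div(counts.sum(axis=1), axis=0)
    if isinstance(x, SampleMetadata):
        x = x.covariates()
    x = x.reindex(y.index)
    covariates = list(covariates) if covariates is not None else list(x.columns)
    for cov in covariates:
        if not pd.api.types.is_numeric_dtype(x[cov]):
            raise ValueError(f"covariate {cov!r} is not numeric")
    n = len(y)
    if n < 2 * min_leaf:
        raise ValueError("too few sites for the requested min_leaf")
    if max_leaves is None:
        max_leaves = int(min(10, n // min_leaf))
    Y = y.to_numpy(float)
    root = _grow(Y, x, min_leaf, max_leaves, covariates)
    tree = MrtTree(root, list(y.index), list(y.columns), covariates,
                   root.ss, max_leaves, None, x)
    grown = len(tree.leaves(max_leaves))
    if grown == 1:
        warnings.warn("no valid split found; returning a single-leaf tree")
        tree.size = 1
        return tree
    sizes = np.arange(1, grown + 1)
    rel = np.array([1.0 - tree.explained_variance(m) if root.ss > 0 else 0.0
                    for m in sizes])
    if size is not None:
        tree.size = int(min(size, grown))
        tree.cv_table = pd.DataFrame({"size": sizes, "rel_error": rel})
        return tree
    # cross-validated relative error
    rng = np.random.default_rng(seed)
    folds = rng.permutation(n) % cv_folds if cv_folds <= n else np.arange(n)
    n_folds = len(np.unique(folds))
    fold_err = np.zeros((n_folds, len(sizes)))
    for f in range(n_folds):
        test = np.where(folds == f)[0]
        train = np.where(folds != f)[0]
        sub_y = y.iloc[train]
        sub_root = _grow(sub_y.to_numpy(float), x.iloc[train], min_leaf,
                         max_leaves, covariates)
        sub = MrtTree(sub_root, list(sub_y.index), tree.groups, covariates,
                      sub_root.ss, max_leaves, None, x.iloc[train])
        for si, m in enumerate(sizes):
            err = 0.0
            for t in test:
                leaf = sub.predict_leaf(x.iloc[t], size=int(m))
                err += float(((Y[t] - leaf.mean) ** 2).sum())
            fold_err[f, si] = err
    # each fold holds ~1/n_folds of the data: scale to a relative error
    rel_f = fold_err * n_folds / max(root.ss, 1e-300)
    cv_err = rel_f.mean(axis=0)
    cv_se = rel_f.std(axis=0, ddof=1) / np.sqrt(n_folds) if n_folds > 1 else \
        np.zeros_like(cv_err)
    best = int(np.argmin(cv_err))
    ok = np.where(cv_err <= cv_err[best] + cv_se[best] + 1e-12)[0]
    tree.size = int(sizes[ok[0]])
    tree.cv_table = pd.DataFrame({"size": sizes, "rel_error": rel,
                                  "cv_error": cv_err, "cv_se": cv_se})
    return tree


def mrt_leaf_summary(tree: MrtTree, metadata: SampleMetadata | None = None
                     ) -> pd.DataFrame:
    """Per-leaf composition: mean abundance vector, site count, habitat tally."""
    rows = []
    for k, leaf in enumerate(tree.leaves(), start=1):
        sites = [tree.sites[i] for i in leaf.idx]
        row = {"leaf": k, "n_sites": len(sites), "ss": leaf.ss,
               "sites": ",".join(sites)}
        row.update({g: float(m) for g, m in zip(tree.groups, leaf.mean)})
        if metadata is not None:
            tally = metadata.habitat.reindex(sites).value_counts()
            row["habitats"] = ";".join(f"{h}:{c}" for h, c in tally.items())
        rows.append(row)
    return pd.DataFrame(rows).set_index("leaf")
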