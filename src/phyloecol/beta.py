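"""Beta diversity: weighted UniFrac, PCoA and permutational MANOVA.

Weighted UniFrac between two clone libraries A and B is the branch-length
weighted divergence of their abundance distributions on the tree,

    W(A, B) = sum_i b_i |p_i^A - p_i^B|,

where p_i^X is the fraction of X's clones descending through branch i.
The normalised variant divides by sum_i b_i (p_i^A + p_i^B), bounding the
distance in [0, 1].  PCoA embeds the distance matrix by Gower double
centering and eigendecomposition; PERMANOVA partitions the squared
distances against habitat labels or numeric covariates (McArdle-Anderson
hat-matrix form) with permutation p-values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import DistanceMatrix as SkbioDM
from skbio import TreeNode

from ._tree import BranchMatrix, branch_matrix
from .io import OtuTable, SampleMetadata


@dataclass
class PcoaResult:
    coords: pd.DataFrame          # sites x axes (PC1, PC2, ...)
    explained: np.ndarray         # fraction of positive-eigenvalue mass per axis
    eigenvalues: np.ndarray       # all eigenvalues, descending
    negative_mass: float          # sum |negative eigenvalues| / sum |eigenvalues|


@dataclass
class PermanovaResult:
    table: pd.DataFrame  # per factor: df, SS, R2, pseudo_F, p
    n_perm: int
    mode: str


def weighted_unifrac(table: OtuTable, tree: TreeNode | BranchMatrix,
                     normalized: bool = True) -> SkbioDM:
    """Pairwise weighted UniFrac distances between all sites."""
    bm = tree if isinstance(tree, BranchMatrix) else branch_matrix(tree)
    counts = table.counts
    totals = counts.sum(axis=1)
    empty = totals.index[totals == 0]
    if len(empty):
        warnings.warn(f"excluding empty sites: {list(empty)}")
        counts = counts.drop(index=empty)
        totals = totals.drop(index=empty)
    idx = bm.tip_indexer(counts.columns)  # raises for OTUs absent from tree
    frac = np.zeros((len(counts), len(bm.tip_ids)))
    frac[:, idx] = counts.to_numpy(float) / totals.to_numpy(float)[:, None]
    # per-branch descendant fraction for every site: sites x branches
    P = frac @ bm.incidence.T.astype(float)
    b = bm.lengths
    n = len(counts)
    d = np.zeros((n, n))
    for i in range(n):
        diff = np.abs(P[i] - P[i + 1:])
        raw = diff @ b
        if normalized:
            denom = (P[i] + P[i + 1:]) @ b
            with np.errstate(invalid="ignore", divide="ignore"):
                raw = np.where(denom > 0, raw / denom, 0.0)
        d[i, i + 1:] = raw
    d = d + d.T
    return SkbioDM(d, ids=list(counts.index))


def pcoa(dm, n_axes: int | None = None, lingoes: bool = False) -> PcoaResult:
    """Principal coordinates analysis by Gower double centering.

    Explained fractions are eigenvalue shares of the positive-eigenvalue
    mass; negative-eigenvalue mass (non-Euclidean distortion) is reported
    separately.  ``lingoes`` adds the Lingoes constant correction
    (adds -2*lambda_min to all squared off-diagonal distances).
    """
    if isinstance(dm, SkbioDM):
        ids, D = list(dm.ids), dm.data.copy()
    else:
        D = np.asarray(dm, dtype=float)
        ids = [str(i) for i in range(len(D))]
    if D.shape[0] != D.shape[1] or not np.allclose(D, D.T):
        raise ValueError("PCoA requires a square symmetric matrix")
    n = len(D)
    J = np.eye(n) - np.ones((n, n)) / n
    G = -0.5 * J @ (D ** 2) @ J
    eigval, eigvec = np.linalg.eigh((G + G.T) / 2.0)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    if lingoes and eigval[-1] < -1e-12:
        c = -eigval[-1]
        D2 = D ** 2 + 2.0 * c * (1 - np.eye(n))
        G = -0.5 * J @ D2 @ J
        eigval, eigvec = np.linalg.eigh((G + G.T) / 2.0)
        order = np.argsort(eigval)[::-1]
        eigval, eigvec = eigval[order], eigvec[:, order]
    tol = max(abs(eigval).max(), 1.0) * 1e-12
    pos = eigval > tol
    coords = eigvec[:, pos] * np.sqrt(eigval[pos])
    if n_axes is not None:
        coords = coords[:, :n_axes]
    explained = eigval[pos] / eigval[pos].sum() if pos.any() else np.array([])
    neg_mass = float(np.abs(eigval[eigval < -tol]).sum())
    denom = float(np.abs(eigval).sum())
    cols = [f"PC{k + 1}" for k in range(coords.shape[1])]
    return PcoaResult(pd.DataFrame(coords, index=ids, columns=cols),
                      explained[: coords.shape[1]], eigval,
                      neg_mass / denom if denom > 0 else 0.0)


def _gower(D: np.ndarray) -> np.ndarray:
    n = len(D)
    J = np.eye(n) - np.ones((n, n)) / n
    return -0.5 * J @ (D ** 2) @ J


def _hat(X: np.ndarray) -> np.ndarray:
    Q, _ = np.linalg.qr(X)
    return Q @ Q.T


def _design(factor: pd.Series, ids) -> tuple[np.ndarray, int]:
    """Design matrix (without intercept) and its df for one factor."""
    x = factor.reindex(ids)
    if x.isna().any():
        raise ValueError("factor has missing values for some sites")
    if pd.api.types.is_numeric_dtype(x):
        vals = x.to_numpy(float)
        if len(np.unique(vals)) < 3:
            raise ValueError("numeric covariate needs >= 3 distinct values")
        return vals[:, None] - vals.mean(), 1
    levels = pd.unique(x)
    if len(levels) < 2:
        raise ValueError("categorical factor must have >= 2 groups")
    dummies = pd.get_dummies(x).to_numpy(float)[:, :-1]
    return dummies - dummies.mean(axis=0), len(levels) - 1


def permanova(dm, factors, n_perm: int = 1000, seed=None,
              mode: str = "sequential") -> PermanovaResult:
    """Permutational MANOVA on a distance matrix.

    ``factors`` is a Series (one factor, categorical or numeric) or a
    DataFrame of several.  With several factors ``mode='sequential'``
    attributes sums of squares in column order (Type-I) while
    ``mode='marginal'`` tests each factor alone.  pseudo-F for a term uses
    the residual of the fullest model containing it; p-values come from
    permuting sample identities (rows/columns of the distance matrix).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if isinstance(dm, SkbioDM):
        ids, D = list(dm.ids), dm.data
    else:
        D = np.asarray(dm, dtype=float)
        ids = list(factors.index) if hasattr(factors, "index") else \
            [str(i) for i in range(len(D))]
    n = len(D)
    if isinstance(factors, pd.Series):
        factors = factors.to_frame(factors.name or "factor")
    G = _gower(D)
    ss_total = float(np.trace(G))
    designs, dfs = {}, {}
    for col in factors.columns:
        designs[col], dfs[col] = _design(factors[col], ids)
    rng = np.random.default_rng(seed)
    perms = [np.arange(n)] + [rng.permutation(n) for _ in range(n_perm)]

    # hat matrices do not depend on the permutation (G is permuted instead)
    hats = {}
    if mode == "sequential":
        X = np.ones((n, 1))
        prev_hat = _hat(X)
        for col in factors.columns:
            X = np.hstack([X, designs[col]])
            cur_hat = _hat(X)
            hats[col] = cur_hat - prev_hat  # projector difference: term SS
            prev_hat = cur_hat
    elif mode == "marginal":
        for col in factors.columns:
            X = np.hstack([np.ones((n, 1)), designs[col]])
            hats[col] = _hat(X)
    else:
        raise ValueError(f"unknown mode {mode!r}")

    def term_stats(G_):
        """SS per term under the chosen mode for one (permuted) G."""
        return {col: float(np.sum(hats[col] * G_)) for col in factors.columns}

    # residual df from the full model (sequential) or per-factor (marginal)
    rows = []
    obs = term_stats(G)
    if mode == "sequential":
        df_model = sum(dfs.values())
        ss_resid = ss_total - sum(obs.values())
        resid_df = n - 1 - df_model
    f_obs, f_perm = {}, {col: np.empty(n_perm) for col in factors.columns}
    for k, p in enumerate(perms):
        Gp = G[np.ix_(p, p)]
        ss = obs if k == 0 else term_stats(Gp)
        for col in factors.columns:
            if mode == "marginal":
                rdf = n - 1 - dfs[col]
                rss = ss_total - ss[col]
            else:
                rdf = resid_df
                rss = ss_total - sum(ss.values())
            F = (ss[col] / dfs[col]) / (rss / rdf) if rdf > 0 and rss > 0 else np.inf
            if k == 0:
                f_obs[col] = F
            else:
                f_perm[col][k - 1] = F
    for col in factors.columns:
        p_val = (1 + np.sum(f_perm[col] >= f_obs[col])) / (1 + n_perm)
        rows.append({"factor": col, "df": dfs[col], "SS": obs[col],
                     "R2": obs[col] / ss_total, "pseudo_F": f_obs[col],
                     "p": float(p_val)})
    if mode == "sequential":
        rows.append({"factor": "Residual", "df": resid_df, "SS": ss_resid,
                     "R2": ss_resid / ss_total, "pseudo_F": np.nan, "p": np.nan})
    out = pd.DataFrame(rows).set_index("factor")
    return PermanovaResult(out, n_perm, mode)
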