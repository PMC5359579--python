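"""Independent brute-force oracles used to validate the implementations.

Every function here recomputes a quantity from first principles by a
different route than the package (explicit path/branch enumeration,
exhaustive search, closed forms) so that agreement is meaningful.
"""

import itertools
import math

import numpy as np
from scipy import special


def tip_names(tree):
    return [t.name for t in tree.tips()]


def branch_tip_sets(tree):
    """[(branch_length, frozenset of descendant tip names)] by recursion."""
    out = []

    def walk(node):
        if node.is_tip():
            tips = frozenset([node.name])
        else:
            tips = frozenset()
            for child in node.children:
                tips |= walk(child)
        if node.parent is not None:
            out.append((float(node.length or 0.0), tips))
        return tips

    walk(tree)
    return out


def unifrac_bruteforce(tree, counts_a, counts_b, normalized=True):
    """Weighted UniFrac by explicit per-branch enumeration.

    ``counts_a``/``counts_b`` map tip name -> count.
    """
    ta, tb = sum(counts_a.values()), sum(counts_b.values())
    raw = denom = 0.0
    for length, tips in branch_tip_sets(tree):
        pa = sum(counts_a.get(t, 0) for t in tips) / ta
        pb = sum(counts_b.get(t, 0) for t in tips) / tb
        raw += length * abs(pa - pb)
        denom += length * (pa + pb)
    if normalized:
        return raw / denom if denom > 0 else 0.0
    return raw


def root_path(tree, name):
    node = next(t for t in tree.tips() if t.name == name)
    path = []
    while node.parent is not None:
        path.append(node)
        node = node.parent
    return path


def psv_bruteforce(tree, present):
    """PSV via per-pair path enumeration of shared branch lengths."""
    present = list(present)
    n = len(present)
    depths = {t: sum(float(n_.length) for n_ in root_path(tree, t))
              for t in present}
    C = np.eye(n)
    for i, j in itertools.combinations(range(n), 2):
        pi = set(id(x) for x in root_path(tree, present[i]))
        shared = sum(float(x.length) for x in root_path(tree, present[j])
                     if id(x) in pi)
        C[i, j] = C[j, i] = shared / ((depths[present[i]] +
                                       depths[present[j]]) / 2.0)
    return (n * np.trace(C) - C.sum()) / (n * (n - 1))


def spearman_bruteforce(x, y):
    """Spearman rho and two-sided t-approximation p, midranks by hand."""

    def midrank(v):
        v = np.asarray(v, dtype=float)
        order = np.argsort(v, kind="stable")
        ranks = np.empty(len(v))
        i = 0
        sv = v[order]
        while i < len(v):
            j = i
            while j + 1 < len(v) and sv[j + 1] == sv[i]:
                j += 1
            ranks[order[i:j + 1]] = (i + j) / 2.0 + 1.0
            i = j + 1
        return ranks

    rx, ry = midrank(x), midrank(y)
    rho = np.corrcoef(rx, ry)[0, 1]
    n = len(rx)
    if abs(rho) >= 1.0:
        return float(np.sign(rho)), 0.0
    t = rho * math.sqrt((n - 2) / (1 - rho ** 2))
    p = 2 * special.stdtr(n - 2, -abs(t))
    return float(rho), float(p)


def fisher_bruteforce(a, b, c, d):
    """Two-sided Fisher exact p by hypergeometric enumeration."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(x):
        return (math.comb(r1, x) * math.comb(r2, c1 - x)) / math.comb(n, c1)

    p_obs = prob(a)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    return sum(prob(x) for x in range(lo, hi + 1)
               if prob(x) <= p_obs * (1 + 1e-9))


def ols_bruteforce(x, y):
    """Slope, intercept, R^2 by the normal equations."""
    X = np.column_stack([np.ones(len(x)), np.asarray(x, float)])
    beta = np.linalg.solve(X.T @ X, X.T @ np.asarray(y, float))
    resid = y - X @ beta
    ss_res = float(resid @ resid)
    ss_tot = float(((y - np.mean(y)) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return float(beta[1]), float(beta[0]), r2

def permanova_f(D, labels):
    """Pseudo-F from the direct group-sum decomposition (Anderson)."""
    D = np.asarray(D, float)
    labels = np.asarray(labels)
    n = len(labels)
    ss_total = (D ** 2).sum() / (2 * n)
    ss_within = 0.0
    groups = np.unique(labels)
    for g in groups:
        idx = np.where(labels == g)[0]
        ss_within += (D[np.ix_(idx, idx)] ** 2).sum() / (2 * len(idx))
    a = len(groups)
    ss_between = ss_total - ss_within
    return (ss_between / (a - 1)) / (ss_within / (n - a))


def mrt_best_split_bruteforce(Y, X_df, min_leaf=1):
    """Exhaustive (covariate, threshold) search minimising child SS."""

    def ss(rows):
        sub = Y[rows]
        return float(((sub - sub.mean(axis=0)) ** 2).sum()) if len(rows) else 0.0

    n = len(Y)
    best = None
    for cov in X_df.columns:
        v = X_df[cov].to_numpy(float)
        for thr in np.unique(v):
            left = np.where(v <= thr)[0]
            right = np.where(v > thr)[0]
            if len(left) < min_leaf or len(right) < min_leaf:
                continue
            total = ss(left) + ss(right)
            if best is None or total < best[0] - 1e-12:
                best = (total, cov, thr)
    return best
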