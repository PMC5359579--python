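"""Dufrene-Legendre indicator value (IndVal) analysis.

For group g and habitat h, specificity A is g's mean relative abundance in
h divided by the sum of its habitat means, fidelity B is the fraction of
h's sites where g occurs, and IndVal = A * B.  A group's indicator habitat
is the habitat maximising IndVal; significance comes from permuting the
site -> habitat labels (habitat sizes fixed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import OtuTable, SampleMetadata


@dataclass
class IndvalResult:
    table: pd.DataFrame          # per group: habitat, A, B, indval, p, significant
    matrix: pd.DataFrame         # group x habitat IndVal matrix (observed)
    n_perm: int
    alpha: float


def _indval_matrix(frac: np.ndarray, occ: np.ndarray, hab_codes: np.ndarray,
                   n_hab: int, mode: str) -> np.ndarray:
    """IndVal matrix (n_groups x n_habitats) from per-site fractions."""
    n_sites, n_groups = frac.shape
    sums_a = np.zeros((n_hab, n_groups))
    sums_b = np.zeros((n_hab, n_groups))
    sizes = np.bincount(hab_codes, minlength=n_hab).astype(float)
    np.add.at(sums_a, hab_codes, frac)
    np.add.at(sums_b, hab_codes, occ)
    mean_a = sums_a / sizes[:, None]          # habitat means of abundance
    B = sums_b / sizes[:, None]               # fidelity
    if mode == "presence":
        mean_a = B.copy()
    denom = mean_a.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        A = np.where(denom > 0, mean_a / denom, 0.0)
    return (A * B).T


def indval(table, metadata: SampleMetadata, by: str = "lineage",
           n_perm: int = 999, alpha: float = 0.05, seed=None,
           mode: str = "abundance") -> IndvalResult:
    """Indicator value of each group for each habitat, with permutation p.

    ``table`` is an :class:`OtuTable` (aggregated to ``by`` = 'lineage' or
    analysed per 'otu'; counts are converted to per-site relative
    abundances) or a ready site x group abundance DataFrame, used as-is.
    ``mode='presence'`` replaces abundance-based specificity with
    presence-based.  p per group = (1 + #{permuted max-IndVal >= observed
    max}) / (1 + n_perm).
    """
    if isinstance(table, OtuTable):
        counts = table.lineage_table() if by == "lineage" else table.counts
        totals = counts.sum(axis=1)
        counts = counts.div(totals.where(totals > 0, 1.0), axis=0)
    else:
        counts = table
    hab = metadata.habitat.reindex(counts.index)
    if hab.isna().any():
        raise ValueError("unlabelled sites in metadata")
    habitats = pd.unique(hab)
    if len(habitats) < 2:
        raise ValueError("IndVal requires >= 2 habitats")
    absent = counts.columns[counts.sum(axis=0) == 0]
    if len(absent):
        warnings.warn(f"excluding groups absent everywhere: {list(absent)}")
        counts = counts.drop(columns=absent)
    frac = counts.to_numpy(float)
    occ = (frac > 0).astype(float)
    hab_codes = pd.Categorical(hab, categories=habitats).codes.astype(int)
    n_hab = len(habitats)
    obs_mat = _indval_matrix(frac, occ, hab_codes, n_hab, mode)
    obs_max = obs_mat.max(axis=1)
    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(obs_max))
    for _ in range(n_perm):
        perm = rng.permutation(hab_codes)
        pm = _indval_matrix(frac, occ, perm, n_hab, mode)
        exceed += pm.max(axis=1) >= obs_max - 1e-12
    p = (1 + exceed) / (1 + n_perm)
    best = obs_mat.argmax(axis=1)
    # recompute A, B at the best habitat for reporting
    sums_a = np.zeros((n_hab, frac.shape[1]))
    sums_b = np.zeros((n_hab, frac.shape[1]))
    sizes = np.bincount(hab_codes, minlength=n_hab).astype(float)
    np.add.at(sums_a, hab_codes, frac)
    np.add.at(sums_b, hab_codes, occ)
    mean_a = sums_a / sizes[:, None]
    if mode == "presence":
        mean_a = sums_b / sizes[:, None]
    denom = mean_a.sum(axis=0)
    A_mat = np.where(denom > 0, mean_a / denom, 0.0).T
    B_mat = (sums_b / sizes[:, None]).T
    rows = pd.DataFrame({
        "habitat": [habitats[b] for b in best],
        "A": A_mat[np.arange(len(best)), best],
        "B": B_mat[np.arange(len(best)), best],
        "indval": obs_max,
        "p": p,
    }, index=counts.columns)
    rows["significant"] = rows["p"] <= alpha
    matrix = pd.DataFrame(obs_mat, index=counts.columns, columns=habitats)
    return IndvalResult(rows, matrix, n_perm, alpha)
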