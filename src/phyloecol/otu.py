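"""Pairwise distances, OTU clustering and abundance summaries.

Sequences are clustered into OTUs by complete-linkage (furthest-neighbour)
agglomeration of uncorrected p-distances, the classic clone-library
workflow: at identity threshold ``t`` two clusters merge only while the
maximum pairwise distance stays at or below ``1 - t``.  The resulting
site x OTU count table feeds every downstream analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy import stats

from .io import AlignedSeqSet, OtuTable, SampleMetadata

_ACGT = "ACGT"


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix over sequence ids."""

    ids: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.ids)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match ids")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix not symmetric")
        if np.any(np.diag(self.d) != 0):
            raise ValueError("distance matrix diagonal not zero")
        if self.d.size and (self.d.min() < 0 or self.d.max() > 1):
            raise ValueError("distances must lie in [0, 1]")


@dataclass
class SadResult:
    """Occupancy-abundance ('SAD') regression across lineages."""

    per_lineage: pd.DataFrame  # columns: mean_relative_abundance, occurrence
    slope: float
    intercept: float
    r2: float
    p: float


def pairwise_pdistance(seqs: AlignedSeqSet,
                       correction: str = "p") -> DistanceMatrix:
    """Uncorrected p-distance between aligned sequences.

    Columns where either sequence has a gap (or any non-ACGT symbol) are
    excluded pair-by-pair; the distance is mismatches / compared columns.
    ``correction='jc'`` applies the Jukes-Cantor transform
    ``-3/4 ln(1 - 4p/3)`` (capped at 1).
    """
    ids = seqs.ids
    n = len(ids)
    if n == 0:
        return DistanceMatrix([], np.zeros((0, 0)))
    L = seqs.n_columns
    # one-hot encode: comparable mask + per-base identity
    arr = np.frombuffer("".join(r.residues for r in seqs.records).encode(),
                        dtype="S1").reshape(n, L)
    comparable = np.isin(arr, [b"A", b"C", b"G", b"T"])
    onehot = np.stack([(arr == base.encode()) & comparable for base in _ACGT],
                      axis=0).astype(np.float32)  # 4 x n x L
    comp_f = comparable.astype(np.float32)
    n_comp = comp_f @ comp_f.T
    n_match = np.einsum("bil,bjl->ij", onehot, onehot)
    if np.any((n_comp == 0) & ~np.eye(n, dtype=bool)):
        i, j = np.argwhere((n_comp == 0) & ~np.eye(n, dtype=bool))[0]
        raise ValueError(
            f"no comparable columns between {ids[i]!r} and {ids[j]!r}")
    with np.errstate(invalid="ignore", divide="ignore"):
        d = 1.0 - n_match / n_comp
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, 1.0).astype(float)
    if correction == "jc":
        with np.errstate(invalid="ignore"):
            d = np.where(d < 0.7499, -0.75 * np.log1p(-4.0 * d / 3.0), 1.0)
        d = np.clip(d, 0.0, 1.0)
        np.fill_diagonal(d, 0.0)
    elif correction != "p":
        raise ValueError(f"unknown correction {correction!r}")
    return DistanceMatrix(ids, d)


def cluster_otus(dm: DistanceMatrix, identity: float,
                 site_ids: dict[str, str] | list[str],
                 seq_lineage: dict[str, str] | None = None) -> tuple[OtuTable, pd.Series]:
    """Complete-linkage OTU clustering at an identity threshold.

    ``site_ids`` maps each sequence id to its site (or is a parallel list).
    Returns the site x OTU count table plus the per-sequence OTU
    assignment.  OTU ids are "OTU_0001", ... in order of first member
    appearance.  The per-OTU lineage label is the majority label of member
    sequences when ``seq_lineage`` is given, else "U".
    """
    if not 0 < identity < 1:
        raise ValueError("identity must be in (0, 1)")
    cutoff = 1.0 - identity
    ids = dm.ids
    n = len(ids)
    if isinstance(site_ids, dict):
        sites = [site_ids[i] for i in ids]
    else:
        sites = list(site_ids)
    if n == 0:
        empty = OtuTable(pd.DataFrame(dtype=int), identity=identity)
        return empty, pd.Series(dtype=object)
    if n == 1:
        labels = np.array([1])
    else:
        Z = linkage(squareform(dm.d, checks=False), method="complete")
        labels = fcluster(Z, t=cutoff, criterion="distance")
    # relabel clusters in order of first appearance
    order: dict[int, int] = {}
    otu_of_seq = []
    for lab in labels:
        if lab not in order:
            order[lab] = len(order) + 1
        otu_of_seq.append(f"OTU_{order[lab]:04d}")
    assignment = pd.Series(otu_of_seq, index=ids, name="otu_id")
    otu_ids = [f"OTU_{k:04d}" for k in range(1, len(order) + 1)]
    site_order = list(dict.fromkeys(sites))
    counts = pd.DataFrame(0, index=site_order, columns=otu_ids, dtype=int)
    for site, otu in zip(sites, otu_of_seq):
        counts.loc[site, otu] += 1
    lineage = None
    if seq_lineage is not None:
        lin = {}
        for otu in otu_ids:
            members = assignment.index[assignment == otu]
            labs = pd.Series([seq_lineage.get(m, "U") for m in members])
            lin[otu] = labs.mode().iloc[0]
        lineage = pd.Series(lin)
    return OtuTable(counts, lineage, identity), assignment


def relative_abundance(table: OtuTable, by: str = "otu", group: str = "site",
                       metadata: SampleMetadata | None = None):
    """Relative abundances per site, or habitat means (+ variances).

    ``by`` aggregates columns to lineage labels first.  With
    ``group='site'`` returns a DataFrame whose rows sum to 1; with
    ``group='habitat'`` returns ``(mean, variance)`` DataFrames of the
    member-site fractions per habitat (population variance would hide
    single-site habitats, so the ddof=0 variance is reported).
    """
    counts = table.lineage_table() if by == "lineage" else table.counts
    totals = counts.sum(axis=1)
    empty = totals.index[totals == 0]
    if len(empty):
        warnings.warn(f"excluding sites with zero total count: {list(empty)}")
        counts = counts.drop(index=empty)
        totals = totals.drop(index=empty)
    frac = counts.div(totals, axis=0)
    if group == "site":
        return frac
    if group != "habitat":
        raise ValueError(f"unknown group {group!r}")
    if metadata is None:
        raise ValueError("metadata required when group='habitat'")
    hab = metadata.habitat.reindex(frac.index)
    mean = frac.groupby(hab).mean()
    var = frac.groupby(hab).var(ddof=0)
    return mean, var


def sad_regression(table: OtuTable, metadata: SampleMetadata | None = None,
                   by: str = "lineage") -> SadResult:
    """Occupancy-abundance regression across lineages.

    Ordinary least squares of each lineage's mean relative abundance
    (averaged over sites) on its occurrence (number of sites where it was
    detected).  Requires at least 3 lineages.
    """
    counts = table.lineage_table() if by == "lineage" else table.counts
    frac = counts.div(counts.sum(axis=1), axis=0)
    mean_ra = frac.mean(axis=0)
    occurrence = (counts > 0).sum(axis=0)
    if len(mean_ra) < 3:
        raise ValueError("SAD regression needs at least 3 lineages")
    res = stats.linregress(occurrence.to_numpy(float), mean_ra.to_numpy(float))
    per = pd.DataFrame({"mean_relative_abundance": mean_ra,
                        "occurrence": occurrence})
    return SadResult(per, float(res.slope), float(res.intercept),
                     float(res.rvalue ** 2), float(res.pvalue))
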