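"""Readers, writers and sequence selection filters.

The pipeline's external formats are deliberately boring: aligned FASTA for
sequences, newick for the rooted phylogeny, and tab-separated tables for
OTU counts and per-site metadata.  Everything downstream works on the three
containers defined here: :class:`AlignedSeqSet`, :class:`OtuTable` and
:class:`SampleMetadata`.
"""

from __future__ import annotations

import io as _io
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO
from skbio import TreeNode

logger = logging.getLogger(__name__)

#: canonical habitat vocabulary; extensible (any non-empty label is accepted)
KNOWN_HABITATS = ("peat", "soil", "hot_spring", "lagoon", "mangrove", "estuary")

#: environmental covariates the pipeline knows how to interpret
ENV_COLUMNS = ("pH", "salinity", "temperature", "TOC", "TN")

UNAMBIGUOUS = frozenset("ACGT-")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass
class SeqRecord:
    id: str
    site_id: str
    residues: str


@dataclass
class AlignedSeqSet:
    """A set of aligned nucleotide sequences (equal-length rows).

    Each record carries the site (clone library) it came from, parsed from
    the FASTA header.
    """

    records: list[SeqRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        lengths = {len(r.residues) for r in self.records}
        if len(lengths) > 1:
            offender = next(
                r for r in self.records
                if len(r.residues) != len(self.records[0].residues)
            )
            raise FormatError(
                f"ragged alignment: record {offender.id!r} has length "
                f"{len(offender.residues)}, expected {len(self.records[0].residues)}"
            )
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            dup = next(i for i in ids if ids.count(i) > 1)
            raise FormatError(f"duplicate sequence id {dup!r}")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def n_columns(self) -> int:
        return len(self.records[0].residues) if self.records else 0

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    @property
    def site_ids(self) -> list[str]:
        return [r.site_id for r in self.records]


@dataclass
class FilterReport:
    n_kept: int
    n_too_short: int
    n_ambiguous: int


@dataclass
class SampleMetadata:
    """Per-site habitat labels and environmental covariates.

    ``table`` is indexed by site_id; it always has a ``habitat`` column and
    whatever numeric covariates were supplied (pH, salinity in PSU,
    temperature in degrees C, TOC and TN in % dry weight).  Missing cells
    are NaN and are never imputed here.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.table.index.is_unique:
            dups = self.table.index[self.table.index.duplicated()].tolist()
            raise FormatError(f"duplicate site ids in metadata: {dups}")
        if "habitat" not in self.table.columns:
            raise FormatError("metadata must have a 'habitat' column")
        hab = self.table["habitat"]
        empty = self.table.index[hab.isna() | (hab.astype(str).str.strip() == "")]
        if len(empty):
            raise FormatError(f"sites with empty habitat: {empty.tolist()}")

    @property
    def sites(self) -> list[str]:
        return self.table.index.tolist()

    @property
    def habitat(self) -> pd.Series:
        return self.table["habitat"]

    def covariates(self, columns=None) -> pd.DataFrame:
        cols = list(columns) if columns is not None else [
            c for c in ENV_COLUMNS if c in self.table.columns
        ]
        return self.table[cols]

    def sites_in(self, habitat: str) -> list[str]:
        return self.table.index[self.table["habitat"] == habitat].tolist()


@dataclass
class OtuTable:
    """Site x OTU count matrix with an OTU -> lineage label map.

    ``counts`` rows are sites (clone libraries), columns are OTU ids, values
    are non-negative integer clone counts.  ``lineage`` maps every OTU id to
    a lineage/subgroup label ("U" for unclassified).  ``identity`` records
    the clustering identity threshold the table was built at (0.97, 0.90, or
    None when unknown).
    """

    counts: pd.DataFrame
    lineage: pd.Series | None = None
    identity: float | None = None

    def __post_init__(self) -> None:
        arr = self.counts.to_numpy()
        if arr.size and (arr < 0).any():
            raise ValueError("negative counts in OTU table")
        if arr.size and not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                raise ValueError("non-integer counts in OTU table")
            self.counts = self.counts.astype(int)
        if self.lineage is None:
            self.lineage = pd.Series("U", index=self.counts.columns, name="lineage")
        else:
            missing = self.counts.columns.difference(self.lineage.index)
            if len(missing):
                extra = pd.Series("U", index=missing)
                self.lineage = pd.concat([self.lineage, extra])
            self.lineage = self.lineage.reindex(self.counts.columns)
            self.lineage.name = "lineage"

    @property
    def sites(self) -> list[str]:
        return self.counts.index.tolist()

    @property
    def otus(self) -> list[str]:
        return self.counts.columns.tolist()

    @property
    def n_sequences(self) -> int:
        return int(self.counts.to_numpy().sum())

    def drop_empty_otus(self) -> "OtuTable":
        keep = self.counts.columns[self.counts.sum(axis=0) > 0]
        return OtuTable(self.counts[keep], self.lineage.reindex(keep), self.identity)

    def lineage_table(self) -> pd.DataFrame:
        """Aggregate counts to site x lineage."""
        return self.counts.T.groupby(self.lineage).sum().T


# ---------------------------------------------------------------------------
# FASTA

def read_fasta_alignment(path, site_delimiter: str = "|",
                         site_field: int = 0) -> AlignedSeqSet:
    """Read an aligned FASTA file.

    The site id is taken from the header, split on ``site_delimiter`` and
    indexed with ``site_field`` (a header without the delimiter yields the
    whole id as its own site).  Residues are upper-cased on read.  All
    records must have identical aligned length.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        parts = rec.id.split(site_delimiter)
        site = parts[site_field] if len(parts) > site_field else parts[0]
        records.append(SeqRecord(rec.id, site, str(rec.seq).upper()))
    if not records:
        warnings.warn(f"empty FASTA file: {path}")
    return AlignedSeqSet(records)


def filter_sequences(seqs: AlignedSeqSet,
                     min_len: int = 700) -> tuple[AlignedSeqSet, FilterReport]:
    """Apply the sequence selection criteria.

    A record is kept iff its ungapped length is strictly greater than
    ``min_len`` AND it contains no ambiguity codes (anything outside
    A, C, G, T and the gap character).  Order is preserved; the report
    counts removals by (first matching) reason.
    """
    kept, n_short, n_amb = [], 0, 0
    for rec in seqs.records:
        ungapped = len(rec.residues) - rec.residues.count("-")
        if ungapped <= min_len:
            n_short += 1
        elif set(rec.residues) - UNAMBIGUOUS:
            n_amb += 1
        else:
            kept.append(rec)
    return AlignedSeqSet(kept), FilterReport(len(kept), n_short, n_amb)


# ---------------------------------------------------------------------------
# Newick

def read_newick(path, on_missing_length: str = "error") -> TreeNode:
    """Read a rooted newick tree with branch lengths.

    ``on_missing_length`` is ``"error"`` (default) or ``"zero"`` (assume 0
    with a warning).  A root with more than two children is taken to be an
    unrooted tree and rejected.
    """
    tree = TreeNode.read(str(path), format="newick")
    return _validate_tree(tree, on_missing_length)


def parse_newick(newick: str, on_missing_length: str = "error") -> TreeNode:
    tree = TreeNode.read(_io.StringIO(newick), format="newick")
    return _validate_tree(tree, on_missing_length)


def _validate_tree(tree: TreeNode, on_missing_length: str) -> TreeNode:
    if len(tree.children) > 2:
        raise FormatError(
            "input tree appears unrooted (root has more than two children); "
            "root it (e.g. by outgroup or midpoint) before use"
        )
    missing = [n for n in tree.traverse(include_self=False) if n.length is None]
    if missing:
        if on_missing_length == "zero":
            warnings.warn(f"{len(missing)} branches lack lengths; assuming 0")
            for n in missing:
                n.length = 0.0
        else:
            raise FormatError(
                f"missing branch length on node {missing[0].name!r} "
                "(pass on_missing_length='zero' to assume 0)"
            )
    bad = [n for n in tree.traverse(include_self=False)
           if not np.isfinite(n.length) or n.length < 0]
    if bad:
        raise FormatError(f"non-finite or negative branch length at {bad[0].name!r}")
    tips = [t.name for t in tree.tips()]
    if len(set(tips)) != len(tips):
        dup = next(t for t in tips if tips.count(t) > 1)
        raise FormatError(f"duplicate tip label {dup!r}")
    tree.length = None
    return tree


def write_newick(tree: TreeNode, path) -> None:
    tree.write(str(path), format="newick")


# ---------------------------------------------------------------------------
# TSV tables

def read_metadata(path) -> SampleMetadata:
    """Read per-site metadata (TSV, sites as rows, first column = site id)."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})
    df.index = df.index.astype(str)
    for col in ENV_COLUMNS:
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce")
    return SampleMetadata(df)


def write_metadata(meta: SampleMetadata, path) -> None:
    meta.table.to_csv(path, sep="\t", index_label="site_id",
                      float_format="%.10g")


def read_otu_table(path, lineage_path=None, metadata: SampleMetadata | None = None,
                   identity: float | None = None) -> OtuTable:
    """Read a site x OTU TSV count table (sites as rows).

    ``lineage_path`` is an optional 2-column sidecar TSV (otu_id, lineage).
    If ``metadata`` is supplied, sites present in the table but absent from
    the metadata raise an error naming the orphans.
    """
    counts = pd.read_csv(path, sep="\t", index_col=0)
    counts.index = counts.index.astype(str)
    counts.index.name = None
    lineage = None
    if lineage_path is not None:
        lin = pd.read_csv(lineage_path, sep="\t", index_col=0)
        lineage = lin.iloc[:, 0].astype(str)
        lineage.index = lineage.index.astype(str)
        lineage.index.name = None
    table = OtuTable(counts, lineage, identity)
    if metadata is not None:
        validate_sites(table, metadata)
    return table


def write_otu_table(table: OtuTable, path, lineage_path=None) -> None:
    table.counts.to_csv(path, sep="\t", index_label="site_id")
    if lineage_path is not None:
        table.lineage.to_frame().to_csv(lineage_path, sep="\t",
                                        index_label="otu_id")


def validate_sites(table: OtuTable, metadata: SampleMetadata) -> None:
    orphans = [s for s in table.sites if s not in metadata.table.index]
    if orphans:
        raise FormatError(f"sites in OTU table absent from metadata: {orphans}")
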