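"""Readers, writers, rarefaction and occurrence filtering.

On-disk dialects
----------------
Feature table: TSV with taxa as rows and samples as columns, header
``#TaxonID<TAB>sample1<TAB>...``; a BIOM-style TSV (leading line
``# Constructed from biom file``, header ``#OTU ID ...``) is accepted.
A ``orientation="samples_by_taxa"`` flag declares a transposed file.
Tree: Newick with branch lengths. Metadata: TSV with header
``sample_id  dataset  stage_year  month  replicate`` followed by numeric
environmental columns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from skbio import TreeNode

from .containers import (
    CommunityTable,
    FormatError,
    SampleMetadata,
    ValidationError,
    validate_tree,
)

__all__ = [
    "read_community_table",
    "write_community_table",
    "read_newick",
    "write_newick",
    "read_metadata",
    "write_metadata",
    "rarefy",
    "RarefactionReport",
    "filter_by_occurrence",
]

logger = logging.getLogger(__name__)


def read_community_table(
    path: str | Path,
    format: str = "tsv",
    orientation: str = "taxa_by_samples",
) -> CommunityTable:
    """Read a feature table from TSV.

    Parameters
    ----------
    format:
        ``"tsv"`` (header ``#TaxonID ...``) or ``"biom_tsv"`` (one leading
        comment line, then the header).
    orientation:
        ``"taxa_by_samples"`` (default on-disk convention) or
        ``"samples_by_taxa"`` for transposed files.
    """
    path = Path(path)
    if format not in ("tsv", "biom_tsv"):
        raise ValueError(f"unknown table format {format!r}")
    if orientation not in ("taxa_by_samples", "samples_by_taxa"):
        raise ValueError(f"unknown orientation {orientation!r}")
    skiprows = 1 if format == "biom_tsv" else 0
    with open(path) as fh:
        for _ in range(skiprows):
            fh.readline()
        header = fh.readline().rstrip("\n").split("\t")[1:]
    if len(header) != len(set(header)):
        dups = sorted({h for h in header if header.count(h) > 1})
        raise FormatError(f"duplicate labels in {path}: {dups}")
    df = pd.read_csv(path, sep="\t", index_col=0, skiprows=skiprows)
    if df.index.has_duplicates:
        raise FormatError(f"duplicate labels in {path}")
    arr = df.to_numpy()
    if not np.issubdtype(arr.dtype, np.number):
        raise ValidationError(f"non-numeric entries in {path}")
    if np.any(arr < 0) or not np.all(np.equal(np.mod(arr, 1), 0)):
        raise ValidationError(f"counts in {path} must be non-negative integers")
    if orientation == "taxa_by_samples":
        df = df.T
    df.index.name = "sample_id"
    df.columns.name = "taxon_id"
    return CommunityTable(df.astype(np.int64))


def write_community_table(
    table: CommunityTable,
    path: str | Path,
    format: str = "tsv",
    orientation: str = "taxa_by_samples",
) -> None:
    df = table.data
    if orientation == "taxa_by_samples":
        df = df.T
        df.index.name = "#TaxonID"
    else:
        df = df.copy()
        df.index.name = "#SampleID"
    with open(path, "w") as fh:
        if format == "biom_tsv":
            fh.write("# Constructed from biom file\n")
        df.to_csv(fh, sep="\t")


def read_newick(path: str | Path) -> TreeNode:
    """Read a rooted Newick tree and validate branch lengths."""
    tree = TreeNode.read(str(path), format="newick")
    validate_tree(tree)
    return tree


def write_newick(tree: TreeNode, path: str | Path) -> None:
    tree.write(str(path), format="newick")


def read_metadata(path: str | Path) -> SampleMetadata:
    df = pd.read_csv(path, sep="\t", index_col="sample_id")
    return SampleMetadata(df)


def write_metadata(meta: SampleMetadata, path: str | Path) -> None:
    df = meta.frame.copy()
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t")


@dataclass
class RarefactionReport:
    """Outcome of rarefaction: retained depth and any dropped samples."""

    depth: int
    dropped: list[str]
    kept: list[str]


def rarefy(
    table: CommunityTable,
    depth: int,
    seed: int = 0,
) -> tuple[CommunityTable, RarefactionReport]:
    """Subsample every sample to exactly ``depth`` reads without replacement.

    Each retained sample is drawn from a multivariate hypergeometric
    distribution over its own reads, so per-taxon counts never exceed the
    originals and column sums are exactly ``depth``. Samples whose total is
    below ``depth`` are dropped and listed in the report.
    """
    if depth <= 0:
        raise ValueError(f"rarefaction depth must be >= 1, got {depth}")
    rng = np.random.default_rng(seed)
    totals = table.data.sum(axis=1)
    kept = [s for s in table.sample_ids if totals[s] >= depth]
    dropped = [s for s in table.sample_ids if totals[s] < depth]
    if not kept:
        raise ValueError("all samples fall below the rarefaction depth")
    if dropped:
        logger.info("rarefy: dropping %d samples below depth %d: %s",
                    len(dropped), depth, dropped)
    rows = []
    for s in kept:
        counts = table.data.loc[s].to_numpy()
        if counts.sum() == depth:
            rows.append(counts)
        else:
            rows.append(rng.multivariate_hypergeometric(counts, depth))
    out = pd.DataFrame(
        np.vstack(rows), index=pd.Index(kept, name="sample_id"),
        columns=table.data.columns,
    )
    return CommunityTable(out), RarefactionReport(depth, dropped, kept)


def filter_by_occurrence(
    table: CommunityTable, min_occurrence: int
) -> CommunityTable:
    """Keep taxa present (count > 0) in strictly more than ``min_occurrence``
    samples; samples are unchanged."""
    if min_occurrence < 0:
        raise ValueError("min_occurrence must be >= 0")
    occ = (table.data > 0).sum(axis=0)
    keep = occ > min_occurrence
    return CommunityTable(table.data.loc[:, keep].copy())
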