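"""Core domain containers shared by every analysis stage.

The package standardises on a small set of in-memory objects:

* :class:`CommunityTable` — a samples x taxa matrix of non-negative integer
  counts (ASV/OTU abundances), wrapping a :class:`pandas.DataFrame`.
* :class:`SampleMetadata` — per-sample design variables (nucleic-acid
  fraction, successional stage, sampling month, replicate) plus optional
  numeric environmental columns.
* Phylogenies are :class:`skbio.TreeNode` objects (rooted, with branch
  lengths); distance matrices are :class:`skbio.DistanceMatrix`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode

__all__ = [
    "CommunityTable",
    "SampleMetadata",
    "DATASETS",
    "STAGE_YEARS",
    "MONTHS",
    "ValidationError",
    "FormatError",
    "validate_tree",
]

#: Closed vocabularies of the sampling design.
DATASETS = ("DNA", "RNA")
STAGE_YEARS = (0, 10, 40, 70, 110)
MONTHS = ("May", "Jul", "Sep", "Nov")


class ValidationError(ValueError):
    """An object violates a container invariant."""


class FormatError(ValueError):
    """A file does not conform to the expected on-disk dialect."""


@dataclass
class CommunityTable:
    """Samples x taxa matrix of non-negative integer counts.

    Parameters
    ----------
    data:
        DataFrame with samples as the index and taxa as the columns.
        Values must be non-negative integers.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample labels: {dups}")
        if df.columns.has_duplicates:
            dups = df.columns[df.columns.duplicated()].unique().tolist()
            raise FormatError(f"duplicate taxon labels: {dups}")
        arr = df.to_numpy()
        if arr.size and not np.issubdtype(arr.dtype, np.number):
            raise ValidationError("counts must be numeric")
        if arr.size:
            if np.any(arr < 0):
                raise ValidationError("counts must be non-negative")
            if not np.all(np.equal(np.mod(arr, 1), 0)):
                raise ValidationError("counts must be integers")
        self.data = df.astype(np.int64)

    # -- accessors ---------------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def counts(self) -> np.ndarray:
        """Samples x taxa integer matrix (a copy-free view when possible)."""
        return self.data.to_numpy()

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.data.shape[1]

    def sample_counts(self, sample_id: str) -> np.ndarray:
        return self.data.loc[sample_id].to_numpy()

    def relative_abundance(self) -> pd.DataFrame:
        """Row-normalised table; all-zero samples stay zero."""
        totals = self.data.sum(axis=1).replace(0, 1)
        return self.data.div(totals, axis=0)

    def subset_samples(self, sample_ids: Sequence[str]) -> "CommunityTable":
        missing = set(sample_ids) - set(self.data.index)
        if missing:
            raise KeyError(f"samples not in table: {sorted(missing)}")
        return CommunityTable(self.data.loc[list(sample_ids)].copy())

    def drop_empty_taxa(self) -> "CommunityTable":
        keep = self.data.sum(axis=0) > 0
        return CommunityTable(self.data.loc[:, keep].copy())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CommunityTable):
            return NotImplemented
        return self.data.equals(other.data)


@dataclass
class SampleMetadata:
    """Per-sample design factors and environmental measurements.

    ``frame`` is indexed by sample id and carries the design columns
    ``dataset``, ``stage_year``, ``month``, ``replicate``; any further
    numeric columns are treated as environmental variables.
    """

    frame: pd.DataFrame
    REQUIRED = ("dataset", "stage_year", "month", "replicate")

    def __post_init__(self) -> None:
        df = self.frame
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise ValidationError(f"metadata missing columns: {missing}")
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids in metadata: {dups}")
        bad = set(df["dataset"]) - set(DATASETS)
        if bad:
            raise ValidationError(
                f"unknown dataset value(s) {sorted(bad)}; expected {DATASETS}"
            )
        bad_m = set(df["month"]) - set(MONTHS)
        if bad_m:
            raise ValidationError(
                f"unknown month value(s) {sorted(bad_m)}; expected {MONTHS}"
            )
        self.frame = df

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame.index)

    @property
    def env_columns(self) -> list[str]:
        return [c for c in self.frame.columns if c not in self.REQUIRED]

    def env(self, variable: str) -> pd.Series:
        if variable not in self.env_columns:
            raise KeyError(f"unknown environmental variable {variable!r}")
        return self.frame[variable]

    def covers(self, table: CommunityTable) -> bool:
        return set(table.sample_ids) <= set(self.frame.index)

    def require_covers(self, table: CommunityTable) -> None:
        missing = set(table.sample_ids) - set(self.frame.index)
        if missing:
            raise ValidationError(
                f"samples without metadata: {sorted(missing)[:5]}..."
            )

    def subset(self, sample_ids: Sequence[str]) -> "SampleMetadata":
        return SampleMetadata(self.frame.loc[list(sample_ids)].copy())


def validate_tree(tree: TreeNode, taxa: Iterable[str] | None = None) -> None:
    """Check a phylogeny satisfies the invariants the analyses rely on.

    The tree must be rooted (single root), tips uniquely labelled, every
    non-root branch must carry a non-negative length, and — when ``taxa``
    is given — the tip set must cover those taxa.
    """
    tips = [t.name for t in tree.tips()]
    if len(tips) != len(set(tips)):
        raise ValidationError("duplicate tip labels in tree")
    for node in tree.traverse(include_self=False):
        if node.length is None:
            if node.name:
                label = node.name
            elif node.is_tip():
                label = "<unnamed tip>"
            else:
                inside = ",".join(t.name or "?" for t in list(node.tips())[:3])
                label = f"clade({inside})"
            raise ValidationError(f"branch leading to {label} has no length")
        if node.length < 0:
            raise ValidationError("negative branch length")
    if taxa is not None:
        missing = set(taxa) - set(tips)
        if missing:
            raise ValidationError(
                f"taxa absent from tree: {sorted(missing)[:10]}"
            )
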