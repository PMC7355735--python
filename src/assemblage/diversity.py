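"""Alpha- and beta-diversity metrics.

Shannon uses natural logarithms, so Pielou's evenness is H / ln(richness).
UniFrac (weighted: unnormalized by default) and Faith's PD delegate to
scikit-bio; Bray-Curtis to scipy.
"""

from __future__ import annotations

import itertools
import warnings

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix, TreeNode
from skbio.diversity import beta_diversity
from skbio.diversity.alpha import faith_pd

from .containers import CommunityTable, SampleMetadata, validate_tree

__all__ = [
    "alpha_diversity",
    "bray_curtis",
    "unifrac",
    "temporal_turnover",
]


def alpha_diversity(
    table: CommunityTable, tree: TreeNode | None = None
) -> pd.DataFrame:
    """Per-sample richness, Shannon (nats), Pielou evenness and Faith's PD.

    Pielou is NaN for samples with a single taxon (ln richness = 0), and
    all metrics are NaN for empty samples. Faith's PD requires ``tree``.
    """
    counts = table.counts.astype(float)
    if tree is not None:
        validate_tree(tree, table.taxon_ids)
    records = []
    for i, sid in enumerate(table.sample_ids):
        row = counts[i]
        total = row.sum()
        if total == 0:
            warnings.warn(f"sample {sid} is empty; alpha metrics undefined")
            records.append((sid, 0, np.nan, np.nan, np.nan))
            continue
        p = row[row > 0] / total
        richness = int(p.size)
        shannon = float(-(p * np.log(p)).sum())
        pielou = shannon / np.log(richness) if richness > 1 else np.nan
        pd_val = np.nan
        if tree is not None:
            pd_val = float(faith_pd(row, table.taxon_ids, tree))
        records.append((sid, richness, shannon, pielou, pd_val))
    return pd.DataFrame(
        records, columns=["sample_id", "richness", "shannon", "pielou", "faith_pd"]
    ).set_index("sample_id")


def bray_curtis(table: CommunityTable) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarity, d = sum|x-y| / sum(x+y)."""
    if table.n_samples < 2:
        raise ValueError("need at least 2 samples")
    counts = table.counts.astype(float)
    empty = counts.sum(axis=1) == 0
    if empty.any():
        bad = [s for s, e in zip(table.sample_ids, empty) if e]
        warnings.warn(f"all-zero samples make Bray-Curtis undefined: {bad}")
    dm = squareform(pdist(counts, metric="braycurtis"))
    dm = np.nan_to_num(dm, nan=0.0)  # pairs of all-zero samples
    return DistanceMatrix(dm, ids=table.sample_ids)


def unifrac(
    table: CommunityTable,
    tree: TreeNode,
    weighted: bool = True,
    normalized: bool = False,
) -> DistanceMatrix:
    """Weighted (default, unnormalized) or unweighted UniFrac.

    Unweighted UniFrac is the fraction of branch length on the union
    subtree unique to one sample; weighted UniFrac sums branch lengths
    times the absolute difference in the proportion of each sample's
    reads descending from that branch.
    """
    validate_tree(tree, table.taxon_ids)
    if weighted:
        metric = "weighted_unifrac"
        kwargs = {"normalized": normalized}
    else:
        metric = "unweighted_unifrac"
        kwargs = {}
    return beta_diversity(
        metric,
        table.counts,
        ids=table.sample_ids,
        taxa=table.taxon_ids,
        tree=tree,
        **kwargs,
    )


def temporal_turnover(
    dist: DistanceMatrix, meta: SampleMetadata
) -> pd.DataFrame:
    """Within-stage, cross-month pairwise distances, per dataset.

    Returns one row per (same dataset, same stage, different month) sample
    pair with columns ``dataset, stage_year, month_a, month_b, replicate_a,
    replicate_b, sample_a, sample_b, distance``. Pairs sampled in the same
    month are excluded; a (dataset, stage) group in which all samples share
    one month contributes nothing and triggers a warning.
    """
    ids = list(dist.ids)
    mf = meta.frame.loc[ids]
    rows = []
    for (ds, stage), grp in mf.groupby(["dataset", "stage_year"], sort=True):
        if grp["month"].nunique() < 2:
            warnings.warn(
                f"dataset {ds}, stage {stage}: fewer than two months sampled; "
                "no temporal turnover"
            )
            continue
        for a, b in itertools.combinations(grp.index, 2):
            ma, mb = grp.loc[a, "month"], grp.loc[b, "month"]
            if ma == mb:
                continue
            # canonical order: by month position then replicate
            rows.append(
                (
                    ds, stage, ma, mb,
                    grp.loc[a, "replicate"], grp.loc[b, "replicate"],
                    a, b, dist[a, b],
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "dataset", "stage_year", "month_a", "month_b",
            "replicate_a", "replicate_b", "sample_a", "sample_b", "distance",
        ],
    )
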