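"""Phylogenetic signal in environmental optima.

βNTI inference is only licensed when close relatives have similar niches.
This module estimates each taxon's environmental optimum as the
abundance-weighted average of the environments in which it occurs, and
tests, with a Mantel correlogram, whether taxa at short phylogenetic
(patristic) distances have more similar optima than expected by chance.

Correlogram conventions: distance classes partition (0, max patristic
distance] into equal-width bins (Sturges' rule on the number of pairs
when not given); the Mantel statistic per class is the Pearson
correlation between niche distances and the 0/1 class-membership
indicator with its sign inverted, so positive values at short distances
mean phylogenetic signal; p-values come from joint row/column
permutations of the niche-distance matrix (two-tailed), with
progressive Holm correction across classes.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform
from skbio import DistanceMatrix, TreeNode

from .containers import CommunityTable, SampleMetadata

__all__ = [
    "cophenetic_matrix",
    "niche_optima",
    "mantel_correlogram",
    "phylogenetic_signal",
]


def cophenetic_matrix(tree: TreeNode) -> DistanceMatrix:
    """Patristic (branch-length path) distance between every pair of tips."""
    return tree.tip_tip_distances()


def niche_optima(
    table: CommunityTable,
    env: pd.Series | pd.DataFrame,
) -> pd.DataFrame:
    """Abundance-weighted environmental optimum per taxon.

    ``optimum_t = sum_s(count_ts * env_s) / sum_s(count_ts)`` for each
    environmental column; the result also carries each taxon's occurrence
    (number of samples with count > 0). Taxa with zero total count are
    excluded with a warning. Every sample with nonzero counts must have
    an environmental value.
    """
    if isinstance(env, pd.Series):
        env = env.to_frame()
    missing = set(table.sample_ids) - set(env.index)
    nonzero = table.data.sum(axis=1) > 0
    missing &= set(table.data.index[nonzero])
    if missing:
        raise ValueError(f"samples without environmental values: {sorted(missing)[:5]}")
    env = env.loc[table.sample_ids]
    counts = table.data.astype(float)
    totals = counts.sum(axis=0)
    empty = totals[totals == 0].index.tolist()
    if empty:
        warnings.warn(f"excluding {len(empty)} zero-count taxa from niche optima")
        counts = counts.drop(columns=empty)
        totals = totals.drop(empty)
    optima = counts.T.to_numpy() @ env.to_numpy() / totals.to_numpy()[:, None]
    out = pd.DataFrame(optima, index=counts.columns, columns=list(env.columns))
    out["occurrence"] = (counts > 0).sum(axis=0).astype(int)
    out.index.name = "taxon_id"
    return out


def _holm_adjust(ps: np.ndarray) -> np.ndarray:
    """Holm step-down adjusted p-values (monotone, capped at 1)."""
    n = ps.size
    order = np.argsort(ps)
    adj = np.empty(n)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (n - rank) * ps[idx])
        adj[idx] = min(1.0, running)
    return adj


def _holm_progressive(p_raw: np.ndarray) -> np.ndarray:
    """Progressive correction: class k's p-value is Holm-adjusted within
    the family of the first k+1 classes (NaN classes pass through and do
    not count toward the family size)."""
    out = np.full_like(p_raw, np.nan, dtype=float)
    for k in range(p_raw.size):
        if np.isnan(p_raw[k]):
            continue
        family_idx = np.flatnonzero(~np.isnan(p_raw[: k + 1]))
        adj = _holm_adjust(p_raw[family_idx])
        out[k] = adj[family_idx == k][0]
    return out


def mantel_correlogram(
    phylo_dist: DistanceMatrix,
    niche_dist: DistanceMatrix,
    n_classes: int | None = None,
    n_perm: int = 999,
    seed: int = 0,
) -> pd.DataFrame:
    """Mantel correlogram of niche distance against phylogenetic distance.

    Returns one row per distance class with ``lower, upper, midpoint,
    n_pairs, mantel_r, p_raw, p_corrected``. Classes without pairs are
    flagged with NaN statistics.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if set(phylo_dist.ids) != set(niche_dist.ids):
        raise ValueError("matrices must share taxon ids")
    niche_dist = niche_dist.filter(phylo_dist.ids)
    pvec = phylo_dist.condensed_form()
    nsq = niche_dist.data
    T = len(phylo_dist.ids)
    m = pvec.size
    if m < 1:
        raise ValueError("need at least 2 taxa to build a correlogram")
    if n_classes is None:
        n_classes = int(math.ceil(1 + math.log2(m)))  # Sturges on pair count
    dmax = pvec.max()
    edges = np.linspace(0.0, dmax, n_classes + 1)
    # class of each pair: (lower, upper] bins
    cls = np.clip(np.searchsorted(edges, pvec, side="left") - 1, 0, n_classes - 1)
    n_pairs = np.bincount(cls, minlength=n_classes)

    xvec = squareform(nsq, checks=False)
    x_mean = xvec.mean()
    x_ss = ((xvec - x_mean) ** 2).sum()

    def class_r(values: np.ndarray) -> np.ndarray:
        sums = np.bincount(cls, weights=values, minlength=n_classes)
        with np.errstate(invalid="ignore", divide="ignore"):
            num = sums - n_pairs * x_mean
            den = np.sqrt(n_pairs * (1.0 - n_pairs / m) * x_ss)
            r = num / den
        return -r  # sign inverted: positive = similarity within the class

    r_obs = class_r(xvec)
    r_obs[n_pairs == 0] = np.nan

    rng = np.random.default_rng(seed)
    exceed = np.zeros(n_classes)
    for _ in range(n_perm):
        p = rng.permutation(T)
        xp = squareform(nsq[np.ix_(p, p)], checks=False)
        r_perm = class_r(xp)
        exceed += np.abs(r_perm) >= np.abs(r_obs)  # two-tailed
    p_raw = (exceed + 1.0) / (n_perm + 1.0)
    p_raw[n_pairs == 0] = np.nan
    p_corr = _holm_progressive(p_raw)

    return pd.DataFrame(
        {
            "lower": edges[:-1],
            "upper": edges[1:],
            "midpoint": 0.5 * (edges[:-1] + edges[1:]),
            "n_pairs": n_pairs,
            "mantel_r": r_obs,
            "p_raw": p_raw,
            "p_corrected": p_corr,
        }
    )


def phylogenetic_signal(
    table: CommunityTable,
    tree: TreeNode,
    meta: SampleMetadata,
    env_vars: list[str] | None = None,
    min_occurrence: int = 5,
    n_classes: int | None = None,
    n_perm: int = 999,
    seed: int = 0,
) -> dict[str, pd.DataFrame]:
    """One Mantel correlogram per environmental variable.

    Taxa are restricted to occurrence strictly above ``min_occurrence``;
    niche distance is the absolute difference of abundance-weighted
    optima.
    """
    from .io import filter_by_occurrence  # local import avoids cycle

    meta.require_covers(table)
    env_vars = env_vars or meta.env_columns
    work = filter_by_occurrence(table, min_occurrence)
    env = meta.frame.loc[work.sample_ids, env_vars]
    optima = niche_optima(work, env)
    phylo = cophenetic_matrix(tree).filter(list(optima.index))
    results = {}
    for i, var in enumerate(env_vars):
        vals = optima[var].to_numpy()
        nd = DistanceMatrix(
            np.abs(vals[:, None] - vals[None, :]), ids=list(optima.index)
        )
        results[var] = mantel_correlogram(
            phylo, nd, n_classes=n_classes, n_perm=n_perm, seed=seed + i
        )
    return results
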