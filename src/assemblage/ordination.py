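"""Ordination and hypothesis tests: PCoA, sequential PERMANOVA, Wilcoxon.

The PERMANOVA is the distance-based multivariate ANOVA of McArdle &
Anderson: the Gower-centered matrix G of the (squared, halved) distances
is partitioned by projection ("hat") matrices of a sequential (Type I)
design, so sums of squares for each term are conditioned on all terms
listed before it. Pseudo-F per term uses the residual mean square;
p-values come from free permutation of sample identities.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from skbio import DistanceMatrix
from skbio.stats.ordination import pcoa as _skbio_pcoa

from .containers import SampleMetadata

__all__ = [
    "PcoaResult",
    "pcoa",
    "permanova",
    "factorial_terms",
    "wilcoxon_signed_rank",
]


@dataclass
class PcoaResult:
    """Principal-coordinate embedding of a distance matrix.

    ``proportion_explained`` is computed over positive eigenvalues only;
    negative eigenvalues (non-Euclidean input) are reported uncorrected.
    """

    coordinates: pd.DataFrame
    eigenvalues: pd.Series
    proportion_explained: pd.Series


def pcoa(dist: DistanceMatrix) -> PcoaResult:
    if len(dist.ids) < 3:
        raise ValueError("PCoA needs at least 3 samples")
    res = _skbio_pcoa(dist, method="eigh", number_of_dimensions=0)
    eig = res.eigvals
    pos = eig[eig > 0]
    prop = pd.Series(np.zeros(len(eig)), index=eig.index)
    if len(pos):
        prop[pos.index] = pos / pos.sum()
    return PcoaResult(res.samples, eig, prop)


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------

def factorial_terms(factors: list[str]) -> list[tuple[str, ...]]:
    """Main effects then all interactions, in order of increasing order:
    A, B, C, A:B, A:C, B:C, A:B:C."""
    terms: list[tuple[str, ...]] = []
    for k in range(1, len(factors) + 1):
        terms.extend(itertools.combinations(factors, k))
    return terms


def _term_design(mf: pd.DataFrame, term: tuple[str, ...]) -> np.ndarray:
    """Cell-indicator columns for the (interaction) term."""
    key = mf[list(term)].astype(str).agg(":".join, axis=1)
    return pd.get_dummies(key).to_numpy(dtype=float)


def _hat(X: np.ndarray) -> tuple[np.ndarray, int]:
    """Projection matrix onto the column space of X, and its rank.

    SVD-based so rank-deficient (aliased) designs project correctly.
    """
    u, s, _ = np.linalg.svd(X, full_matrices=False)
    keep = s > s.max() * 1e-10
    u = u[:, keep]
    return u @ u.T, int(keep.sum())


def permanova(
    dist: DistanceMatrix,
    meta: SampleMetadata | pd.DataFrame,
    formula: list[str] | list[tuple[str, ...]],
    n_perm: int = 9999,
    seed: int = 0,
) -> pd.DataFrame:
    """Sequential (Type I) multi-factor PERMANOVA on a distance matrix.

    ``formula`` is an ordered list of factor names (expanded to the full
    factorial with all interactions) or an explicit ordered list of
    terms, each a tuple of factor names. Returns a table with one row per
    term plus Residual and Total, carrying df, SS, MS, pseudo-F, R2 and
    the permutation p-value. All terms share one permutation scheme.
    """
    mf = meta.frame if isinstance(meta, SampleMetadata) else meta
    ids = list(dist.ids)
    missing = set(ids) - set(mf.index)
    if missing:
        raise ValueError(f"samples without metadata: {sorted(missing)[:5]}")
    mf = mf.loc[ids]
    if formula and isinstance(formula[0], str):
        terms = factorial_terms(list(formula))  # type: ignore[arg-type]
    else:
        terms = [tuple(t) for t in formula]     # type: ignore[union-attr]
    for name in {f for t in terms for f in t}:
        if mf[name].nunique() < 2:
            raise ValueError(f"factor {name!r} has a single level")

    n = len(ids)
    D = dist.data
    A = -0.5 * D**2
    J = np.eye(n) - np.ones((n, n)) / n
    G = J @ A @ J

    ones = np.ones((n, 1))
    H_prev, rank_prev = _hat(ones)
    X = ones
    hat_diffs, dfs = [], []
    for term in terms:
        X = np.hstack([X, _term_design(mf, term)])
        H, rank = _hat(X)
        df = rank - rank_prev
        if df == 0:
            raise ValueError(
                f"term {':'.join(term)} adds no degrees of freedom "
                "(aliased or single-level)"
            )
        hat_diffs.append(H - H_prev)
        dfs.append(df)
        H_prev, rank_prev = H, rank
    resid_proj = np.eye(n) - H_prev
    df_res = n - rank_prev
    if df_res <= 0:
        raise ValueError("model is saturated; no residual degrees of freedom")

    Hd = np.stack(hat_diffs + [resid_proj])        # (T+1, n, n)
    dfs_arr = np.array(dfs + [df_res], dtype=float)

    def decompose(Gp: np.ndarray) -> np.ndarray:
        return np.einsum("kij,ij->k", Hd, Gp)

    ss = decompose(G)
    ss_total = float(np.trace(G))
    ms = ss / dfs_arr
    f_obs = ms[:-1] / ms[-1]

    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(terms))
    # permutations that tie the observed F in exact arithmetic must count;
    # allow for round-off in the permuted traces
    tol = 1e-8 * np.maximum(np.abs(f_obs), 1.0)
    for _ in range(n_perm):
        p = rng.permutation(n)
        ssp = decompose(G[np.ix_(p, p)])
        msp = ssp / dfs_arr
        exceed += (msp[:-1] / msp[-1]) >= f_obs - tol
    pvals = (exceed + 1.0) / (n_perm + 1.0)

    rows = []
    for i, term in enumerate(terms):
        rows.append(
            {
                "term": ":".join(term),
                "df": int(dfs_arr[i]),
                "sum_sq": ss[i],
                "mean_sq": ms[i],
                "pseudo_f": f_obs[i],
                "r2": ss[i] / ss_total,
                "p_value": pvals[i],
            }
        )
    rows.append(
        {
            "term": "Residual",
            "df": df_res,
            "sum_sq": ss[-1],
            "mean_sq": ms[-1],
            "pseudo_f": np.nan,
            "r2": ss[-1] / ss_total,
            "p_value": np.nan,
        }
    )
    rows.append(
        {
            "term": "Total",
            "df": n - 1,
            "sum_sq": ss_total,
            "mean_sq": np.nan,
            "pseudo_f": np.nan,
            "r2": 1.0,
            "p_value": np.nan,
        }
    )
    return pd.DataFrame(rows).set_index("term")


# ---------------------------------------------------------------------------
# paired Wilcoxon
# ---------------------------------------------------------------------------

def wilcoxon_signed_rank(
    values_a: np.ndarray, values_b: np.ndarray
) -> tuple[float, float]:
    """Paired two-sided Wilcoxon signed-rank test.

    Returns the signed rank statistic ``T+ − T−`` (positive when a > b
    overall; swapping the inputs negates it) and the two-sided p-value
    (exact for n ≤ 25 without ties, normal approximation with tie
    correction otherwise). Zero differences are dropped first.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    d = a - b
    d = d[d != 0]
    if d.size == 0:
        raise ValueError("all paired differences are zero; no test possible")
    if d.size < 5:
        raise ValueError("need at least 5 nonzero paired differences")
    ranks = stats.rankdata(np.abs(d))
    statistic = float(np.sum(np.sign(d) * ranks))
    if d.size <= 25:
        p = _exact_signflip_p(ranks, d)
    else:
        p = float(
            stats.wilcoxon(d, alternative="two-sided", method="approx").pvalue
        )
    return statistic, p


def _exact_signflip_p(ranks: np.ndarray, d: np.ndarray) -> float:
    """Exact two-sided p over all 2^n sign assignments.

    Midranks from ties are half-integers, so doubling makes them integers
    and the distribution of T+ (sum of positive-sign ranks) is built by
    convolution. Two-sided p = 2 * min(P(T+ <= t), P(T+ >= t)), capped
    at 1 — matching the standard exact convention.
    """
    scaled = np.round(ranks * 2).astype(int)
    total = scaled.sum()
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r in scaled:
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[: dist.size - r]
        dist = 0.5 * (dist + shifted)
    t_plus = int(np.round(scaled[d > 0].sum()))
    lower = dist[: t_plus + 1].sum()
    upper = dist[t_plus:].sum()
    return float(min(1.0, 2.0 * min(lower, upper)))
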