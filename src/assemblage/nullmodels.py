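"""Null-model partitioning of community assembly processes.

Two complementary null models are applied to every pair of communities:

* **βNTI** (β-nearest taxon index): the z-score of the observed β-mean
  nearest taxon distance (βMNTD, phylogenetic turnover) against a null
  distribution obtained by randomly shuffling taxa across the tips of the
  phylogeny. βNTI > 2 → variable selection; βNTI < −2 → homogeneous
  selection; |βNTI| < 2 → selection is absent and stochastic processes
  are examined with RC-bray.
* **RC_bray** (abundance-weighted Raup-Crick): the scaled rank, in
  [−1, 1], of the observed Bray-Curtis dissimilarity within a null
  distribution of dissimilarities between randomly assembled community
  pairs that preserve each observed community's richness and total
  abundance. RC_bray > 0.95 → dispersal limitation; RC_bray < −0.95 →
  homogenizing dispersal; |RC_bray| < 0.95 → undominated (drift acting
  with weak selection/dispersal).

Classification boundaries are strict inequalities; values exactly on a
threshold fall to the stochastic/undominated side.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import TreeNode

from .containers import CommunityTable, SampleMetadata, validate_tree
from .phylosignal import cophenetic_matrix

__all__ = [
    "PROCESSES",
    "DegenerateNullError",
    "RegionalPool",
    "bmntd",
    "bnti",
    "BntiResult",
    "raup_crick_bray",
    "RaupCrickResult",
    "classify",
    "regional_pool",
    "assembly_analysis",
    "process_summary",
]

PROCESSES = (
    "variable_selection",
    "homogeneous_selection",
    "dispersal_limitation",
    "homogenizing_dispersal",
    "undominated",
)

_TIE_TOL = 1e-12


class DegenerateNullError(ValueError):
    """The null distribution has zero spread, so a z-score is undefined."""

    def __init__(self, message: str, observed: float):
        super().__init__(message)
        self.observed = observed


# ---------------------------------------------------------------------------
# betaMNTD / betaNTI
# ---------------------------------------------------------------------------

def _community_support(counts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Present-taxon indices and their relative abundances."""
    counts = np.asarray(counts, dtype=float)
    idx = np.flatnonzero(counts > 0)
    if idx.size == 0:
        raise ValueError("community is empty")
    w = counts[idx] / counts[idx].sum()
    return idx, w

def _unweighted_weights(r_a: int, r_b: int) -> tuple[np.ndarray, np.ndarray]:
    """Weights making betaMNTD the pooled mean of all nearest-taxon minima
    (both directions together), the presence-absence convention."""
    w = 2.0 / (r_a + r_b)
    return np.full(r_a, w), np.full(r_b, w)


def _bmntd_from_indices(
    dmat: np.ndarray,
    idx_a: np.ndarray, w_a: np.ndarray,
    idx_b: np.ndarray, w_b: np.ndarray,
) -> float:
    sub = dmat[np.ix_(idx_a, idx_b)]
    dmin_a = sub.min(axis=1)
    dmin_b = sub.min(axis=0)
    return 0.5 * (float(w_a @ dmin_a) + float(w_b @ dmin_b))

def _bmntd_null(
    dmat: np.ndarray,
    idx_a: np.ndarray, w_a: np.ndarray,
    idx_b: np.ndarray, w_b: np.ndarray,
    perms: np.ndarray,
    chunk: int | None = None,
) -> np.ndarray:
    """βMNTD under each tip permutation in ``perms`` (n_null x n_taxa)."""
    if chunk is None:
        # keep the (chunk, rA, rB) gather below ~25M doubles
        chunk = max(1, int(25_000_000 / max(idx_a.size * idx_b.size, 1)))
    out = np.empty(perms.shape[0])
    for start in range(0, perms.shape[0], chunk):
        p = perms[start:start + chunk]
        pa = p[:, idx_a]                      # (c, rA)
        pb = p[:, idx_b]                      # (c, rB)
        sub = dmat[pa[:, :, None], pb[:, None, :]]   # (c, rA, rB)
        out[start:start + chunk] = 0.5 * (
            sub.min(axis=2) @ w_a + sub.min(axis=1) @ w_b
        )
    return out

def _resolve_dmat(
    tree_or_dmat: TreeNode | np.ndarray,
    taxa: list[str],
    comms: tuple[np.ndarray, ...],
) -> tuple[np.ndarray, tuple[np.ndarray, ...]]:
    """Cophenetic matrix and count vectors aligned to it.

    With a tree input the matrix covers *all* tips — the tip-shuffling
    null permutes taxa across the whole tree, not only the observed
    subset — and the community vectors are embedded into tip space.
    """
    if isinstance(tree_or_dmat, TreeNode):
        dm = cophenetic_matrix(tree_or_dmat)
        tip_index = {name: i for i, name in enumerate(dm.ids)}
        missing = set(taxa) - tip_index.keys()
        if missing:
            raise ValueError(f"taxa absent from tree: {sorted(missing)[:10]}")
        cols = np.array([tip_index[t] for t in taxa])
        out = []
        for c in comms:
            v = np.zeros(len(dm.ids))
            v[cols] = c
            out.append(v)
        return dm.data, tuple(out)
    arr = np.asarray(tree_or_dmat, dtype=float)
    if arr.shape != (len(taxa), len(taxa)):
        raise ValueError("distance matrix shape does not match taxa")
    return arr, comms


def bmntd(
    comm_a: np.ndarray,
    comm_b: np.ndarray,
    tree_or_dmat: TreeNode | np.ndarray,
    taxa: list[str] | None = None,
    abundance_weighted: bool = True,
) -> float:
    """β-mean nearest taxon distance between two communities.

    For every taxon present in one community, the patristic distance to
    its closest relative present in the other community is found; βMNTD is
    the (abundance-weighted) mean of those minima, averaged symmetrically
    over both directions. Identical communities score 0.

    ``tree_or_dmat`` is a tree (tips covering ``taxa``) or a precomputed
    cophenetic matrix aligned to ``taxa``; ``taxa`` defaults to positional
    alignment with the matrix.
    """
    comm_a = np.asarray(comm_a, dtype=float)
    comm_b = np.asarray(comm_b, dtype=float)
    if taxa is None:
        if isinstance(tree_or_dmat, TreeNode):
            raise ValueError("taxa labels are required with a tree input")
        taxa = [str(i) for i in range(len(comm_a))]
    dmat, (comm_a, comm_b) = _resolve_dmat(tree_or_dmat, taxa, (comm_a, comm_b))
    idx_a, w_a = _community_support(comm_a)
    idx_b, w_b = _community_support(comm_b)
    if not abundance_weighted:
        w_a, w_b = _unweighted_weights(idx_a.size, idx_b.size)
    return _bmntd_from_indices(dmat, idx_a, w_a, idx_b, w_b)


@dataclass
class BntiResult:
    bnti: float
    bmntd_obs: float
    null_mean: float
    null_sd: float


def bnti(
    comm_a: np.ndarray,
    comm_b: np.ndarray,
    tree_or_dmat: TreeNode | np.ndarray,
    taxa: list[str] | None = None,
    n_null: int = 999,
    seed: int = 0,
    abundance_weighted: bool = True,
) -> BntiResult:
    """β-nearest taxon index for one community pair.

    The null distribution is βMNTD recomputed after each of ``n_null``
    independent random permutations of the taxon labels across the tips
    of the whole tree (taxa keep their abundances but move to random
    phylogenetic positions); βNTI = (observed − null mean) / null sd.
    """
    if n_null < 1:
        raise ValueError("n_null must be >= 1")
    comm_a = np.asarray(comm_a, dtype=float)
    comm_b = np.asarray(comm_b, dtype=float)
    if taxa is None:
        if isinstance(tree_or_dmat, TreeNode):
            raise ValueError("taxa labels are required with a tree input")
        taxa = [str(i) for i in range(len(comm_a))]
    dmat, (comm_a, comm_b) = _resolve_dmat(tree_or_dmat, taxa, (comm_a, comm_b))
    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(dmat.shape[0]) for _ in range(n_null)])
    return _bnti_with_perms(comm_a, comm_b, dmat, perms, abundance_weighted)


def _bnti_with_perms(
    comm_a: np.ndarray,
    comm_b: np.ndarray,
    dmat: np.ndarray,
    perms: np.ndarray,
    abundance_weighted: bool = True,
) -> BntiResult:
    idx_a, w_a = _community_support(comm_a)
    idx_b, w_b = _community_support(comm_b)
    if not abundance_weighted:
        w_a, w_b = _unweighted_weights(idx_a.size, idx_b.size)
    obs = _bmntd_from_indices(dmat, idx_a, w_a, idx_b, w_b)
    null = _bmntd_null(dmat, idx_a, w_a, idx_b, w_b, perms)
    mu = float(null.mean())
    sd = float(null.std(ddof=1))
    if sd == 0.0:
        raise DegenerateNullError(
            "tip shuffling does not change betaMNTD (degenerate null); "
            f"observed value {obs:.6g}", observed=obs,
        )
    return BntiResult((obs - mu) / sd, obs, mu, sd)


# ---------------------------------------------------------------------------
# Raup-Crick (Bray-Curtis variant)
# ---------------------------------------------------------------------------

@dataclass
class RegionalPool:
    """Occupancy and mean relative abundance per taxon, the weights used
    when assembling null communities."""

    occupancy: np.ndarray        # number of samples in which taxon occurs
    mean_abundance: np.ndarray   # mean relative abundance across samples

    def __post_init__(self) -> None:
        self.occupancy = np.asarray(self.occupancy, dtype=float)
        self.mean_abundance = np.asarray(self.mean_abundance, dtype=float)
        if self.occupancy.shape != self.mean_abundance.shape:
            raise ValueError("pool arrays must have equal length")


def regional_pool(table: CommunityTable) -> RegionalPool:
    """Build the regional pool from all samples of a table (one group)."""
    occ = (table.counts > 0).sum(axis=0).astype(float)
    mean_ab = table.relative_abundance().mean(axis=0).to_numpy()
    return RegionalPool(occ, mean_ab)


@dataclass
class RaupCrickResult:
    rc_bray: float
    bc_obs: float


def _bray(a: np.ndarray, b: np.ndarray) -> float:
    denom = (a + b).sum()
    if denom == 0:
        raise ValueError("Bray-Curtis undefined for two empty communities")
    return float(np.abs(a - b).sum() / denom)


def raup_crick_bray(
    comm_a: np.ndarray,
    comm_b: np.ndarray,
    pool: RegionalPool,
    n_null: int = 999,
    seed: int = 0,
) -> RaupCrickResult:
    """Abundance-weighted Raup-Crick deviation of Bray-Curtis dissimilarity.

    Each null replicate assembles a random counterpart for each observed
    community, preserving its richness and total abundance: taxon
    identities are drawn without replacement with probability
    proportional to regional occupancy, each chosen taxon receives one
    individual, and the remaining individuals are assigned by a
    multinomial draw proportional to regional mean relative abundance
    (restricted to the chosen taxa). RC_bray is the scaled rank of the
    observed dissimilarity in the null distribution,
    ``2 * [(#null < obs) + 0.5 * (#null = obs)] / n_null − 1``.
    """
    if n_null < 1:
        raise ValueError("n_null must be >= 1")
    rng = np.random.default_rng(seed)
    comm_a = np.asarray(comm_a, dtype=float)
    comm_b = np.asarray(comm_b, dtype=float)
    if comm_a.shape != comm_b.shape or comm_a.shape != pool.occupancy.shape:
        raise ValueError("communities and pool must share one taxon axis")
    present = (comm_a > 0) | (comm_b > 0)
    if np.any(pool.occupancy[present] <= 0):
        raise ValueError("regional pool does not cover all observed taxa")
    obs = _bray(comm_a, comm_b)
    null = _null_bray_distribution(comm_a, comm_b, pool, n_null, rng)
    below = int((null < obs - _TIE_TOL).sum())
    ties = int((np.abs(null - obs) <= _TIE_TOL).sum())
    rc = 2.0 * (below + 0.5 * ties) / n_null - 1.0
    return RaupCrickResult(rc, obs)


def _null_bray_distribution(
    comm_a: np.ndarray,
    comm_b: np.ndarray,
    pool: RegionalPool,
    n_null: int,
    rng: np.random.Generator,
) -> np.ndarray:
    cand = np.flatnonzero(pool.occupancy > 0)
    occ_w = pool.occupancy[cand]
    ab_w = pool.mean_abundance[cand]
    ab_w = np.where(ab_w > 0, ab_w, np.min(ab_w[ab_w > 0]) * 1e-6) \
        if np.any(ab_w > 0) else np.ones_like(ab_w)
    log_occ = np.log(occ_w)
    S = cand.size
    nulls = []
    for comm in (comm_a, comm_b):
        r = int((comm > 0).sum())
        N = int(comm.sum())
        if r > S:
            raise ValueError("community richness exceeds regional pool size")
        # Gumbel top-k == successive weighted sampling without replacement
        keys = log_occ[None, :] + rng.gumbel(size=(n_null, S))
        chosen = np.argpartition(-keys, r - 1, axis=1)[:, :r]
        counts = np.zeros((n_null, S))
        row_idx = np.repeat(np.arange(n_null), r)
        counts[row_idx, chosen.ravel()] = 1.0
        extra = N - r
        if extra > 0:
            for i in range(n_null):
                p = ab_w[chosen[i]]
                counts[i, chosen[i]] += rng.multinomial(extra, p / p.sum())
        nulls.append(counts)
    na, nb = nulls
    denom = na.sum(axis=1) + nb.sum(axis=1)
    return np.abs(na - nb).sum(axis=1) / denom


# ---------------------------------------------------------------------------
# classification + orchestration
# ---------------------------------------------------------------------------

def classify(bnti_value: float, rc_bray_value: float) -> str:
    """Five-way assembly-process classification of one community pair."""
    if not (math.isfinite(bnti_value) and math.isfinite(rc_bray_value)):
        raise ValueError("classify requires finite betaNTI and RC_bray")
    if bnti_value > 2:
        return "variable_selection"
    if bnti_value < -2:
        return "homogeneous_selection"
    if rc_bray_value > 0.95:
        return "dispersal_limitation"
    if rc_bray_value < -0.95:
        return "homogenizing_dispersal"
    return "undominated"


PAIR_SCOPES = ("all", "within_stage_temporal", "within_timepoint_spatial")


def _pairs_for_scope(
    mf: pd.DataFrame, scope: str
) -> list[tuple[str, str]]:
    pairs = []
    for a, b in itertools.combinations(mf.index, 2):
        if scope == "all":
            pairs.append((a, b))
        elif scope == "within_stage_temporal":
            if (
                mf.loc[a, "stage_year"] == mf.loc[b, "stage_year"]
                and mf.loc[a, "month"] != mf.loc[b, "month"]
            ):
                pairs.append((a, b))
        elif scope == "within_timepoint_spatial":
            if (
                mf.loc[a, "month"] == mf.loc[b, "month"]
                and mf.loc[a, "stage_year"] != mf.loc[b, "stage_year"]
            ):
                pairs.append((a, b))
    return pairs


def assembly_analysis(
    table: CommunityTable,
    tree: TreeNode,
    meta: SampleMetadata | None = None,
    pair_scope: str = "all",
    n_null: int = 999,
    seed: int = 0,
    abundance_weighted: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run βNTI + RC_bray over sample pairs and summarise process fractions.

    Samples are grouped by ``dataset`` (all samples form one group when
    ``meta`` is None); the regional pool and the evaluated pairs are
    defined within each group. ``pair_scope`` selects which pairs are
    evaluated: ``all`` pairs in a group, within-stage cross-month pairs
    (temporal turnover), or within-month cross-stage pairs (spatial
    turnover). Both null models share one seeded generator, and the same
    ``n_null`` tip shuffles are reused for every pair of a run.

    Returns ``(records, summary)``: one row per pair with βMNTD, βNTI,
    Bray-Curtis, RC_bray and the assigned process, and per-group process
    fractions (summing to 1).
    """
    if pair_scope not in PAIR_SCOPES:
        raise ValueError(f"pair_scope must be one of {PAIR_SCOPES}")
    work = table.drop_empty_taxa()
    validate_tree(tree, work.taxon_ids)
    # tip shuffles act on the whole tree, so the cophenetic matrix covers
    # every tip and count vectors are embedded into tip space
    dm = cophenetic_matrix(tree)
    dmat = dm.data
    tip_index = {name: i for i, name in enumerate(dm.ids)}
    cols = np.array([tip_index[t] for t in work.taxon_ids])
    rng = np.random.default_rng(seed)
    n_tips = len(dm.ids)
    perms = np.array([rng.permutation(n_tips) for _ in range(n_null)])

    if meta is not None:
        meta.require_covers(work)
        mf = meta.frame.loc[work.sample_ids]
        groups = {ds: grp.index.tolist() for ds, grp in mf.groupby("dataset")}
    else:
        mf = None
        groups = {"all": work.sample_ids}

    records = []
    for group_name in sorted(groups):
        sample_ids = groups[group_name]
        sub = work.subset_samples(sample_ids)
        pool = regional_pool(sub)
        if mf is not None:
            pairs = _pairs_for_scope(mf.loc[sample_ids], pair_scope)
        else:
            if pair_scope != "all":
                raise ValueError(f"pair_scope {pair_scope!r} requires metadata")
            pairs = list(itertools.combinations(sample_ids, 2))
        counts = {s: sub.sample_counts(s) for s in sample_ids}
        embedded = {}
        for s, c in counts.items():
            v = np.zeros(n_tips)
            v[cols] = c
            embedded[s] = v
        for a, b in pairs:
            try:
                res = _bnti_with_perms(
                    embedded[a], embedded[b], dmat, perms, abundance_weighted
                )
            except DegenerateNullError as exc:
                # e.g. both communities occupy exactly the same taxa: every
                # shuffle leaves betaMNTD unchanged, so there is no
                # phylogenetic deviation to score; the pair falls through
                # to the taxonomic (RC_bray) step
                res = BntiResult(0.0, exc.observed, exc.observed, 0.0)
            rc_seed = int(rng.integers(2**31))
            rc = raup_crick_bray(counts[a], counts[b], pool, n_null, rc_seed)
            records.append(
                {
                    "sample_a": a,
                    "sample_b": b,
                    "group": group_name,
                    "bmntd": res.bmntd_obs,
                    "null_mean": res.null_mean,
                    "null_sd": res.null_sd,
                    "bnti": res.bnti,
                    "bray_curtis": rc.bc_obs,
                    "rc_bray": rc.rc_bray,
                    "process": classify(res.bnti, rc.rc_bray),
                }
            )
    if not records:
        raise ValueError(f"pair scope {pair_scope!r} yields no sample pairs")
    rec_df = pd.DataFrame(records)
    return rec_df, process_summary(rec_df, by=("group",))


def process_summary(
    records: pd.DataFrame, by: tuple[str, ...] = ("group",)
) -> pd.DataFrame:
    """Fraction of pairs assigned to each process, per grouping key."""
    rows = []
    for key, grp in records.groupby(list(by)):
        if not isinstance(key, tuple):
            key = (key,)
        frac = grp["process"].value_counts(normalize=True)
        row = dict(zip(by, key))
        for proc in PROCESSES:
            row[proc] = float(frac.get(proc, 0.0))
        row["n_pairs"] = int(len(grp))
        rows.append(row)
    return pd.DataFrame(rows)
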