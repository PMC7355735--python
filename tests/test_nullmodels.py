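"""βMNTD, βNTI, Raup-Crick and the process classification."""

import itertools

import numpy as np
import pandas as pd
import pytest
from skbio import TreeNode

import assemblage as am
from assemblage.nullmodels import (
    DegenerateNullError,
    RegionalPool,
    raup_crick_bray,
)
from conftest import TEN_TAXA
from test_io import make_table


def bmntd_bruteforce(comm_a, comm_b, dmat, weighted=True):
    """Exhaustive nearest-taxon search, written independently."""
    A = [i for i, c in enumerate(comm_a) if c > 0]
    B = [i for i, c in enumerate(comm_b) if c > 0]
    dmin_a = {i: min(dmat[i][j] for j in B) for i in A}
    dmin_b = {j: min(dmat[i][j] for i in A) for j in B}
    if weighted:
        ta = sum(comm_a[i] for i in A)
        tb = sum(comm_b[j] for j in B)
        return 0.5 * (
            sum(comm_a[i] / ta * dmin_a[i] for i in A)
            + sum(comm_b[j] / tb * dmin_b[j] for j in B)
        )
    return (sum(dmin_a.values()) + sum(dmin_b.values())) / (len(A) + len(B))


class TestBmntd:
    def test_identical_communities_zero(self, ten_tip_tree):
        comm = np.array([0, 3, 1, 0, 2, 0, 0, 4, 0, 1])
        assert am.bmntd(comm, comm, ten_tip_tree, TEN_TAXA) == 0.0

    def test_two_singletons_give_patristic_distance(self, ten_tip_tree):
        dm = am.cophenetic_matrix(ten_tip_tree)
        a = np.zeros(10)
        b = np.zeros(10)
        a[0], b[7] = 5, 9
        expected = dm["t0001", "t0008"]
        assert am.bmntd(a, b, ten_tip_tree, TEN_TAXA) == pytest.approx(expected)

    def test_matches_reference_implementation_value(self, ten_tip_tree):
        # values computed with picante::comdistnt on this exact tree/table
        a = np.array([0, 0, 0, 17, 11, 15, 16, 4, 1, 6])
        b = np.array([5, 17, 18, 0, 9, 16, 2, 0, 0, 0])
        assert am.bmntd(a, b, ten_tip_tree, TEN_TAXA) == pytest.approx(
            0.7101389, abs=1e-7
        )
        assert am.bmntd(
            a, b, ten_tip_tree, TEN_TAXA, abundance_weighted=False
        ) == pytest.approx(0.6043018, abs=1e-7)

    def test_empty_community_rejected(self, ten_tip_tree):
        with pytest.raises(ValueError):
            am.bmntd(np.zeros(10), np.ones(10), ten_tip_tree, TEN_TAXA)


class TestBnti:
    def test_star_tree_degenerate_null(self):
        star = TreeNode.read(["(A:1,B:1,C:1,D:1);"])
        a = np.array([3, 1, 0, 0])
        b = np.array([0, 0, 2, 5])
        with pytest.raises(DegenerateNullError) as exc:
            am.bnti(a, b, star, ["A", "B", "C", "D"], n_null=49, seed=0)
        assert exc.value.observed == pytest.approx(2.0)

    def test_deterministic_under_seed(self, ten_tip_tree):
        a = np.array([0, 3, 1, 0, 2, 0, 0, 4, 0, 1])
        b = np.array([1, 0, 0, 5, 0, 2, 0, 0, 3, 0])
        r1 = am.bnti(a, b, ten_tip_tree, TEN_TAXA, n_null=99, seed=5)
        r2 = am.bnti(a, b, ten_tip_tree, TEN_TAXA, n_null=99, seed=5)
        assert r1 == r2

    def test_null_matches_exhaustive_enumeration_4_tips(self):
        # all 4! tip relabelings enumerated exactly
        tree = am.simulate_tree(4, seed=13)
        taxa = [t.name for t in tree.tips()]
        dm = am.cophenetic_matrix(tree).filter(taxa).data
        a = np.array([5, 1, 0, 0])
        b = np.array([0, 0, 3, 7])
        exact = []
        for perm in itertools.permutations(range(4)):
            p = np.array(perm)
            ap, bp = np.zeros(4), np.zeros(4)
            ap[p] = a  # taxon i moves to tip p[i], keeping its abundance
            bp[p] = b
            exact.append(bmntd_bruteforce(ap, bp, dm, True))
        exact = np.array(exact)
        res = am.bnti(a, b, dm, taxa, n_null=999, seed=3)
        se_mean = exact.std(ddof=1) / np.sqrt(999)
        se_sd = exact.std(ddof=1) / np.sqrt(2 * 999)
        assert abs(res.null_mean - exact.mean()) <= 3 * se_mean
        assert abs(res.null_sd - exact.std(ddof=1)) <= 3 * se_sd


class TestRaupCrick:
    def test_identical_communities_bottom_rank(self):
        comm = np.array([40, 40, 20, 0, 0, 0])
        pool = RegionalPool(
            occupancy=np.array([3, 3, 2, 2, 1, 1], dtype=float),
            mean_abundance=np.array([0.3, 0.3, 0.1, 0.1, 0.1, 0.1]),
        )
        res = raup_crick_bray(comm, comm, pool, n_null=199, seed=1)
        assert res.bc_obs == 0.0
        assert res.rc_bray == -1.0

    def test_disjoint_pair_with_dominant_pool_top_rank(self):
        # occupancy mass concentrated on two taxa the pair does not use:
        # every null pair shares those dominants, so null BC < 1 = obs
        a = np.array([0, 0, 30, 10, 0, 0])
        b = np.array([0, 0, 0, 0, 25, 15])
        pool = RegionalPool(
            occupancy=np.array([1e9, 1e9, 1, 1, 1, 1]),
            mean_abundance=np.array([0.45, 0.45, 0.025, 0.025, 0.025, 0.025]),
        )
        res = raup_crick_bray(a, b, pool, n_null=199, seed=2)
        assert res.bc_obs == 1.0
        assert res.rc_bray == 1.0

    def test_pool_must_cover_observed_taxa(self):
        a = np.array([1, 1, 0])
        b = np.array([0, 1, 1])
        pool = RegionalPool(np.array([1.0, 1.0, 0.0]), np.array([0.5, 0.5, 0.0]))
        with pytest.raises(ValueError):
            raup_crick_bray(a, b, pool, n_null=9, seed=0)

    def test_bounds_and_determinism(self):
        rng = np.random.default_rng(8)
        for _ in range(10):
            counts = rng.integers(0, 12, size=(2, 8))
            counts[:, 0] += 1
            occ = (counts > 0).sum(axis=0) + rng.integers(0, 3, 8)
            pool = RegionalPool(
                occ.astype(float) + 0.5, rng.dirichlet(np.ones(8))
            )
            r1 = raup_crick_bray(counts[0], counts[1], pool, n_null=99, seed=4)
            r2 = raup_crick_bray(counts[0], counts[1], pool, n_null=99, seed=4)
            assert r1 == r2
            assert -1.0 <= r1.rc_bray <= 1.0


class TestClassify:
    @pytest.mark.parametrize(
        "bnti_value,rc,expected",
        [
            (2.5, 0.0, "variable_selection"),
            (2.5, -0.99, "variable_selection"),
            (-2.5, 0.0, "homogeneous_selection"),
            (-2.5, 0.99, "homogeneous_selection"),
            (0.5, 0.97, "dispersal_limitation"),
            (0.5, -0.97, "homogenizing_dispersal"),
            (0.5, 0.0, "undominated"),
        ],
    )
    def test_rule_table(self, bnti_value, rc, expected):
        assert am.classify(bnti_value, rc) == expected

    def test_boundaries_fall_to_weaker_claim(self):
        assert am.classify(2.0, 0.0) == "undominated"
        assert am.classify(-2.0, 0.96) == "dispersal_limitation"
        assert am.classify(0.0, 0.95) == "undominated"
        assert am.classify(0.0, -0.95) == "undominated"

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            am.classify(np.nan, 0.0)
        with pytest.raises(ValueError):
            am.classify(0.0, np.inf)


class TestAssemblyAnalysis:
    def test_pair_count_all_scope(self, ten_tip_tree):
        rng = np.random.default_rng(2)
        counts = rng.integers(1, 20, (8, 10)) * (rng.random((8, 10)) < 0.5)
        counts[np.arange(8), rng.integers(0, 10, 8)] += 1  # no empty sample
        table = make_table(counts, taxa=TEN_TAXA)
        records, summary = am.assembly_analysis(
            table, ten_tip_tree, None, "all", n_null=49, seed=0
        )
        assert len(records) == 8 * 7 // 2
        assert summary.n_pairs.sum() == len(records)

    def test_summary_fractions_sum_to_one(self, ten_tip_tree, small_table,
                                          design_metadata):
        records, summary = am.assembly_analysis(
            small_table, ten_tip_tree, design_metadata,
            "within_stage_temporal", n_null=49, seed=1,
        )
        frac_cols = list(am.nullmodels.PROCESSES)
        np.testing.assert_allclose(
            summary[frac_cols].sum(axis=1), 1.0, atol=1e-12
        )
        # scope semantics: same dataset, same stage, different month
        mf = design_metadata.frame
        for rec in records.itertuples():
            assert mf.loc[rec.sample_a, "dataset"] == mf.loc[rec.sample_b, "dataset"]
            assert mf.loc[rec.sample_a, "month"] != mf.loc[rec.sample_b, "month"]

    def test_empty_scope_errors(self, ten_tip_tree, small_table):
        meta = am.SampleMetadata(
            pd.DataFrame(
                {
                    "dataset": ["DNA"] * 6,
                    "stage_year": [0, 0, 10, 10, 40, 40],
                    "month": ["May"] * 6,
                    "replicate": [1, 2] * 3,
                },
                index=small_table.sample_ids,
            )
        )
        with pytest.raises(ValueError, match="no sample pairs"):
            am.assembly_analysis(
                small_table, ten_tip_tree, meta,
                "within_stage_temporal", n_null=9, seed=0,
            )

    def test_records_satisfy_zscore_identity(self, ten_tip_tree, small_table):
        records, _ = am.assembly_analysis(
            small_table, ten_tip_tree, None, "all", n_null=99, seed=7
        )
        z = (records.bmntd - records.null_mean) / records.null_sd
        np.testing.assert_allclose(records.bnti, z, atol=1e-12)
        assert records.rc_bray.between(-1, 1).all()
        for rec in records.itertuples():
            assert am.classify(rec.bnti, rec.rc_bray) == rec.process
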