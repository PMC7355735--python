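"""Synthetic-data generator: trees, traits, assembly, full designs."""

import numpy as np
import pytest

import assemblage as am
from assemblage.simulate import SimulationConfig


class TestSimulateTree:
    def test_two_taxa_is_a_cherry(self):
        tree = am.simulate_tree(2, seed=0)
        assert tree.count(tips=True) == 2
        assert all(c.is_tip() for c in tree.children)

    def test_determinism_and_seed_sensitivity(self):
        a = str(am.simulate_tree(64, seed=7))
        b = str(am.simulate_tree(64, seed=7))
        c = str(am.simulate_tree(64, seed=8))
        assert a == b
        assert a != c

    def test_tip_count_and_positive_lengths(self):
        for n in (2, 5, 33):
            tree = am.simulate_tree(n, seed=n)
            assert tree.count(tips=True) == n
            assert all(
                node.length > 0 for node in tree.traverse(include_self=False)
            )

    def test_depth_grows_with_taxa(self):
        # mean number of internal nodes on a root-to-tip path increases
        def mean_depth(n, seed):
            tree = am.simulate_tree(n, seed)
            depths = []
            for tip in tree.tips():
                d, node = 0, tip
                while node.parent is not None:
                    d += 1
                    node = node.parent
                depths.append(d)
            return np.mean(depths)

        small = np.mean([mean_depth(8, s) for s in range(100)])
        large = np.mean([mean_depth(64, s) for s in range(100)])
        assert large > small

    def test_too_few_taxa(self):
        with pytest.raises(ValueError):
            am.simulate_tree(1, seed=0)


class TestEvolveTrait:
    def test_zero_rate_keeps_root_value(self):
        tree = am.simulate_tree(10, seed=1)
        traits = am.evolve_trait(tree, 0.0, root_value=3.5, seed=2)
        assert np.allclose(traits.to_numpy(), 3.5)

    def test_negative_rate_rejected(self):
        tree = am.simulate_tree(4, seed=1)
        with pytest.raises(ValueError):
            am.evolve_trait(tree, -1.0)

    def test_tip_variance_matches_brownian_expectation(self):
        # ultrametric height-1 tree: Var[tip] = sigma2 * height
        tree = am.simulate_tree(8, seed=3)
        sigma2 = 2.0
        vals = np.array(
            [
                am.evolve_trait(tree, sigma2, seed=s).to_numpy()
                for s in range(2000)
            ]
        )
        per_tip_var = vals.var(axis=0, ddof=1)
        assert np.allclose(per_tip_var.mean(), sigma2, rtol=0.05)

    def test_close_relatives_are_more_similar(self):
        tree = am.simulate_tree(16, seed=4)
        dm = am.cophenetic_matrix(tree)
        ids = list(dm.ids)
        d = dm.data
        iu = np.triu_indices(len(ids), k=1)
        close = d[iu] < np.median(d[iu])
        sq_diffs = []
        for s in range(200):
            tr = am.evolve_trait(tree, 1.0, seed=1000 + s)
            v = tr[ids].to_numpy()
            sq_diffs.append((v[iu[0]] - v[iu[1]]) ** 2)
        msd = np.mean(sq_diffs, axis=0)
        assert msd[close].mean() < msd[~close].mean()


class TestAssembleCommunity:
    def setup_method(self):
        self.pool = np.array([0.5, 0.3, 0.15, 0.05])
        self.traits = np.array([0.0, 1.0, 2.0, 3.0])

    def test_argmin_limit(self):
        counts = am.assemble_community(
            self.pool, self.traits, env=1.9, selection_sd=0.0,
            migration_rate=1.0, community_size=50, rng=0,
        )
        assert counts.tolist() == [0, 0, 50, 0]

    def test_pure_mass_effect_matches_pool(self):
        acc = np.zeros(4)
        reps = 400
        for s in range(reps):
            acc += am.assemble_community(
                self.pool, self.traits, env=0.0, selection_sd=None,
                migration_rate=1.0, community_size=100, rng=s,
            )
        freq = acc / acc.sum()
        se = np.sqrt(self.pool * (1 - self.pool) / (100 * reps))
        assert np.all(np.abs(freq - self.pool) <= 4 * se)

    def test_deterministic_under_seed(self):
        kw = dict(
            pool=self.pool, traits=self.traits, env=1.0, selection_sd=0.7,
            migration_rate=0.5, community_size=200,
        )
        a = am.assemble_community(rng=42, **kw)
        b = am.assemble_community(rng=42, **kw)
        assert (a == b).all()

    def test_bad_parameters(self):
        with pytest.raises(ValueError):
            am.assemble_community(
                self.pool, self.traits, 0.0, selection_sd=-0.5,
                migration_rate=1.0, community_size=10, rng=0,
            )
        with pytest.raises(ValueError):
            am.assemble_community(
                self.pool * 2, self.traits, 0.0, selection_sd=None,
                migration_rate=1.0, community_size=10, rng=0,
            )


class TestChronosequence:
    def test_design_arithmetic(self):
        cfg = SimulationConfig(n_taxa=100, community_size=300, seed=1)
        table, meta, tree, truth = am.generate_chronosequence(cfg)
        # 5 stages x 4 months x 3 replicates x 2 fractions
        assert table.n_samples == 120
        assert (table.counts.sum(axis=1) == 300).all()
        assert meta.frame["dataset"].value_counts().to_dict() == {
            "DNA": 60, "RNA": 60,
        }
        assert tree.count(tips=True) == 100
        assert set(truth.latent_env.index) == set(table.sample_ids)

    def test_bit_reproducible(self):
        cfg = SimulationConfig(n_taxa=80, community_size=200, seed=9)
        t1, m1, tr1, _ = am.generate_chronosequence(cfg)
        t2, m2, tr2, _ = am.generate_chronosequence(cfg)
        assert t1 == t2
        assert m1.frame.equals(m2.frame)
        assert str(tr1) == str(tr2)

    def test_degenerate_generator_pairs_dna_rna(self):
        # no relic carryover, no month noise: the DNA sample is a plain
        # multinomial resample of its paired RNA community
        cfg = SimulationConfig(
            n_taxa=150, community_size=2000, relic_carryover=0.0,
            env_month_noise_sd=0.0, seed=4,
        )
        table, meta, _, _ = am.generate_chronosequence(cfg)
        rel = table.relative_abundance()
        diffs = []
        for sid in meta.frame.index[meta.frame.dataset == "RNA"]:
            partner = sid.replace("RNA", "DNA")
            diffs.append(
                0.5 * np.abs(rel.loc[sid] - rel.loc[partner]).sum()
            )
        cross = 0.5 * np.abs(
            rel.iloc[0] - rel.loc[meta.frame.index[40]]
        ).sum()
        assert np.mean(diffs) < 0.2
        assert np.mean(diffs) < cross

    def test_environment_gradient_is_monotone(self):
        cfg = SimulationConfig(n_taxa=60, community_size=100, seed=2,
                               env_month_noise_sd=0.0)
        _, meta, _, truth = am.generate_chronosequence(cfg)
        by_stage = truth.latent_env.groupby(
            meta.frame["stage_year"]
        ).mean()
        assert by_stage.is_monotonic_increasing


class TestRegimes:
    @pytest.mark.parametrize(
        "regime",
        [
            "variable_selection",
            "homogeneous_selection",
            "dispersal_limitation",
            "homogenizing_dispersal",
            "drift",
        ],
    )
    def test_regime_smoke_and_counts(self, regime):
        cfg = SimulationConfig(
            n_taxa=100, community_size=400, regime=regime,
            n_communities=5, seed=3,
        )
        table, meta, tree, truth = am.generate_regime(cfg)
        assert table.n_samples == 5
        assert (table.counts.sum(axis=1) == 400).all()
        assert truth.regime == regime
        assert truth.pair_regime("C001", "C002") == regime

    def test_homogeneous_bmntd_below_variable(self):
        # selection toward one shared optimum clusters communities more
        # tightly on the tree than selection toward spread-out optima
        means = {"homogeneous_selection": [], "variable_selection": []}
        for seed in range(20):
            for regime in means:
                cfg = SimulationConfig(
                    n_taxa=400, community_size=600, regime=regime,
                    n_communities=4, seed=seed,
                )
                table, _, tree, _ = am.generate_regime(cfg)
                dm = am.cophenetic_matrix(tree)
                taxa = table.taxon_ids
                d = dm.filter(taxa).data
                vals = []
                counts = table.counts
                for i in range(4):
                    for j in range(i + 1, 4):
                        vals.append(am.bmntd(counts[i], counts[j], d, taxa))
                means[regime].append(np.mean(vals))
        assert (
            np.mean(means["homogeneous_selection"])
            < np.mean(means["variable_selection"])
        )

    def test_config_validation(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_taxa=2)
        with pytest.raises(ValueError):
            SimulationConfig(relic_carryover=1.0)
        with pytest.raises(ValueError):
            SimulationConfig(regime="mass_effects")

    def test_yaml_round_trip(self, tmp_path):
        cfg = SimulationConfig(n_taxa=50, seed=17, regime="drift")
        path = tmp_path / "config.yaml"
        cfg.to_yaml(path)
        assert SimulationConfig.from_yaml(path) == cfg
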