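"""The generative model: trees, traits, sizes, diets, regions, experts."""

import numpy as np
import pandas as pd
import pytest

from trophoguild import core_data
from trophoguild import synthetic_data as sd
from trophoguild._phylo import PhyloArrays
from trophoguild.phylo_signal import compute_delta


class TestTree:
    def test_tip_count_and_labels(self):
        tree = sd.simulate_tree(50, seed=1)
        labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
        assert len(labels) == 50 and len(set(labels)) == 50

    def test_ultrametric_unit_depth(self):
        arr = PhyloArrays.from_dendropy(sd.simulate_tree(40, seed=2))
        depths = arr.depths[: arr.n_tips]
        assert depths.max() == pytest.approx(1.0, abs=1e-6)
        assert depths.max() - depths.min() < 1e-6

    def test_deterministic_per_seed(self):
        t1 = sd.simulate_tree(20, seed=9).as_string(schema="newick")
        t2 = sd.simulate_tree(20, seed=9).as_string(schema="newick")
        assert t1 == t2

    def test_too_few_species_rejected(self):
        with pytest.raises(ValueError):
            sd.simulate_tree(2)


class TestGuilds:
    def test_zero_rate_keeps_root_state(self):
        tree = sd.simulate_tree(30, seed=3)
        trait = sd.simulate_guilds(tree, 4, 0.0, seed=1, min_states=1)
        assert len(set(trait.states.values())) == 1

    def test_expected_change_count_matches_poisson_rate(self):
        # E[#changes] = rate x total branch length for the jump process
        tree = sd.simulate_tree(40, seed=4)
        arr = PhyloArrays.from_dendropy(tree)
        total_len = arr.blen.sum()
        rate = 0.2
        k = 26  # many states: changes ~ distinct states - 1, few reversals
        n_states = []
        for rep in range(60):
            tr = sd.simulate_guilds(tree, k, rate, seed=rep, min_states=1)
            n_states.append(len(set(tr.states.values())) - 1)
        expected = rate * total_len
        sem = np.sqrt(expected / 60)
        assert np.mean(n_states) == pytest.approx(expected, abs=4 * sem)

    def test_high_rate_approaches_uniform_states(self):
        tree = sd.simulate_tree(60, seed=5)
        tr = sd.simulate_guilds(tree, 3, 100.0, seed=2)
        counts = pd.Series(list(tr.states.values())).value_counts()
        assert counts.max() / counts.sum() < 0.6

    def test_min_count_conditioning(self):
        tree = sd.simulate_tree(64, seed=6)
        tr = sd.simulate_guilds(tree, 4, 0.4, seed=3, min_states=4,
                                min_count=4)
        counts = pd.Series(list(tr.states.values())).value_counts()
        assert len(counts) == 4 and counts.min() >= 4

    def test_clade_guilds_cover_all_k(self):
        tree = sd.simulate_tree(32, seed=7)
        tr = sd.simulate_clade_guilds(tree, 8)
        assert len(set(tr.states.values())) == 8


class TestSizes:
    def test_zero_sd_gives_exact_guild_means(self):
        tree = sd.simulate_tree(20, seed=8)
        tr = sd.simulate_clade_guilds(tree, 2)
        means = np.log([10.0, 40.0])
        attrs = sd.simulate_sizes(tree, tr, means, bm_sd=0.0, seed=1)
        for sp, g in tr.states.items():
            assert attrs.at[sp, "max_size_cm"] == pytest.approx(
                np.exp(means[g - 1]))

    def test_within_guild_log_mean_converges(self):
        tree = sd.simulate_tree(300, seed=9)
        tr = sd.simulate_clade_guilds(tree, 2)
        means = np.log([10.0, 40.0])
        attrs = sd.simulate_sizes(tree, tr, means, bm_sd=0.3, seed=2)
        for g in (1, 2):
            sp = [s for s, v in tr.states.items() if v == g]
            got = np.log(attrs.loc[sp, "max_size_cm"]).mean()
            assert got == pytest.approx(means[g - 1], abs=0.35)

    def test_sizes_positive(self):
        tree = sd.simulate_tree(25, seed=10)
        tr = sd.simulate_clade_guilds(tree, 3)
        attrs = sd.simulate_sizes(tree, tr, np.log([5, 20, 80]), bm_sd=1.0,
                                  seed=3)
        assert (attrs["max_size_cm"] > 0).all()


class TestDiets:
    def test_individual_proportions_sum_to_one(self):
        tree = sd.simulate_tree(10, seed=11)
        tr = sd.simulate_clade_guilds(tree, 2)
        rec = sd.simulate_diets(tr, sd.default_guild_profiles(2),
                                guts_per_species=(3, 5), seed=4)
        sums = rec.groupby("individual_id")["value"].sum()
        assert np.abs(sums - 1.0).max() < 1e-9

    def test_profiles_concentrate_at_high_concentration(self):
        tree = sd.simulate_tree(60, seed=12)
        tr = sd.simulate_clade_guilds(tree, 2)
        profiles = sd.default_guild_profiles(2)
        rec = sd.simulate_diets(tr, profiles, concentration_species=1e6,
                                concentration_individual=1e6,
                                guts_per_species=(2, 2), seed=5,
                                )
        diet = core_data.build_diet_matrix(rec)
        for g in (1, 2):
            sp = [s for s, v in tr.states.items() if v == g]
            got = diet.matrix.loc[sp].mean(axis=0)
            # truncation of <1% trace items redistributes a little mass
            big = profiles.loc[g] > 0.03
            assert np.abs(got[big.values] - profiles.loc[g][big.values]).max() < 0.02

    def test_guild_profiles_must_sum_to_one(self):
        tree = sd.simulate_tree(10, seed=13)
        tr = sd.simulate_clade_guilds(tree, 2)
        bad = sd.default_guild_profiles(2) * 2.0
        with pytest.raises(ValueError):
            sd.simulate_diets(tr, bad)


class TestRegions:
    def test_full_sharing_puts_every_species_everywhere(self):
        tree = sd.simulate_tree(12, seed=14)
        tr = sd.simulate_clade_guilds(tree, 2)
        rec = sd.simulate_regions(tr, sd.default_guild_profiles(2),
                                  n_regions=3, share_fraction=1.0,
                                  guts_per_species=(2, 3), seed=6)
        per_sp = rec.groupby("species")["location"].nunique()
        assert (per_sp == 3).all()

    def test_region_partition_covers_all_species(self):
        tree = sd.simulate_tree(20, seed=15)
        tr = sd.simulate_clade_guilds(tree, 2)
        rec = sd.simulate_regions(tr, sd.default_guild_profiles(2),
                                  n_regions=4, share_fraction=0.2,
                                  guts_per_species=(2, 3), seed=7)
        assert set(rec["species"]) == set(tr.states)

    def test_single_region_rejected(self):
        tree = sd.simulate_tree(10, seed=16)
        tr = sd.simulate_clade_guilds(tree, 2)
        with pytest.raises(ValueError):
            sd.simulate_regions(tr, sd.default_guild_profiles(2), n_regions=1)


class TestExperts:
    def test_zero_error_gives_identical_schemes(self):
        truth = {f"sp{i}": "invertivores" if i % 2 else "piscivores"
                 for i in range(30)}
        schemes = sd.simulate_expert_schemes(truth, 4, 0.0, seed=8)
        assert all(s.labels == truth for s in schemes)

    def test_deterministic_per_seed(self):
        truth = {f"sp{i}": "invertivores" if i % 2 else "piscivores"
                 for i in range(30)}
        a = sd.simulate_expert_schemes(truth, 3, 0.3, seed=9)
        b = sd.simulate_expert_schemes(truth, 3, 0.3, seed=9)
        assert all(x.labels == y.labels for x, y in zip(a, b))

    def test_invalid_epsilon_rejected(self):
        with pytest.raises(ValueError):
            sd.simulate_expert_schemes({"a": "x"}, 2, 1.5)


class TestDatasetAndKnobs:
    def test_bit_identical_reproduction(self):
        cfg = sd.SimulationConfig(n_species=25, n_guilds=3, n_regions=2,
                                  guts_min=2, guts_max=4, n_experts=3, seed=77)
        d1 = sd.simulate_dataset(cfg)
        d2 = sd.simulate_dataset(cfg)
        pd.testing.assert_frame_equal(d1.records, d2.records)
        assert d1.trait.states == d2.trait.states
        pd.testing.assert_frame_equal(d1.attrs, d2.attrs)
        assert d1.tree.as_string(schema="newick") == \
            d2.tree.as_string(schema="newick")

    def test_conservatism_knob_drives_loo_accuracy_and_auc(self):
        """Lower Mk rate -> higher guild predictability end to end.

        Guild size means are equal here so phylogeny is the only route
        to the guild label; the knob must act through the tree.
        """
        from trophoguild import guild_phylo_model as gpm
        from trophoguild import interaction_predictor as ip

        tree = sd.simulate_tree(32, seed=55)
        accs, aucs = [], []
        for rate in (0.2, 1.5, 8.0):
            trait = sd.simulate_guilds(tree, 3, rate, seed=56, min_states=3,
                                       min_count=3, max_tries=2000)
            attrs = sd.simulate_sizes(tree, trait, np.log([20, 20, 20]),
                                      bm_sd=0.4, seed=57)
            res = gpm.loo_cv(trait, attrs, tree, chains=1, iterations=250,
                             warmup=100, n_draws=80, seed=58, leapfrog=8)
            accs.append(res["accuracy"])
            rec = sd.simulate_diets(trait, sd.default_guild_profiles(3),
                                    concentration_species=150,
                                    concentration_individual=60,
                                    guts_per_species=(6, 8), seed=59)
            diet = core_data.build_diet_matrix(rec)
            pem = ip.phylo_eigenvectors(tree)
            table = ip.build_interaction_table(diet, presence_threshold=0.01)
            X = ip.assemble_features(table, pem, attrs)
            y = table["label"].to_numpy()
            m = ip.fit_ensemble(X, y, folds=5, n_trees=60, seed=60)
            aucs.append(ip.rank_auc(y, m.oof["stacked"].to_numpy()))
        assert accs[0] > accs[1] > accs[2]
        assert aucs[0] > aucs[1] > aucs[2]

    def test_lower_rate_gives_higher_delta(self, yule64):
        deltas = []
        for rate in (0.2, 1.0, 8.0):
            vals = [compute_delta(yule64,
                                  sd.simulate_guilds(yule64, 4, rate,
                                                     seed=100 + rep,
                                                     min_states=2,
                                                     min_count=4))
                    for rep in range(8)]
            deltas.append(np.median(vals))
        assert deltas[0] > deltas[1] > deltas[2]
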