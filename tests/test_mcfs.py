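import numpy as np
import pytest
from scipy.stats import mannwhitneyu

import atlasrules as ar
from atlasrules.mcfs import MCFSParams, TreeAccount, ri_contribution, run_mcfs


class TestRiContribution:
    def test_feature_absent_from_splits_is_zero(self):
        acc = TreeAccount(wacc=0.9, nodes=[(1, 0.4, 8)], n_tree=10)
        assert ri_contribution(acc, feature=7, params=MCFSParams()) == 0.0

    def test_single_root_split(self):
        acc = TreeAccount(wacc=0.8, nodes=[(3, 0.5, 10)], n_tree=10)
        assert ri_contribution(acc, 3, MCFSParams()) == pytest.approx(0.4)

    def test_node_fraction_exponent(self):
        acc = TreeAccount(wacc=0.8, nodes=[(3, 0.5, 5)], n_tree=10)
        assert ri_contribution(acc, 3, MCFSParams(v=2)) == pytest.approx(0.1)

    def test_wacc_exponent(self):
        acc = TreeAccount(wacc=0.5, nodes=[(0, 1.0, 10)], n_tree=10)
        assert ri_contribution(acc, 0, MCFSParams(u=2)) == pytest.approx(0.25)

    def test_multiple_nodes_sum(self):
        acc = TreeAccount(wacc=1.0, nodes=[(2, 0.5, 10), (2, 0.25, 4),
                                           (5, 0.9, 6)], n_tree=10)
        expected = 0.5 * 1.0 + 0.25 * 0.4
        assert ri_contribution(acc, 2, MCFSParams()) == pytest.approx(expected)

    def test_inconsistent_account_rejected(self):
        with pytest.raises(ValueError):
            TreeAccount(wacc=0.5, nodes=[(0, 0.1, 20)], n_tree=10)
        with pytest.raises(ValueError):
            TreeAccount(wacc=1.5, nodes=[], n_tree=10)


class TestRunMcfs:
    def test_single_tree_ri_replays_the_account(self, small_synth):
        """m=1, t=1, s=all: the reported RI of every gene equals the
        hand-walked sum over that one tree's recorded nodes."""
        ds, _ = small_synth
        params = MCFSParams(m=1, t=1, s=ds.n_genes, seed=0)
        ranked, accounts = run_mcfs(ds, params=params, return_accounts=True)
        assert len(accounts) == 1
        ri_by_gene = dict(zip(ranked.indices, ranked.scores))
        for f in range(ds.n_genes):
            expected = ri_contribution(accounts[0], f, params)
            assert ri_by_gene[f] == pytest.approx(expected)

    def test_never_drawn_feature_has_zero_ri_and_ranks_last(self, small_synth):
        ds, _ = small_synth
        params = MCFSParams(m=2, t=2, s=3, seed=1)
        ranked, accounts = run_mcfs(ds, features=np.arange(20),
                                    params=params, return_accounts=True)
        drawn = {f for acc in accounts for f, _, _ in acc.nodes}
        subset_union = set()
        for acc in accounts:
            subset_union |= drawn
        undrawn = [f for f, s in zip(ranked.indices, ranked.scores) if s == 0]
        assert len(undrawn) >= 1          # t=2 subsets of 3 from 20 genes
        # all zero-RI features rank after every positive-RI feature
        scores = ranked.scores
        first_zero = np.argmax(scores == 0)
        assert np.all(scores[first_zero:] == 0)

    def test_ri_conservation_against_accounts(self, small_synth):
        """sum_f RI_f == sum over trees of wAcc^u * sum IG * fraction^v."""
        ds, _ = small_synth
        params = MCFSParams(m=3, t=4, s=5, seed=2, u=1.0, v=1.0)
        ranked, accounts = run_mcfs(ds, features=np.arange(30),
                                    params=params, return_accounts=True)
        total_from_accounts = sum(
            (acc.wacc ** params.u) * sum(
                ig * ((n_node / acc.n_tree) ** params.v)
                for _, ig, n_node in acc.nodes
            )
            for acc in accounts
        )
        assert ranked.scores.sum() == pytest.approx(total_from_accounts)

    def test_reproducible_from_seed(self, small_synth):
        ds, _ = small_synth
        params = MCFSParams(m=3, t=3, s=4, seed=9)
        r1 = run_mcfs(ds, features=np.arange(25), params=params)
        r2 = run_mcfs(ds, features=np.arange(25), params=params)
        assert list(r1.indices) == list(r2.indices)
        assert np.array_equal(r1.scores, r2.scores)

    def test_subset_larger_than_candidates_rejected(self, small_synth):
        ds, _ = small_synth
        with pytest.raises(ValueError, match="exceeds"):
            run_mcfs(ds, features=np.arange(5), params=MCFSParams(s=10))

    def test_marker_recovery_on_five_class_atlas(self):
        """Planted markers dominate the RI ranking.  With t=30 shared
        subsets of s=10 from 120 candidates each gene misses every subset
        with probability (1 - 10/120)^30 ~ 0.075, so a couple of markers
        are structurally invisible; the drawn markers concentrate at the
        top (frozen to the deterministic outcome at this seed)."""
        spec = ar.SyntheticSpec(n_classes=5, class_sizes=(80,) * 5,
                                markers_per_class=4, n_noise_genes=100,
                                effect_size=2.0, seed=2)
        ds, truth = ar.generate_dataset(spec)
        ranked = run_mcfs(ds, params=MCFSParams(m=20, t=30, s=10, seed=2))
        top40 = set(ranked.gene_ids[:40])
        markers = set(truth.marker_ids)
        assert len(top40 & markers) >= 14
        # and markers rank far above noise genes overall
        rank_of = {g: i for i, g in enumerate(ranked.gene_ids)}
        marker_ranks = [rank_of[g] for g in markers]
        noise_ranks = [rank_of[g] for g in ranked.gene_ids if g not in markers]
        stat = mannwhitneyu(marker_ranks, noise_ranks, alternative="less")
        assert stat.pvalue < 0.01

    def test_null_labels_give_markers_no_advantage(self):
        """With permuted labels, former markers rank uniformly."""
        spec = ar.SyntheticSpec(n_classes=3, class_sizes=(60,) * 3,
                                markers_per_class=3, n_noise_genes=40,
                                effect_size=2.0, seed=6)
        ds, truth = ar.generate_dataset(spec)
        rng = np.random.default_rng(6)
        shuffled = [ds.labels[i] for i in rng.permutation(ds.n_cells)]
        ds_null = ar.ExpressionDataset(ds.matrix, ds.gene_ids, ds.cell_ids,
                                       shuffled, ds.class_names)
        ranked = run_mcfs(ds_null, params=MCFSParams(m=10, t=20, s=7, seed=6))
        rank_of = {g: i for i, g in enumerate(ranked.gene_ids)}
        marker_ranks = [rank_of[g] for g in truth.marker_ids]
        noise_ranks = [rank_of[g] for g in ranked.gene_ids
                       if g not in set(truth.marker_ids)]
        stat = mannwhitneyu(marker_ranks, noise_ranks, alternative="two-sided")
        assert stat.pvalue > 0.01
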