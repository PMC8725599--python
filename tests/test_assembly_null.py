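import numpy as np
import pytest

from ecoassembly.assembly_null import (
    PROCESSES,
    beta_mntd,
    bnti,
    classify_pair,
    niche_optima,
    partition_processes,
    phylo_signal,
    rc_bray,
)
from ecoassembly.core_data import (
    CommunityTable,
    ValidationError,
    pairwise_from_condensed,
    tree_from_newick,
)
from ecoassembly.synthetic_data import ScenarioConfig, simulate_scenario, simulate_tree


def brute_force_beta_mntd(counts: np.ndarray, D: np.ndarray, weighted: bool = True):
    """Exhaustive nearest-taxon oracle: loops over all taxon pairs."""
    n_taxa, n_samples = counts.shape
    if weighted:
        F = counts / counts.sum(axis=0)
    else:
        present = (counts > 0).astype(float)
        F = present / present.sum(axis=0)
    out = np.zeros((n_samples, n_samples))
    for j in range(n_samples):
        for k in range(n_samples):
            if j == k:
                continue
            acc = 0.0
            for i in range(n_taxa):
                if counts[i, j] > 0:
                    acc += F[i, j] * min(
                        D[i, ip] for ip in range(n_taxa) if counts[ip, k] > 0
                    )
            for i in range(n_taxa):
                if counts[i, k] > 0:
                    acc += F[i, k] * min(
                        D[i, ip] for ip in range(n_taxa) if counts[ip, j] > 0
                    )
            out[j, k] = 0.5 * acc
    return out


def random_instance(seed, max_taxa=8, max_samples=5):
    rng = np.random.default_rng(seed)
    n_taxa = int(rng.integers(3, max_taxa + 1))
    n_samples = int(rng.integers(2, max_samples + 1))
    tree = simulate_tree(n_taxa, birth_rate=1.0, seed=seed)
    while True:
        counts = rng.integers(0, 20, size=(n_taxa, n_samples))
        if (counts.sum(axis=0) > 0).all() and (counts.sum(axis=1) > 0).all():
            break
    table = CommunityTable(list(tree.tip_names), [f"s{j}" for j in range(n_samples)], counts)
    return table, tree


class TestBetaMNTD:
    def test_identical_communities(self, tiny_tree):
        t = CommunityTable(
            ["OTU_A", "OTU_B", "OTU_C"], ["s1", "s2"],
            np.array([[3, 3], [2, 2], [5, 5]]),
        )
        assert beta_mntd(t, tiny_tree).values[0, 1] == pytest.approx(0.0)

    def test_single_taxon_communities(self, tiny_tree):
        t = CommunityTable(
            ["OTU_A", "OTU_B", "OTU_C"], ["s1", "s2"],
            np.array([[5, 0], [0, 3], [0, 0]]),
        )
        assert beta_mntd(t, tiny_tree).values[0, 1] == pytest.approx(2.0)

    @pytest.mark.parametrize("weighted", [True, False])
    def test_oracle_equivalence_100_instances(self, weighted):
        for seed in range(100):
            table, tree = random_instance(seed)
            D = tree.patristic(table.taxon_ids)
            got = beta_mntd(table, tree, abundance_weighted=weighted).values
            exp = brute_force_beta_mntd(table.counts, D, weighted=weighted)
            np.testing.assert_allclose(got, exp, atol=1e-12)

    def test_missing_tip_rejected(self, tiny_tree):
        t = CommunityTable(["OTU_A", "OTU_X"], ["s1", "s2"], np.array([[1, 1], [1, 1]]))
        with pytest.raises(ValidationError, match="OTU_X"):
            beta_mntd(t, tiny_tree)

    def test_invariant_to_absent_taxa(self):
        tree = simulate_tree(8, seed=3)
        rng = np.random.default_rng(4)
        counts = rng.integers(1, 10, size=(6, 3))
        taxa = list(tree.tip_names)
        t_small = CommunityTable(taxa[:6], ["a", "b", "c"], counts)
        padded = np.vstack([counts, np.zeros((2, 3), dtype=int)])
        t_padded = CommunityTable(taxa, ["a", "b", "c"], padded)
        np.testing.assert_allclose(
            beta_mntd(t_small, tree).values, beta_mntd(t_padded, tree).values
        )


class TestBnti:
    def test_identical_communities_are_null_invariant(self):
        # exactly identical membership: betaMNTD = 0 under ANY tip
        # relabeling, so the pair is degenerate (null sd = 0), not negative
        tree = simulate_tree(12, seed=5)
        rng = np.random.default_rng(6)
        col = rng.integers(1, 8, 12)
        counts = np.column_stack([col, col])
        t = CommunityTable(list(tree.tip_names), ["a", "b"], counts)
        res = bnti(t, tree, n_null=99, seed=1)
        assert res.observed.values[0, 1] == pytest.approx(0.0)
        assert res.n_degenerate == 1

    def test_near_identical_communities_negative_bnti(self):
        # high-overlap pair: observed betaMNTD ~ 0 while shuffled tips put
        # the few unshared taxa anywhere on the tree -> null mean > 0
        tree = simulate_tree(16, seed=5)
        rng = np.random.default_rng(6)
        base = rng.integers(1, 8, 16)
        a = base.copy()
        b = base.copy()
        a[:2] = 0  # two taxa exclusive to each sample
        b[2:4] = 0
        counts = np.column_stack([a, b])
        t = CommunityTable(list(tree.tip_names), ["a", "b"], counts)
        res = bnti(t, tree, n_null=199, seed=1)
        assert res.null_mean.values[0, 1] > res.observed.values[0, 1]
        assert res.bnti.values[0, 1] < 0

    def test_reproducible_for_seed(self, selection_bundle):
        table, tree, _, _ = selection_bundle
        sub = table.select_samples(table.sample_ids[:6]).drop_zero_taxa()
        a = bnti(sub, tree, n_null=49, seed=11)
        b = bnti(sub, tree, n_null=49, seed=11)
        np.testing.assert_array_equal(a.bnti.values, b.bnti.values)

    def test_bnti_definition(self, selection_bundle):
        table, tree, _, _ = selection_bundle
        sub = table.select_samples(table.sample_ids[:5]).drop_zero_taxa()
        res = bnti(sub, tree, n_null=99, seed=2)
        iu = np.triu_indices(sub.n_samples, k=1)
        expected = (res.observed.values[iu] - res.null_mean.values[iu]) / res.null_sd.values[iu]
        np.testing.assert_allclose(res.bnti.values[iu], expected)

    def test_full_tree_shuffle_variant(self, selection_bundle):
        table, tree, _, _ = selection_bundle
        sub = table.select_samples(table.sample_ids[:5]).drop_zero_taxa()
        res = bnti(sub, tree, n_null=99, seed=2, shuffle_within_pool=False)
        v = res.bnti.condensed()
        assert np.isfinite(v).any()
        # same contract: bnti = (obs - mean) / sd
        iu = np.triu_indices(sub.n_samples, k=1)
        expected = (res.observed.values[iu] - res.null_mean.values[iu]) / res.null_sd.values[iu]
        np.testing.assert_allclose(v, expected)

    def test_degenerate_star_tree_flagged(self):
        # star tree with equal branch lengths: every shuffle is identical
        newick = "(" + ",".join(f"T{i}:1" for i in range(5)) + ");"
        tree = tree_from_newick(newick)
        counts = np.array([[4, 0], [3, 0], [0, 2], [0, 5], [1, 1]])
        t = CommunityTable([f"T{i}" for i in range(5)], ["a", "b"], counts)
        res = bnti(t, tree, n_null=49, seed=0)
        assert res.n_degenerate == 1
        assert np.isnan(res.bnti.values[0, 1])


class TestRcBray:
    def test_bounds(self, neutral_bundle):
        table, *_ = neutral_bundle
        sub = table.select_samples(table.sample_ids[:6]).drop_zero_taxa()
        res = rc_bray(sub, n_null=199, seed=3)
        v = res.rc.condensed()
        assert (np.abs(v) <= 1.0).all()

    def test_identical_communities_rc_minus_one(self):
        rng = np.random.default_rng(7)
        col = rng.integers(0, 30, 40)
        other = rng.integers(0, 30, (40, 4))
        counts = np.column_stack([col, col, other])
        t = CommunityTable(
            [f"T{i}" for i in range(40)], [f"s{j}" for j in range(6)], counts
        ).drop_zero_taxa()
        res = rc_bray(t, n_null=299, seed=4)
        # obs BC = 0: essentially no null draw can do better
        assert res.rc.values[0, 1] == pytest.approx(-1.0, abs=0.02)

    def test_single_taxon_pool_rejected(self):
        t = CommunityTable(["A"], ["a", "b"], np.array([[3, 5]]))
        with pytest.raises(ValidationError, match="2 taxa"):
            rc_bray(t)

    def test_reproducible_and_order_invariant(self, neutral_bundle):
        table, *_ = neutral_bundle
        sub = table.select_samples(table.sample_ids[:5]).drop_zero_taxa()
        a = rc_bray(sub, n_null=99, seed=5)
        b = rc_bray(sub, n_null=99, seed=5)
        np.testing.assert_array_equal(a.rc.values, b.rc.values)


class TestPartition:
    @pytest.mark.parametrize(
        "b,rc,expected",
        [
            (2.5, 0.0, "heterogeneous_selection"),
            (-3.0, 0.0, "homogeneous_selection"),
            (1.0, 0.97, "dispersal_limitation"),
            (0.0, -0.99, "homogenizing_dispersal"),
            (0.0, 0.30, "drift"),
            (2.0, 0.96, "dispersal_limitation"),  # |bNTI| = 2 is NOT selection
        ],
    )
    def test_classification_rules(self, b, rc, expected):
        assert classify_pair(b, rc) == expected

    def test_fractions_sum_to_one(self):
        rng = np.random.default_rng(8)
        ids = [f"s{i}" for i in range(10)]
        n_pairs = 45
        b = pairwise_from_condensed(ids, rng.normal(0, 3, n_pairs), diagonal=np.nan)
        rc = pairwise_from_condensed(ids, rng.uniform(-1, 1, n_pairs), diagonal=np.nan)
        part = partition_processes(b, rc)
        assert sum(part.fractions.values()) == pytest.approx(1.0, abs=1e-12)
        assert part.n_pairs == n_pairs
        assert set(part.fractions) == set(PROCESSES)

    def test_degenerate_pairs_excluded(self):
        ids = ["a", "b", "c"]
        b = pairwise_from_condensed(ids, np.array([np.nan, 3.0, 0.0]), diagonal=np.nan)
        rc = pairwise_from_condensed(ids, np.array([0.5, 0.2, 0.1]), diagonal=np.nan)
        part = partition_processes(b, rc)
        assert part.n_excluded == 1
        assert part.n_pairs == 2

    def test_permutation_invariance(self, selection_bundle):
        table, tree, _, _ = selection_bundle
        sub = table.select_samples(table.sample_ids[:6]).drop_zero_taxa()
        bres = bnti(sub, tree, n_null=99, seed=6)
        rres = rc_bray(sub, n_null=99, seed=6)
        part1 = partition_processes(bres.bnti, rres.rc)
        order = list(reversed(sub.sample_ids))
        part2 = partition_processes(
            bres.bnti.submatrix(order), rres.rc.submatrix(order)
        )
        assert part1.fractions == part2.fractions


class TestPhyloSignal:
    def test_single_occurrence_optimum_equals_sample_value(self):
        import pandas as pd

        t = CommunityTable(
            ["A", "B"], ["s1", "s2"], np.array([[4, 0], [1, 3]])
        )
        env = pd.DataFrame({"temp": [10.0, 20.0]}, index=["s1", "s2"])
        opt = niche_optima(t, env, min_occurrences=1)
        assert opt.loc["A", "temp"] == pytest.approx(10.0)

    def test_rare_taxa_excluded(self):
        import pandas as pd

        t = CommunityTable(["A", "B"], ["s1", "s2"], np.array([[4, 0], [1, 3]]))
        env = pd.DataFrame({"temp": [10.0, 20.0]}, index=["s1", "s2"])
        opt = niche_optima(t, env, min_occurrences=2)
        assert "A" not in opt.index and "B" in opt.index

    def test_brownian_optima_short_distance_signal(self, selection_bundle):
        table, tree, meta, _ = selection_bundle
        cor = phylo_signal(
            table, tree, meta, variables=["temperature"],
            n_classes=8, n_perm=199, seed=3,
        )
        valid = ~np.isnan(cor.mantel_r)
        first = np.flatnonzero(valid)[0]
        assert cor.mantel_r[first] > 0
        assert cor.p_corrected[first] < 0.05

    def test_permuted_optima_no_signal(self, selection_bundle):
        table, tree, meta, _ = selection_bundle
        rng = np.random.default_rng(9)
        shuffled = table.counts[rng.permutation(table.n_taxa)]
        t2 = CommunityTable(table.taxon_ids, table.sample_ids, shuffled).drop_zero_taxa()
        cor = phylo_signal(
            t2, tree, meta, variables=["temperature"],
            n_classes=8, n_perm=199, seed=4,
        )
        sig = np.nansum(cor.p_corrected < 0.05)
        assert sig <= 1  # at most nominal
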