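import itertools

import numpy as np
import pandas as pd
import pytest

from assemblyscope.community_data import CountTable, PairwiseMatrix, read_tree
from assemblyscope.community_data import patristic_distances
from assemblyscope.null_models import (
    PROCESSES,
    NullEnsembleSpec,
    beta_nti,
    classify_processes,
    null_community_ensemble,
    raup_crick_bray,
)
from assemblyscope.simulate import simulate_tree


def brute_force_beta_mntd(counts_i, counts_j, d):
    """Plain-python abundance-weighted betaMNTD for one pair (oracle)."""
    def half(ci, cj):
        total = sum(ci)
        acc = 0.0
        for k, ck in enumerate(ci):
            if ck == 0:
                continue
            nearest = min(d[k][l] for l, cl in enumerate(cj) if cl > 0)
            acc += (ck / total) * nearest
        return acc

    return 0.5 * (half(counts_i, counts_j) + half(counts_j, counts_i))


class TestBetaNTI:
    def test_monte_carlo_matches_exhaustive_permutations(self):
        """5-tip tree: all 120 tip permutations give the exact null z-score."""
        tree = simulate_tree(5, seed=42)
        taxa = [t.name for t in tree.tips()]
        counts = [[5, 3, 0, 0, 2], [0, 1, 4, 6, 0]]
        tab = CountTable(pd.DataFrame(counts, index=["a", "b"], columns=taxa))
        d = patristic_distances(tree, taxa).values.tolist()

        obs = brute_force_beta_mntd(counts[0], counts[1], d)
        nulls = []
        for perm in itertools.permutations(range(5)):
            dp = [[d[perm[k]][perm[l]] for l in range(5)] for k in range(5)]
            nulls.append(brute_force_beta_mntd(counts[0], counts[1], dp))
        exact_z = (obs - np.mean(nulls)) / np.std(nulls)

        mc = beta_nti(tab, tree, NullEnsembleSpec(n_null=5000, seed=1))
        assert mc.pair("a", "b") == pytest.approx(exact_z, abs=0.15)

    def test_equidistant_tips_flagged_undefined(self):
        # all tip-to-tip distances equal -> every null equals the observed
        tree = read_tree("((A:1,B:1):0,(C:1,D:1):0):0;")
        tab = CountTable(pd.DataFrame(
            [[1, 1, 0, 0], [0, 0, 1, 1]], index=["a", "b"], columns=list("ABCD")))
        z = beta_nti(tab, tree, NullEnsembleSpec(n_null=99, seed=0))
        assert np.isnan(z.pair("a", "b"))

    def test_identical_communities_never_positive(self, balanced_tree):
        tab = CountTable(pd.DataFrame(
            [[2, 1, 3, 0], [2, 1, 3, 0]], index=["a", "b"], columns=list("ABCD")))
        z = beta_nti(tab, balanced_tree, NullEnsembleSpec(n_null=99, seed=0))
        v = z.pair("a", "b")
        assert np.isnan(v) or v <= 0

    def test_invariant_under_branch_length_scaling(self):
        tree_a = simulate_tree(20, seed=9)
        tree_b = tree_a.copy()
        for node in tree_b.traverse(include_self=False):
            node.length = node.length * 7.5
        rng = np.random.default_rng(3)
        taxa = [t.name for t in tree_a.tips()]
        counts = rng.integers(0, 5, size=(4, 20))
        counts[:, 0] += 1
        tab = CountTable(pd.DataFrame(
            counts, index=list("abcd"), columns=taxa))
        za = beta_nti(tab, tree_a, NullEnsembleSpec(n_null=199, seed=5))
        zb = beta_nti(tab, tree_b, NullEnsembleSpec(n_null=199, seed=5))
        assert np.allclose(za.values, zb.values, equal_nan=True)


def oracle_raup_crick(table, pair, n_draws, seed):
    """Independent large-n Monte-Carlo RC_bray oracle.

    Weighted sampling without replacement via Efraimidis-Spirakis keys
    (u^(1/w)), one-individual seeding, multinomial filling, and direct
    Bray-Curtis comparison against the observed value.
    """
    rng = np.random.default_rng(seed)
    counts = table.counts()
    occ = (counts > 0).mean(axis=0)
    ab = counts.sum(axis=0) / counts.sum()
    i, j = (table.sample_ids.index(s) for s in pair)

    def bc(a, b):
        return 1.0 - 2.0 * np.minimum(a, b).sum() / (a.sum() + b.sum())

    obs = bc(counts[i], counts[j])

    def draw(row):
        rich, total = int((row > 0).sum()), int(row.sum())
        keys = rng.random(len(row)) ** (1.0 / occ)
        chosen = np.argsort(-keys)[:rich]
        out = np.zeros(len(row), dtype=int)
        p = ab[chosen] / ab[chosen].sum()
        out[chosen] = 1 + rng.multinomial(total - rich, p)
        return out

    below = ties = 0
    for _ in range(n_draws):
        v = bc(draw(counts[i]), draw(counts[j]))
        if v < obs - 1e-12:
            below += 1
        elif abs(v - obs) <= 1e-12:
            ties += 1
    return 2.0 * (below + 0.5 * ties) / n_draws - 1.0


class TestRaupCrick:
    def test_matches_brute_force_oracle_on_toy(self, toy_table):
        """Implementation (n_null=999) vs 10^5 independent draws, +/-0.10."""
        rc = raup_crick_bray(toy_table, NullEnsembleSpec(n_null=999, seed=3))
        ids = toy_table.sample_ids
        for a, b in itertools.combinations(ids, 2):
            expected = oracle_raup_crick(toy_table, (a, b), n_draws=100_000,
                                         seed=hash((a, b)) % 2**31)
            assert rc.pair(a, b) == pytest.approx(expected, abs=0.10)

    def test_boundary_plus_one_when_obs_exceeds_all_nulls(self):
        df = pd.DataFrame(
            [[97, 1, 1, 1], [1, 1, 1, 97], [25, 25, 25, 25]],
            index=["a", "b", "c"], columns=list("ABCD"))
        rc = raup_crick_bray(CountTable(df), NullEnsembleSpec(n_null=199, seed=0))
        assert rc.pair("a", "b") == pytest.approx(1.0)

    def test_boundary_minus_one_for_identical_full_samples(self):
        df = pd.DataFrame(
            [[25, 25, 25, 25], [25, 25, 25, 25], [10, 30, 5, 55]],
            index=["a", "b", "c"], columns=list("ABCD"))
        rc = raup_crick_bray(CountTable(df), NullEnsembleSpec(n_null=199, seed=0))
        assert rc.pair("a", "b") == pytest.approx(-1.0)

    def test_values_bounded(self, toy_table):
        rc = raup_crick_bray(toy_table, NullEnsembleSpec(n_null=199, seed=1))
        vals = rc.condensed()
        assert ((vals >= -1) & (vals <= 1)).all()

    def test_null_self_consistency_is_centred(self):
        """RC of communities generated BY the null is ~uniform on [-1,1]."""
        rng = np.random.default_rng(8)
        n_taxa = 30
        occ = rng.random(n_taxa) * 0.8 + 0.1
        ab = rng.dirichlet(np.ones(n_taxa))
        rcs = []
        for rep in range(8):  # 8 tables x 28 pairs = 224 RC values
            rows = null_community_ensemble(
                np.random.default_rng(1000 + rep), 10, 60, occ, ab, 8)
            tab = CountTable(pd.DataFrame(
                rows, index=[f"s{i}" for i in range(8)],
                columns=[f"t{k}" for k in range(n_taxa)],
            )).drop_empty_taxa()
            rc = raup_crick_bray(tab, NullEnsembleSpec(n_null=199, seed=rep))
            rcs.extend(rc.condensed())
        rcs = np.array(rcs)
        assert np.abs(rcs).mean() <= 0.6
        assert (np.abs(rcs) > 0.95).mean() <= 0.10


class TestClassifyProcesses:
    @staticmethod
    def matrices(bnti_val, rc_val):
        ids = ["a", "b"]
        z = np.array([[np.nan, bnti_val], [bnti_val, np.nan]])
        r = np.array([[np.nan, rc_val], [rc_val, np.nan]])
        return (PairwiseMatrix(ids, z, "beta_nti"),
                PairwiseMatrix(ids, r, "rc_bray"))

    @pytest.mark.parametrize(
        "bnti,rc,expected",
        [
            (2.5, 0.1, "variable_selection"),
            (-2.5, 0.99, "homogeneous_selection"),
            (-1.0, 0.99, "dispersal_limitation"),
            (1.0, -0.99, "homogenizing_dispersal"),
            (0.3, 0.2, "undominated"),
            # boundary values fall on the non-significant side
            (2.0, 0.2, "undominated"),
            (-2.0, 0.2, "undominated"),
            (0.0, 0.95, "undominated"),
            (0.0, -0.95, "undominated"),
        ],
    )
    def test_rules(self, bnti, rc, expected):
        summ = classify_processes(*self.matrices(bnti, rc))
        assert summ.labels.iloc[0]["process"] == expected

    def test_fractions_sum_to_one_on_random_fixtures(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n = rng.integers(3, 8)
            ids = [f"s{i}" for i in range(n)]
            z = rng.normal(0, 3, (n, n))
            z = (z + z.T) / 2
            np.fill_diagonal(z, np.nan)
            r = np.clip(rng.normal(0, 0.8, (n, n)), -1, 1)
            r = (r + r.T) / 2
            np.fill_diagonal(r, np.nan)
            summ = classify_processes(
                PairwiseMatrix(ids, z, "beta_nti"),
                PairwiseMatrix(ids, r, "rc_bray"),
            )
            assert sum(summ.fractions_exact.values()) == 1  # exact, as count ratios
            assert sum(summ.counts.values()) == summ.n_pairs

    def test_undefined_pairs_excluded_and_counted(self):
        ids = ["a", "b", "c"]
        z = np.full((3, 3), 0.5)
        z[0, 1] = z[1, 0] = np.nan
        np.fill_diagonal(z, np.nan)
        r = np.zeros((3, 3))
        summ = classify_processes(
            PairwiseMatrix(ids, z, "beta_nti"), PairwiseMatrix(ids, r, "rc_bray"))
        assert summ.n_excluded == 1
        assert summ.n_pairs == 2
        assert ("a", "b") in summ.excluded_pairs
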