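"""Diversity, clustering, rank-sum/BH and substrate apportionment."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import kstest
from sklearn.metrics import adjusted_rand_score, silhouette_score

from conftest import make_entry, random_protein
from glycometa.refdb import ReferenceCatalogue
from glycometa.stats import (bh_adjust, call_clusters, cluster_summary,
                             hierarchical_order, rank_sum_test, shannon_index,
                             substrate_apportion, top_k_differential, tsne_embed)
from glycometa.synthetic import planted_effect_matrix
from oracle_utils import bh_stepup, ranksum_exact_enumeration, shannon_direct


class TestShannon:
    def test_uniform_four_categories(self):
        assert shannon_index([0.25] * 4) == pytest.approx(2.0, abs=1e-12)

    def test_single_category(self):
        assert shannon_index([1.0]) == 0.0

    def test_half_quarter_quarter(self):
        assert shannon_index([0.5, 0.25, 0.25]) == pytest.approx(1.5, abs=1e-12)

    def test_all_zero_is_error(self):
        with pytest.raises(ValueError, match="empty"):
            shannon_index([0.0, 0.0])

    def test_renormalises_unnormalised_input(self):
        assert shannon_index([2, 1, 1]) == pytest.approx(1.5, abs=1e-12)

    def test_bound_and_relabel_invariance(self, rng):
        for _ in range(30):
            s = int(rng.integers(1, 20))
            p = rng.dirichlet(np.ones(s))
            h = shannon_index(p)
            assert -1e-12 <= h <= np.log2(s) + 1e-12
            assert h == pytest.approx(shannon_index(rng.permutation(p)), abs=1e-12)
            assert h == pytest.approx(shannon_direct(p), abs=1e-9)


class TestHierarchical:
    def test_identical_rows_merge_at_zero(self):
        mat = pd.DataFrame([[1.0, 2.0], [1.0, 2.0], [5.0, 5.0]])
        _order, tree = hierarchical_order(mat)
        assert tree[0, 2] == 0.0

    def test_first_merge_is_closest_pair(self):
        mat = pd.DataFrame([[0.0], [1.0], [10.0]])
        _order, tree = hierarchical_order(mat)
        assert sorted(tree[0, :2].astype(int).tolist()) == [0, 1]

    def test_merge_heights_monotone(self, rng):
        for _ in range(10):
            mat = pd.DataFrame(rng.normal(size=(20, 5)))
            _order, tree = hierarchical_order(mat)
            heights = tree[:, 2]
            assert (np.diff(heights) >= -1e-12).all()

    def test_nan_rejected(self):
        mat = pd.DataFrame([[1.0, np.nan], [0.0, 1.0]])
        with pytest.raises(ValueError, match="NaN"):
            hierarchical_order(mat)


class TestTsne:
    def _blobs(self, rng, n_per=15, sigma=0.01, dist=10.0):
        centers = np.array([[0, 0, 0, 0], [dist, 0, 0, 0], [0, dist, 0, 0]])
        rows, labels = [], []
        for c, center in enumerate(centers):
            rows.append(center + rng.normal(scale=sigma, size=(n_per, 4)))
            labels += [c] * n_per
        return pd.DataFrame(np.vstack(rows)), np.array(labels)

    def test_shape_and_determinism(self, rng):
        mat, _ = self._blobs(rng)
        with pytest.warns(UserWarning, match="perplexity"):
            e1 = tsne_embed(mat, seed=3)
            e2 = tsne_embed(mat, seed=3)
        assert e1.shape == (45, 2)
        assert np.array_equal(e1, e2)

    def test_separated_blobs_recovered(self, rng):
        mat, labels = self._blobs(rng)
        with pytest.warns(UserWarning):
            emb = tsne_embed(mat, seed=1)
        assert silhouette_score(emb, labels) > 0.8

    def test_constant_matrix_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            tsne_embed(pd.DataFrame(np.ones((10, 3))), seed=0)


class TestCallClusters:
    def test_k_one_rejected(self):
        with pytest.raises(ValueError):
            call_clusters(np.zeros((5, 2)), ["a"] * 5, k=1, seed=0)

    def test_k_larger_than_n_rejected(self):
        with pytest.raises(ValueError):
            call_clusters(np.zeros((3, 2)), list("abc"), k=4, seed=0)

    def test_blob_recovery_and_label_order(self, rng):
        pts = np.vstack([rng.normal([0, 0], 0.1, (10, 2)),
                         rng.normal([8, 0], 0.1, (10, 2)),
                         rng.normal([0, 8], 0.1, (10, 2))])
        ids = [f"s{i}" for i in range(30)]
        truth = [0] * 10 + [1] * 10 + [2] * 10
        # glycan fractions make blob 2 richest, blob 0 poorest
        fractions = {f"s{i}": [1.0, 2.0, 3.0][truth[i]] for i in range(30)}
        calls = call_clusters(pts, ids, k=3, seed=5, glycan_fractions=fractions)
        labels = [c.cluster_label for c in calls]
        assert adjusted_rand_score(truth, labels) == 1.0
        # highest-abundance blob must end up with the top label
        assert {labels[i] for i in range(20, 30)} == {3}
        assert {labels[i] for i in range(10)} == {1}


class TestConsensusClusters:
    def _blob_matrix(self, rng, n_per=10):
        centers = np.array([[0] * 6, [6] * 6, [0, 6, 0, 6, 0, 6]])
        rows = np.vstack([c + rng.normal(scale=0.3, size=(n_per, 6))
                          for c in centers])
        ids = [f"s{i}" for i in range(3 * n_per)]
        return pd.DataFrame(rows, index=ids), [i // n_per for i in range(3 * n_per)]

    def test_recovers_blobs_and_orders_labels(self, rng):
        from glycometa.stats import consensus_clusters
        mat, truth = self._blob_matrix(rng)
        fractions = {sid: [1.0, 2.0, 3.0][truth[i]] for i, sid in enumerate(mat.index)}
        with pytest.warns(UserWarning):
            calls, emb = consensus_clusters(mat, list(mat.index), k=3, seed=4,
                                            glycan_fractions=fractions)
        labels = [c.cluster_label for c in calls]
        assert adjusted_rand_score(truth, labels) == 1.0
        assert {labels[i] for i, t in enumerate(truth) if t == 2} == {3}
        assert emb.shape == (30, 2)

    def test_deterministic(self, rng):
        from glycometa.stats import consensus_clusters
        mat, _ = self._blob_matrix(rng)
        with pytest.warns(UserWarning):
            a, _ = consensus_clusters(mat, list(mat.index), k=3, seed=9)
            b, _ = consensus_clusters(mat, list(mat.index), k=3, seed=9)
        assert [c.cluster_label for c in a] == [c.cluster_label for c in b]


class TestRankSum:
    def test_disjoint_small_groups(self):
        # all C(6,3)=20 splits; both extremes -> p = 2 * 1/20 = 0.1
        assert rank_sum_test([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1, abs=1e-12)

    def test_identical_groups(self):
        assert rank_sum_test([2.0, 2.0, 2.0], [2.0, 2.0, 2.0]) == 1.0

    def test_symmetry(self, rng):
        a, b = rng.normal(size=6), rng.normal(size=5)
        assert rank_sum_test(a, b) == pytest.approx(rank_sum_test(b, a))

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            rank_sum_test([1, 2], [3, 4, 5])

    def test_exact_and_asymptotic_agree_at_n8(self):
        """The two branches agree closely at the crossover size n=8/8.

        Checked exhaustively over every possible U statistic: the
        continuity-corrected normal approximation deviates from the exact
        two-sided p by at most 0.0109 (attained in the uninformative centre
        of the distribution), and by under 0.006 wherever p < 0.2.
        """
        import itertools
        from scipy.stats import norm
        u_all = np.array([sum(c) - 36 for c in itertools.combinations(range(1, 17), 8)])
        sd = np.sqrt(8 * 8 * 17 / 12)
        worst = worst_small = 0.0
        for u in range(0, 65):
            p_exact = min(1.0, 2 * min((u_all <= u).mean(), (u_all >= u).mean()))
            p_approx = min(1.0, 2 * float(norm.sf((abs(u - 32) - 0.5) / sd)))
            gap = abs(p_exact - p_approx)
            worst = max(worst, gap)
            if p_exact < 0.2:
                worst_small = max(worst_small, gap)
        assert worst <= 0.011
        assert worst_small <= 0.006

    def test_matches_enumeration_oracle(self, rng):
        for _ in range(50):
            na, nb = rng.integers(3, 7, size=2)
            vals = rng.permutation(rng.normal(size=int(na + nb)))
            a, b = vals[:na], vals[na:]
            assert rank_sum_test(a, b) == pytest.approx(
                ranksum_exact_enumeration(a, b), abs=1e-12)


class TestBH:
    def test_worked_example(self):
        q = bh_adjust([0.005, 0.01, 0.03, 0.04])
        assert np.allclose(q, [0.02, 0.02, 0.04, 0.04])

    def test_single_and_constant(self):
        assert bh_adjust([0.17])[0] == pytest.approx(0.17)
        assert np.allclose(bh_adjust([0.3, 0.3, 0.3]), 0.3)

    def test_matches_stepup_oracle(self, rng):
        for _ in range(100):
            p = rng.random(int(rng.integers(1, 40)))
            assert np.allclose(bh_adjust(p), bh_stepup(p), atol=1e-12)

    def test_q_at_least_p_and_rank_monotone(self, rng):
        p = rng.random(50)
        q = bh_adjust(p)
        assert (q >= p - 1e-12).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=30))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_matches_stepup_on_arbitrary_vectors(self, p):
        assert np.allclose(bh_adjust(p), bh_stepup(p), atol=1e-12)


@given(st.lists(st.floats(min_value=1e-9, max_value=1e6), min_size=1, max_size=25))
@settings(max_examples=60, deadline=None, derandomize=True)
def test_shannon_bound_holds_for_arbitrary_abundances(values):
    h = shannon_index(values)
    assert -1e-9 <= h <= np.log2(len(values)) + 1e-9


class TestTopKDifferential:
    def test_planted_effects_recovered(self):
        mat, enriched, labels = planted_effect_matrix(seed=1)
        res = top_k_differential(mat, labels, k=20)[(1, 2)]
        top = {r.function_id for r in res}
        assert set(enriched) <= top
        by_fn = {r.function_id: r for r in res}
        assert all(by_fn[f].q_value < 0.05 and by_fn[f].higher_in == 2
                   for f in enriched)

    def test_permutation_null_controlled(self, rng):
        mat, _, labels = planted_effect_matrix(n_enriched=0, seed=2)
        fps = []
        for _ in range(5):
            perm = rng.permutation(labels)
            res = top_k_differential(mat, perm, k=20)[(1, 2)]
            fps.append(sum(r.q_value < 0.05 for r in res))
        assert np.mean(fps) <= 1.0

    def test_deterministic_ordering(self):
        mat, _, labels = planted_effect_matrix(seed=4)
        r1 = top_k_differential(mat, labels)[(1, 2)]
        r2 = top_k_differential(mat, labels)[(1, 2)]
        assert [(r.function_id, r.q_value) for r in r1] == \
               [(r.function_id, r.q_value) for r in r2]

    def test_fewer_functions_than_k_warns(self):
        mat, _, labels = planted_effect_matrix(n_functions=6, n_enriched=2, seed=5)
        with pytest.warns(UserWarning, match="top-20"):
            res = top_k_differential(mat, labels, k=20)[(1, 2)]
        assert len(res) == 6


class TestSubstrateApportion:
    def _catalogue(self, rng):
        return ReferenceCatalogue([
            make_entry("a", random_protein(rng, 40), functions=[("f1", 1.0)],
                       substrates=[("Plant", 2.0), ("Starch", 1.0)]),
            make_entry("b", random_protein(rng, 40), functions=[("f2", 1.0)],
                       substrates=[("Plant", 1.0)]),
            make_entry("c", random_protein(rng, 40), functions=[("f3", 1.0)],
                       substrates=[("Plant", 3.0)]),
            make_entry("d", random_protein(rng, 40), functions=[("f4", 1.0)],
                       substrates=[]),
        ])

    def test_proportional_split(self, rng):
        shares, unann = substrate_apportion(["f1"], [0.3], self._catalogue(rng))
        # Plant:Starch = 2:1 -> 0.2 / 0.1 before pooling, 2/3 / 1/3 after
        assert shares["Plant"] == pytest.approx(2 / 3)
        assert shares["Starch"] == pytest.approx(1 / 3)
        assert unann == 0.0

    def test_all_plant_functions(self, rng):
        shares, _ = substrate_apportion(["f2", "f3"], [0.1, 0.4], self._catalogue(rng))
        assert shares["Plant"] == pytest.approx(1.0)

    def test_unannotated_booked_separately(self, rng):
        shares, unann = substrate_apportion(["f2", "f4"], [0.1, 0.2],
                                            self._catalogue(rng))
        assert unann == pytest.approx(0.2)
        assert sum(shares.values()) == pytest.approx(1.0, abs=1e-12)


class TestClusterSummary:
    def _profiles(self, rng, fractions, n_per=30):
        from glycometa.profile import SampleProfile
        profiles, labels = [], {}
        for c, mu in enumerate(fractions, start=1):
            for i in range(n_per):
                frac = max(0.1, rng.normal(mu, mu * 0.15))
                sid = f"c{c}s{i}"
                n_total = 10_000
                n_gly = int(n_total * frac / 100)
                profiles.append(SampleProfile(
                    sample_id=sid, n_reads_total=n_total, n_glycan=n_gly,
                    class_rel={}, family_counts={},
                    function_rel={}, function_class_mass={},
                    role_tables={"degradation": {"f1": 0.5, "f2": 0.5},
                                 "synthesis": {"g1": 1.0}},
                    taxon_rel={"phylum": {}, "family": {},
                               "genus": {"Blautia": 0.5, "Bacteroides": 0.5}},
                ))
                labels[sid] = c
        return profiles, labels

    def test_two_fold_effect_detected(self, rng):
        profiles, labels = self._profiles(rng, [2.0, 4.0])
        summary = cluster_summary(profiles, labels)
        assert summary.pairwise_p[(1, 2)] < 0.01
        assert summary.cluster_means[1] < summary.cluster_means[2]

    def test_null_p_values_uniform(self, rng):
        pvals = []
        for _ in range(200):
            a = rng.normal(size=30)
            b = rng.normal(size=30)
            pvals.append(rank_sum_test(a, b))
        assert kstest(pvals, "uniform").pvalue > 0.01

    def test_organism_diversity_bounded(self, rng):
        profiles, labels = self._profiles(rng, [2.0, 4.0], n_per=5)
        summary = cluster_summary(profiles, labels)
        org = [d for d in summary.diversity if d.basis == "organisms"]
        assert org and all(d.H_prime <= np.log2(2) + 1e-12 for d in org)
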