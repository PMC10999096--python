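"""Ranking, enrichment metrics, PR curves, similarity analyses, stats."""

import itertools
import math

import numpy as np
import pytest

from targetsf import evaluation
from targetsf.evaluation import (RankedScreen, cluster_by_similarity,
                                 compare_nef_groups, dissimilar_filter,
                                 ef_fraction, enrichment_report,
                                 max_ef_fraction, nearest_training_similarity,
                                 nef_fraction, pr_auc, pr_curve, random_nef,
                                 rank, select_median_run)


def perfect_screen(n, n_actives):
    labels = np.zeros(n, dtype=bool)
    labels[:n_actives] = True
    return RankedScreen([f"c{i:05d}" for i in range(n)],
                        np.linspace(1, 0, n), labels)


class TestRank:
    def test_matches_plain_sort_on_distinct_scores(self):
        rng = np.random.default_rng(0)
        scores = rng.permutation(20).astype(float)
        ids = [f"m{i}" for i in range(20)]
        screen = rank(ids, scores, scores > 10)
        expected = [ids[i] for i in np.argsort(-scores)]
        assert screen.compound_ids == expected

    def test_all_equal_scores_fall_back_to_id_order(self):
        screen = rank(["c", "a", "b"], [1.0, 1.0, 1.0], [0, 1, 0])
        assert screen.compound_ids == ["a", "b", "c"]

    def test_partial_tie_documented_order(self):
        ids = ["a", "b", "c", "d", "e"]
        scores = [3.0, 1.0, 3.0, 2.0, 1.0]
        screen = rank(ids, scores, [1, 0, 0, 0, 0])
        assert screen.compound_ids == ["a", "c", "d", "b", "e"]

    def test_seeded_shuffle_mode_reproducible(self):
        ids = list("abcdef")
        scores = [1.0] * 6
        s1 = rank(ids, scores, [0] * 6, tie_break="shuffle", tie_seed=4)
        s2 = rank(ids, scores, [0] * 6, tie_break="shuffle", tie_seed=4)
        assert s1.compound_ids == s2.compound_ids

    def test_empty_screen_rejected(self):
        with pytest.raises(ValueError):
            rank([], [], [])


class TestEnrichment:
    def test_perfect_ranking_reaches_printed_maximum(self):
        screen = perfect_screen(3443, 67)
        assert round(ef_fraction(screen), 2) == 50.75

    def test_background_rate_top_bin_gives_ef_one(self):
        # 100 molecules, 10 actives; top-10% bin holds 1 active, exactly
        # the overall hit rate -> no enrichment
        labels = np.zeros(100, dtype=bool)
        labels[5] = True
        labels[50:59] = True
        screen = RankedScreen([f"c{i:03d}" for i in range(100)],
                              np.linspace(1, 0, 100), labels)
        assert ef_fraction(screen, f=0.1) == pytest.approx(1.0)

    def test_small_screen_brute_force_example(self):
        # N=200, A=10, 1 active within the top floor(0.01*200)=2
        labels = np.zeros(200, dtype=bool)
        labels[0] = True
        labels[100:109] = True
        screen = RankedScreen([f"c{i:03d}" for i in range(200)],
                              np.linspace(1, 0, 200), labels)
        assert ef_fraction(screen) == pytest.approx((1 / 10) / 0.01)

    @pytest.mark.parametrize("n,a,expected", [(3443, 67, 50.75),
                                              (3426, 57, 59.65)])
    def test_maximum_matches_printed_values(self, n, a, expected):
        assert round(max_ef_fraction(n, a, 0.01), 2) == expected

    def test_maximum_saturates_at_inverse_fraction(self):
        assert max_ef_fraction(10000, 5, 0.01) == pytest.approx(100.0)

    def test_integer_identity(self):
        for n, a, f in [(3443, 67, 0.01), (500, 3, 0.02), (77, 10, 0.1)]:
            lhs = max_ef_fraction(n, a, f) * a * f
            assert lhs == pytest.approx(min(math.floor(f * n), a), abs=1e-9)

    def test_nef_of_perfect_ranking_is_one(self):
        assert nef_fraction(perfect_screen(3443, 67)) == pytest.approx(1.0)

    @pytest.mark.parametrize("n,a,expected", [(3443, 67, 0.020),
                                              (3426, 57, 0.017)])
    def test_random_baseline_matches_printed_values(self, n, a, expected):
        assert round(random_nef(n, a, 0.01), 3) == expected

    def test_nef_invariant_to_monotone_score_transforms(self):
        rng = np.random.default_rng(5)
        scores = rng.normal(size=300)
        labels = rng.random(300) < 0.1
        if not labels.any():
            labels[0] = True
        ids = [f"c{i:03d}" for i in range(300)]
        base = nef_fraction(rank(ids, scores, labels))
        for transform in (np.exp, lambda s: 3 * s - 7, np.tanh):
            assert nef_fraction(rank(ids, transform(scores), labels)) \
                == pytest.approx(base)

    def test_precision_variant_available(self):
        screen = perfect_screen(3443, 67)
        # precision form: top 34 all active -> (34/34)/(67/3443)
        assert ef_fraction(screen, variant="precision") == \
            pytest.approx((34 / 34) / (67 / 3443))

    def test_enrichment_report_consistency(self):
        screen = perfect_screen(500, 20)
        report = enrichment_report(screen)
        assert report.nef == pytest.approx(report.ef / report.max_ef)
        assert report.random_nef == pytest.approx(1 / report.max_ef)
        assert report.n_top == 5


class TestPrCurve:
    def test_perfect_ranking_keeps_precision_one(self):
        screen = perfect_screen(100, 10)
        points = pr_curve(screen)
        # full recall is reached while precision is still 1, and no
        # operating point trades recall for better-than-perfect precision
        assert (1.0, 1.0) in [(round(r, 9), round(p, 9)) for r, p in points]
        assert pr_auc(screen) == pytest.approx(1.0)

    def test_random_ranking_area_near_base_rate(self):
        rng = np.random.default_rng(9)
        labels = np.zeros(2000, dtype=bool)
        labels[:100] = True
        areas = []
        for _ in range(20):
            scores = rng.random(2000)
            screen = rank([f"c{i:04d}" for i in range(2000)], scores, labels)
            areas.append(pr_auc(screen))
        assert np.mean(areas) == pytest.approx(0.05, abs=0.02)

    def test_inverted_ranking_minimizes_area_on_toy(self):
        scores = np.linspace(1, 0, 6)
        ids = list("abcdef")
        areas = {}
        for labels in set(itertools.permutations([1, 1, 0, 0, 0, 0])):
            screen = RankedScreen(ids, scores, np.array(labels, dtype=bool))
            areas[labels] = pr_auc(screen)
        inverted = (0, 0, 0, 0, 1, 1)
        assert areas[inverted] == pytest.approx(min(areas.values()))


class TestMedianRunSelection:
    class Run:
        def __init__(self, nef):
            self.nef = nef

    def test_odd_count_exact_median(self):
        runs = [self.Run(v) for v in (0.1, 0.5, 0.9)]
        assert select_median_run(runs).nef == 0.5

    def test_all_equal_seeded_choice_reproducible(self):
        runs = [self.Run(0.4) for _ in range(4)]
        first = select_median_run(runs, seed=2)
        assert select_median_run(runs, seed=2) is first

    def test_even_count_tie_resolved_among_straddlers(self):
        runs = [self.Run(v) for v in (0.2, 0.4, 0.6, 0.8)]
        chosen = select_median_run(runs, seed=0)
        assert chosen.nef in (0.4, 0.6)

    def test_no_runs_rejected(self):
        with pytest.raises(ValueError):
            select_median_run([])


class TestSimilarityAnalyses:
    TRAIN = {"t1": "CCCCCCCCCCO", "t2": "c1ccccc1C(=O)N", "t3": "CCN(CC)CC"}
    TEST = {"q1": "CCCCCCCCCCCO",   # homolog of t1: similarity >= 0.7
            "q2": "OC1CCCCC1",
            "q3": "c1ccncc1",
            "q4": "CC(C)(C)C",
            "q5": "NCCS"}

    def _max_sim(self, smiles, pool):
        from rdkit.DataStructs import TanimotoSimilarity

        from targetsf.features import similarity_fingerprint

        fp = similarity_fingerprint(smiles)
        return max(TanimotoSimilarity(fp, similarity_fingerprint(s))
                   for s in pool)

    def test_filter_matches_brute_force(self):
        kept = dissimilar_filter(self.TEST, self.TRAIN, cutoff=0.70)
        expected = [cid for cid, smi in self.TEST.items()
                    if self._max_sim(smi, self.TRAIN.values()) < 0.70]
        assert sorted(kept) == sorted(expected)
        assert "q1" not in kept  # the planted near-duplicate is removed

    def test_zero_similarity_pool_is_identity(self):
        kept = dissimilar_filter({"a": "CCCCCCCC"}, {"t": "c1ccncc1"},
                                 cutoff=0.70)
        assert kept == ["a"]

    def test_cutoff_zero_removes_everything(self):
        assert dissimilar_filter(self.TEST, self.TRAIN, cutoff=0.0) == []

    def test_filter_monotone_in_cutoff(self):
        sizes = [len(dissimilar_filter(self.TEST, self.TRAIN, cutoff=c))
                 for c in (0.1, 0.4, 0.7, 1.01)]
        assert sizes == sorted(sizes)

    def test_nearest_neighbor_identical_molecule(self):
        sim, cid, label = nearest_training_similarity(
            "CCCCCCCCCCO", [("t1", "CCCCCCCCCCO", "active"),
                            ("t2", "c1ccccc1", "inactive")])
        assert (sim, cid, label) == (1.0, "t1", "active")

    def test_nearest_neighbor_matches_brute_force(self):
        from rdkit.DataStructs import TanimotoSimilarity

        from targetsf.features import similarity_fingerprint

        training = [(f"t{i}", smi, "active") for i, smi in
                    enumerate(["CCO", "CCCCCCCCCCO", "c1ccccc1CN"])]
        query = "CCCCCCCCCO"
        sim, cid, _ = nearest_training_similarity(query, training)
        qfp = similarity_fingerprint(query)
        best = max(training,
                   key=lambda t: TanimotoSimilarity(
                       qfp, similarity_fingerprint(t[1])))
        assert cid == best[0]

    def test_nearest_neighbor_empty_training_rejected(self):
        with pytest.raises(ValueError):
            nearest_training_similarity("CCO", [])

    def test_identical_molecules_single_cluster(self):
        clusters = cluster_by_similarity(
            {"a": "CCO", "b": "CCO", "c": "OCC"})
        assert clusters.n_clusters == 1

    def test_pairwise_dissimilar_all_singletons(self):
        clusters = cluster_by_similarity(
            {"a": "CCCCCCCC", "b": "c1ccncc1", "c": "NCCS"})
        assert clusters.n_clusters == 3

    def test_transitive_chain_clusters_together(self):
        # butanol ~ pentanol (0.77) ~ hexanol (0.92) but
        # butanol-hexanol is only 0.71 < cutoff 0.75
        from rdkit.DataStructs import TanimotoSimilarity

        from targetsf.features import similarity_fingerprint

        mols = {"a": "CCCCO", "b": "CCCCCO", "c": "CCCCCCO"}
        fa, fc = (similarity_fingerprint(mols[k]) for k in ("a", "c"))
        assert TanimotoSimilarity(fa, fc) < 0.75
        clusters = cluster_by_similarity(mols, cutoff=0.75)
        assert clusters.n_clusters == 1

    def test_cluster_count_input_order_invariant(self):
        mols = {"a": "CCCCO", "b": "CCCCCO", "c": "c1ccncc1", "d": "NCCS"}
        c1 = cluster_by_similarity(mols, cutoff=0.75)
        c2 = cluster_by_similarity(dict(reversed(list(mols.items()))),
                                   cutoff=0.75)
        assert c1.n_clusters == c2.n_clusters
        assert c1.members() == c2.members()


class TestGroupStats:
    def test_identical_groups_zero_statistic(self):
        g = [0.1, 0.2, 0.3, 0.4]
        out = compare_nef_groups(g, g)
        assert out["welch_t"] == pytest.approx(0.0)

    def test_separated_normals_reject_equality(self):
        rng = np.random.default_rng(12)
        out = compare_nef_groups(rng.normal(0, 1, 30), rng.normal(5, 1, 30))
        assert out["welch_p"] < 1e-3
        assert out["shapiro_p_a"] > 0.01

    def test_tiny_group_rejected(self):
        with pytest.raises(ValueError):
            compare_nef_groups([0.1, 0.2], [0.1, 0.2, 0.3])

    def test_constant_group_flagged(self):
        out = compare_nef_groups([0.5, 0.5, 0.5], [0.1, 0.4, 0.9])
        assert out["shapiro_p_a"] is None
        assert out["shapiro_flag_a"] == "constant"
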