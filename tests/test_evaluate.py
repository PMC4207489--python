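import numpy as np
import pytest

from oracles import brute_overlap_counts, brute_pr_curve
from racer.evaluate import (
    RankedInteractions,
    build_positive_set,
    expression_lasso_baseline,
    pcc_baseline,
    peak_score_baseline,
    precision_recall,
    rank_interactions,
    validated_overlap_curve,
)


class TestRankInteractions:
    def test_mirna_ranked_most_negative_first(self):
        theta = np.array([[-2.0, 3.0], [0.0, -1.0]])  # rows m1,m2; cols g1,g2
        mask = np.ones_like(theta, dtype=bool)
        ranked = rank_interactions(theta, mask, ["m1", "m2"], ["g1", "g2"], kind="miRNA")
        assert [(r, g) for r, g, _ in ranked.pairs] == [
            ("m1", "g1"), ("m2", "g2"), ("m1", "g2")
        ]

    def test_tf_ranked_by_magnitude(self):
        theta = np.array([[-5.0, 2.0]])
        mask = np.ones_like(theta, dtype=bool)
        ranked = rank_interactions(theta, mask, ["t1"], ["g1", "g2"], kind="TF")
        assert [g for _, g, _ in ranked.pairs] == ["g1", "g2"]

    def test_zero_scores_and_masked_pairs_excluded(self):
        theta = np.array([[0.0, -1.0]])
        mask = np.array([[True, False]])
        ranked = rank_interactions(theta, mask, ["m1"], ["g1", "g2"], kind="miRNA")
        assert len(ranked) == 0

    def test_ties_break_lexicographically_and_stably(self):
        theta = np.array([[-1.0, -1.0], [-1.0, 0.0]])
        mask = np.ones_like(theta, dtype=bool)
        r1 = rank_interactions(theta, mask, ["mB", "mA"], ["g2", "g1"], kind="miRNA")
        r2 = rank_interactions(theta, mask, ["mB", "mA"], ["g2", "g1"], kind="miRNA")
        assert r1.pairs == r2.pairs
        assert [(r, g) for r, g, _ in r1.pairs] == [
            ("mA", "g2"), ("mB", "g1"), ("mB", "g2")
        ]


class TestOverlapCurve:
    def test_enumerated_example(self):
        ranked = RankedInteractions(
            pairs=[("m", "a", -4.0), ("m", "c", -3.0), ("m", "b", -2.0), ("m", "d", -1.0)],
            direction="most_negative_first",
        )
        validated = {("m", "a"), ("m", "b")}
        counts = validated_overlap_curve(ranked, validated, ks=[2, 4])
        assert list(counts) == [1, 2]

    def test_empty_validated_set_gives_zeros(self):
        ranked = RankedInteractions([("m", "a", -1.0)], "most_negative_first")
        assert list(validated_overlap_curve(ranked, set(), ks=[1])) == [0]

    def test_validated_superset_counts_equal_ks(self):
        pairs = [("m", g, -float(i + 1)) for i, g in enumerate("abcd")]
        ranked = RankedInteractions(pairs, "most_negative_first")
        validated = {(r, g) for r, g, _ in pairs}
        assert list(validated_overlap_curve(ranked, validated, ks=[1, 2, 4])) == [1, 2, 4]

    def test_monotone_and_matches_bruteforce(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            n = int(rng.integers(3, 30))
            pairs = [("m", f"g{i}", float(-rng.random())) for i in range(n)]
            pairs.sort(key=lambda t: t[2])
            ranked = RankedInteractions(pairs, "most_negative_first")
            validated = {
                ("m", f"g{i}") for i in range(n) if rng.random() < 0.4
            }
            ks = sorted(set(rng.integers(1, n + 1, 4).tolist()))
            counts = validated_overlap_curve(ranked, validated, ks=ks)
            expected = brute_overlap_counts([(r, g) for r, g, _ in pairs], validated, ks)
            assert list(counts) == expected
            assert all(b >= a for a, b in zip(counts, counts[1:]))


class TestPrecisionRecall:
    def test_perfect_separation_gives_auc_one(self):
        scores = {"a": -3.0, "b": -2.0, "c": -1.0, "d": 0.0}
        curve = precision_recall(scores, {"a", "b"}, {"c", "d"})
        assert np.all(curve.precision[curve.recall > 0] <= 1.0)
        assert curve.auc == pytest.approx(1.0)

    def test_worked_four_item_case_matches_enumeration(self):
        # P = {a, b}, N = {c, d}, goodness a > c > b > d
        scores = {"a": -4.0, "c": -3.0, "b": -2.0, "d": -1.0}
        pos, neg = {"a", "b"}, {"c", "d"}
        curve = precision_recall(scores, pos, neg)
        points, auc = brute_pr_curve(scores, pos, neg)
        assert points == [(0.5, 1.0), (0.5, 0.5), (1.0, 2 / 3), (1.0, 0.5)]
        assert auc == pytest.approx(0.7916666666666666)
        assert curve.auc == pytest.approx(auc)

    def test_matches_bruteforce_on_small_instances_with_ties(self):
        rng = np.random.default_rng(8)
        for _ in range(40):
            n = int(rng.integers(2, 9))
            items = [f"i{k}" for k in range(n)]
            scores = {it: float(rng.integers(-3, 3)) for it in items}
            labels = rng.random(n) < 0.5
            if not labels.any() or labels.all():
                continue
            pos = {it for it, l in zip(items, labels) if l}
            neg = set(items) - pos
            for direction in ["most_negative_first", "largest_magnitude_first", "largest_first"]:
                curve = precision_recall(scores, pos, neg, direction=direction)
                _, auc = brute_pr_curve(scores, pos, neg, direction=direction)
                assert curve.auc == pytest.approx(auc, abs=1e-12)

    def test_random_scores_auc_near_prevalence(self):
        rng = np.random.default_rng(0)
        aucs = []
        for _ in range(50):
            items = [f"i{k}" for k in range(100)]
            scores = {it: float(rng.random()) for it in items}
            pos = set(items[:20])
            neg = set(items[20:])
            aucs.append(precision_recall(scores, pos, neg, direction="largest_first").auc)
        assert np.mean(aucs) == pytest.approx(0.2, abs=0.05)

    def test_empty_positives_is_error(self):
        with pytest.raises(ValueError):
            precision_recall({"a": 1.0}, set(), {"a"})


class TestBaselines:
    def test_pcc_perfect_anticorrelation_and_symmetry(self):
        x = np.array([[1.0, 2.0, 3.0, 4.0]])
        e = -x.copy()
        assert pcc_baseline(x, e)[0, 0] == pytest.approx(-1.0)
        rng = np.random.default_rng(1)
        A = rng.standard_normal((3, 10))
        B = rng.standard_normal((2, 10))
        assert np.allclose(pcc_baseline(A, B), pcc_baseline(B, A).T)

    def test_pcc_constant_row_flagged_zero(self):
        x = np.ones((1, 5))
        e = np.arange(5.0)[None, :]
        assert pcc_baseline(x, e)[0, 0] == 0.0

    def test_expression_lasso_zero_row_without_seed_sites(self, small_cohort):
        bundle, _ = small_cohort
        scores = expression_lasso_baseline(bundle, seed=0)
        for g in range(bundle.n_genes):
            if not (bundle.S[:, g] > 0).any():
                assert np.all(scores[:, g] == 0.0)

    def test_expression_lasso_deterministic(self, small_cohort):
        bundle, _ = small_cohort
        s1 = expression_lasso_baseline(bundle, seed=5)
        s2 = expression_lasso_baseline(bundle, seed=5)
        assert np.array_equal(s1, s2)

    def test_peak_score_ranking_matches_rank_interactions(self):
        rng = np.random.default_rng(2)
        B = np.where(rng.random((3, 6)) < 0.4, rng.random((3, 6)) * 10, 0.0)
        tfs = ["t1", "t2", "t3"]
        genes = [f"g{i}" for i in range(6)]
        ranked = peak_score_baseline(B, tfs, genes)
        via_rank = rank_interactions(B, B > 0, tfs, genes, kind="TF")
        assert ranked.pairs == via_rank.pairs
        scaled = peak_score_baseline(3.5 * B, tfs, genes)
        assert [(r, g) for r, g, _ in scaled.pairs] == [(r, g) for r, g, _ in ranked.pairs]


def test_build_positive_set_intersection():
    assert build_positive_set(["a", "b", "c"], ["b", "c", "d"]) == {"b", "c"}
    assert build_positive_set(["a"], ["b"]) == set()
    s = {"x", "y"}
    assert build_positive_set(s, s) == s
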