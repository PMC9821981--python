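"""Screening-power metrics: hand-derived values, brute-force and sklearn oracles."""

import itertools
import math

import numpy as np
import pytest
from sklearn.metrics import average_precision_score, roc_auc_score

from consensus_screen.benchmark import BenchmarkSet
from consensus_screen.metrics import (
    EvalConfig,
    HitList,
    bedroc,
    bootstrap_metric,
    confusion_at,
    enrichment_curve,
    enrichment_factor,
    evaluate_all,
    make_hit_list,
    pr_curve_auc,
    rie,
    roc_curve_auc,
)
from consensus_screen.score_io import ScoreTable


def hits_from(scores, labels):
    """HitList from higher-better scores and boolean labels."""
    ids = [f"m{i:03d}" for i in range(len(scores))]
    bench = BenchmarkSet({m: "active" if a else "decoy" for m, a in zip(ids, labels)})
    return make_hit_list(ScoreTable("p", "higher_better", dict(zip(ids, scores))), bench)


def hits_from_order(labels):
    """HitList whose order is exactly `labels` (True = active), no ties."""
    n = len(labels)
    return hits_from(list(range(n, 0, -1)), labels)


def brute_force_auc(scores, labels):
    """Pair counting: half credit when an active and a decoy tie."""
    actives = [s for s, a in zip(scores, labels) if a]
    decoys = [s for s, a in zip(scores, labels) if not a]
    total = 0.0
    for sa in actives:
        for sd in decoys:
            total += 1.0 if sa > sd else (0.5 if sa == sd else 0.0)
    return total / (len(actives) * len(decoys))


class TestConfusion:
    def test_printed_rate_formulas(self):
        hits = hits_from_order([True] * 5 + [False] * 5 + [True] * 5 + [False] * 5)
        counts, rates = confusion_at(hits, count=10)
        assert (counts.TP, counts.FN) == (5, 5)
        assert rates.TPR == 0.5

    def test_select_all_saturates(self):
        hits = hits_from_order([True, False, True, False])
        _, rates = confusion_at(hits, fraction=1.0)
        assert rates.TPR == 1.0 and rates.FPR == 1.0
        assert rates.TNR == 0.0

    def test_perfect_ranking_precision_one(self):
        hits = hits_from_order([True] * 3 + [False] * 7)
        counts, rates = confusion_at(hits, count=3)
        assert counts.TP == 3 and counts.FP == 0 and rates.PRE == 1.0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            confusion_at(hits_from_order([True, True]), fraction=0.5)


class TestEnrichmentFactor:
    def test_hand_arithmetic(self):
        labels = [True] * 5 + [False] * 5 + [True] * 5 + [False] * 85
        hits = hits_from_order(labels)
        assert enrichment_factor(hits, 0.10) == pytest.approx(5.0)

    def test_full_fraction_is_one(self):
        hits = hits_from_order([False, True] * 10)
        assert enrichment_factor(hits, 1.0) == pytest.approx(1.0)

    def test_perfect_ranking_maximal(self):
        n, N = 10, 100
        hits = hits_from_order([True] * n + [False] * (N - n))
        assert enrichment_factor(hits, n / N) == pytest.approx(N / n)

    def test_bounds_over_random_rankings(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            N = int(rng.integers(10, 80))
            n = int(rng.integers(1, N))
            labels = np.zeros(N, bool)
            labels[rng.choice(N, n, replace=False)] = True
            chi = float(rng.uniform(0.01, 1.0))
            ef = enrichment_factor(hits_from_order(labels.tolist()), chi)
            assert 0 <= ef <= min(1 / chi, N / n) + 1e-9

    def test_enrichment_curve_endpoints(self):
        hits = hits_from_order([True] * 3 + [False] * 27)
        curve = enrichment_curve(hits)
        assert curve.points[-1, 0] == pytest.approx(100.0)
        assert curve.points[-1, 1] == pytest.approx(100.0)
        assert np.all((0 <= curve.points[:, 1]) & (curve.points[:, 1] <= 100))


class TestRocAuc:
    def test_perfect_ranking(self):
        assert roc_curve_auc(hits_from_order([True] * 3 + [False] * 5)).area == 1.0

    def test_interleaved_three_quarters(self):
        assert roc_curve_auc(hits_from_order([True, False, True, False])).area == pytest.approx(0.75)

    def test_reversal_symmetry(self):
        rng = np.random.default_rng(9)
        scores = rng.normal(size=30)
        labels = rng.random(30) < 0.3
        if not (labels.any() and (~labels).any()):
            labels[0], labels[1] = True, False
        a = roc_curve_auc(hits_from(scores, labels)).area
        b = roc_curve_auc(hits_from((-scores), labels)).area
        assert a + b == pytest.approx(1.0)

    def test_exhaustive_brute_force_with_ties(self):
        """Tie-aware AUC equals pair counting for every labeling, N <= 10."""
        rng = np.random.default_rng(2)
        for N in (2, 5, 8, 10):
            scores = np.round(rng.normal(size=N), 0)  # coarse rounding forces ties
            for pattern in itertools.product([False, True], repeat=N):
                if not (any(pattern) and not all(pattern)):
                    continue
                hits = hits_from(scores.tolist(), list(pattern))
                assert roc_curve_auc(hits).area == pytest.approx(
                    brute_force_auc(scores.tolist(), list(pattern))
                )

    def test_matches_sklearn(self):
        rng = np.random.default_rng(23)
        scores = np.round(rng.normal(size=200), 1)
        labels = rng.random(200) < 0.2
        hits = hits_from(scores.tolist(), labels.tolist())
        assert roc_curve_auc(hits).area == pytest.approx(roc_auc_score(labels, scores))

    def test_curve_trapezoid_equals_pair_count(self):
        rng = np.random.default_rng(31)
        scores = np.round(rng.normal(size=60), 0)
        labels = (rng.random(60) < 0.3).tolist()
        labels[0], labels[1] = True, False
        curve = roc_curve_auc(hits_from(scores.tolist(), labels))
        trapezoid = np.trapezoid(curve.points[:, 1], curve.points[:, 0])
        assert curve.area == pytest.approx(trapezoid)
        assert tuple(curve.points[0]) == (0.0, 0.0)
        assert tuple(curve.points[-1]) == (1.0, 1.0)


class TestPrAuc:
    def test_perfect_ranking(self):
        assert pr_curve_auc(hits_from_order([True] * 4 + [False] * 6)).area == pytest.approx(1.0)

    def test_single_active_ranked_last(self):
        N = 20
        assert pr_curve_auc(hits_from_order([False] * (N - 1) + [True])).area == pytest.approx(1 / N)

    def test_matches_sklearn_average_precision(self):
        rng = np.random.default_rng(41)
        scores = rng.normal(size=150)  # unique scores: AP definitions coincide
        labels = rng.random(150) < 0.25
        hits = hits_from(scores.tolist(), labels.tolist())
        assert pr_curve_auc(hits).area == pytest.approx(average_precision_score(labels, scores))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            pr_curve_auc(hits_from_order([True, True, True]))


class TestRieBedroc:
    def test_single_active_rank_one_closed_form(self):
        N, alpha = 100, 20.0
        hits = hits_from_order([True] + [False] * (N - 1))
        denom = (1 / N) * (1 - math.exp(-alpha)) / (math.exp(alpha / N) - 1)
        assert rie(hits, alpha) == pytest.approx(math.exp(-0.2) / denom)

    def test_random_mean_is_one_monte_carlo(self):
        """Closed-form denominator vs 10,000-shuffle simulation oracle."""
        rng = np.random.default_rng(77)
        N, n, alpha, B = 50, 10, 20.0, 10_000
        base = np.array([True] * n + [False] * (N - n))
        vals = np.empty(B)
        for b in range(B):
            vals[b] = rie(hits_from_order(rng.permutation(base).tolist()), alpha)
        se = vals.std(ddof=1) / math.sqrt(B)
        assert abs(vals.mean() - 1.0) < 3 * se

    def test_alpha_to_zero_limit(self):
        rng = np.random.default_rng(3)
        labels = rng.permutation([True] * 5 + [False] * 45).tolist()
        assert rie(hits_from_order(labels), alpha=1e-6) == pytest.approx(1.0, abs=1e-4)

    def test_bedroc_endpoints(self):
        n, N = 4, 40
        perfect = hits_from_order([True] * n + [False] * (N - n))
        inverted = hits_from_order([False] * (N - n) + [True] * n)
        assert bedroc(perfect) == pytest.approx(1.0)
        assert bedroc(inverted) == pytest.approx(0.0)

    def test_bedroc_bounds_random(self):
        rng = np.random.default_rng(13)
        for _ in range(50):
            labels = (rng.random(30) < 0.3).tolist()
            if not (any(labels) and not all(labels)):
                continue
            assert 0.0 <= bedroc(hits_from_order(labels)) <= 1.0

    def test_adjacent_swap_monotonicity(self):
        """Promoting an active past a decoy never decreases AUC, RIE or BEDROC."""
        rng = np.random.default_rng(19)
        labels = rng.permutation([True] * 6 + [False] * 24).tolist()
        for i in range(len(labels) - 1):
            if not labels[i] and labels[i + 1]:
                swapped = labels.copy()
                swapped[i], swapped[i + 1] = swapped[i + 1], swapped[i]
                before, after = hits_from_order(labels), hits_from_order(swapped)
                assert roc_curve_auc(after).area >= roc_curve_auc(before).area
                assert rie(after) >= rie(before)
                assert bedroc(after) >= bedroc(before)


class TestRandomCalibration:
    def test_auc_and_rie_random_baselines(self):
        """Over 1000 seeded shuffles: mean AUC ~ 0.5, mean RIE ~ 1 (3 SE)."""
        rng = np.random.default_rng(101)
        N, n, B = 200, 20, 1000
        base = np.array([True] * n + [False] * (N - n))
        aucs = np.empty(B)
        ries = np.empty(B)
        for b in range(B):
            hits = hits_from_order(rng.permutation(base).tolist())
            aucs[b] = roc_curve_auc(hits).area
            ries[b] = rie(hits)
        assert abs(aucs.mean() - 0.5) < 3 * aucs.std(ddof=1) / math.sqrt(B)
        assert abs(ries.mean() - 1.0) < 3 * ries.std(ddof=1) / math.sqrt(B)


class TestBootstrap:
    def make_hits(self, seed=55, N=120, n=20):
        rng = np.random.default_rng(seed)
        labels = np.zeros(N, bool)
        labels[:n] = True
        scores = rng.normal(size=N) + labels  # signal
        return hits_from(scores.tolist(), labels.tolist())

    def test_determinism(self):
        hits = self.make_hits()
        a = bootstrap_metric(hits, "roc_auc", B=200, seed=42)
        b = bootstrap_metric(hits, "roc_auc", B=200, seed=42)
        assert a == b

    def test_constant_statistic_has_zero_sd(self):
        hits = self.make_hits()
        summary = bootstrap_metric(hits, "ef", B=100, seed=1, fraction=1.0)
        assert summary.point == pytest.approx(1.0)
        assert summary.sd == 0.0

    def test_default_B_is_1000(self):
        hits = self.make_hits(N=40, n=8)
        summary = bootstrap_metric(hits, "roc_auc", seed=3)
        assert summary.B == 1000

    def test_ci_contains_mean_and_point_reasonable(self):
        hits = self.make_hits()
        s = bootstrap_metric(hits, "bedroc", B=300, seed=7, alpha=20.0)
        assert s.ci_low <= s.mean <= s.ci_high
        assert s.sd >= 0

    def test_unknown_metric_rejected(self):
        with pytest.raises(ValueError, match="unknown metric"):
            bootstrap_metric(self.make_hits(), "nope")

    def test_sd_shrinks_as_inverse_sqrt_n(self):
        """Bootstrap SD of AUC ~ N^(-1/2) at fixed class balance (log-log slope)."""
        sds = []
        sizes = [200, 400, 800, 1600, 3200]
        for N in sizes:
            n = N // 10
            rng = np.random.default_rng(N)
            labels = np.zeros(N, bool)
            labels[:n] = True
            scores = rng.normal(size=N) + labels
            hits = hits_from(scores.tolist(), labels.tolist())
            sds.append(bootstrap_metric(hits, "roc_auc", B=400, seed=9).sd)
        slope = np.polyfit(np.log(sizes), np.log(sds), 1)[0]
        assert slope == pytest.approx(-0.5, abs=0.1)


class TestEvaluateAll:
    def make_sources(self, identical=False):
        rng = np.random.default_rng(61)
        N, n = 80, 12
        ids = [f"m{i:03d}" for i in range(N)]
        labels = {m: "active" if i < n else "decoy" for i, m in enumerate(ids)}
        bench = BenchmarkSet(labels)
        s1 = rng.normal(size=N) + np.array([i < n for i in range(N)])
        s2 = s1 if identical else rng.normal(size=N) + np.array([i < n for i in range(N)])
        t1 = ScoreTable("p1", "higher_better", dict(zip(ids, s1)))
        t2 = ScoreTable("p2", "higher_better", dict(zip(ids, s2)))
        return bench, t1, t2

    def test_perfect_ranking_all_ones(self):
        hits = hits_from_order([True] * 5 + [False] * 45)
        report = evaluate_all({"perfect": hits}, bench_of(hits), EvalConfig(bootstrap_samples=50))
        assert report.value("perfect", "ROC-AUC") == 1.0
        assert report.value("perfect", "PR-AUC") == 1.0
        assert report.value("perfect", "BEDROC(20)") == pytest.approx(1.0)
        assert report.value("perfect", "EF10%") == pytest.approx(10.0)

    def test_identical_programs_match_consensus_rbr(self):
        from consensus_screen.benchmark import align_programs
        from consensus_screen.consensus import rank_by_rank

        bench, t1, t2 = self.make_sources(identical=True)
        aligned = align_programs([t1, t2], bench)
        rbr = rank_by_rank(aligned)
        cfg = EvalConfig(bootstrap_samples=50)
        report = evaluate_all({"p1": t1, "RBR": rbr}, bench, cfg)
        for metric in ("ROC-AUC", "PR-AUC", "BEDROC(20)"):
            assert report.value("RBR", metric) == pytest.approx(report.value("p1", metric))

    def test_regeneration_is_identical(self):
        bench, t1, t2 = self.make_sources()
        cfg = EvalConfig(bootstrap_samples=100, seed=5)
        r1 = evaluate_all({"p1": t1, "p2": t2}, bench, cfg)
        r2 = evaluate_all({"p1": t1, "p2": t2}, bench, cfg)
        assert r1.table.equals(r2.table)

    def test_source_order_does_not_matter(self):
        bench, t1, t2 = self.make_sources()
        cfg = EvalConfig(bootstrap_samples=100, seed=5)
        r1 = evaluate_all({"p1": t1, "p2": t2}, bench, cfg)
        r2 = evaluate_all({"p2": t2, "p1": t1}, bench, cfg)
        assert r1.table.equals(r2.table.sort_values(["method", "metric"], kind="stable").reset_index(drop=True))


def bench_of(hits):
    """Benchmark reconstructed from a HitList (helper for direct-HitList tests)."""
    return BenchmarkSet(
        {m: "active" if a else "decoy" for m, a in zip(hits.ids, hits.labels)}
    )
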