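"""Tanimoto k-NN applicability domain, Dc threshold, leverage, curves."""

import numpy as np
import pytest

from tkqsar.admodel import (
    ADScore,
    DcMode,
    FingerprintSet,
    coverage_performance_curve,
    dc_threshold,
    knn_ad_score,
    leverage_ad,
    morgan_fingerprints,
    score_set,
    tanimoto,
)
from tkqsar.chemreg import standardize_structure
from tkqsar.errors import (
    LengthMismatchError,
    SingularMatrixError,
    TrainTooSmallError,
)


def bits(on, n=16):
    v = np.zeros(n, dtype=np.uint8)
    v[list(on)] = 1
    return v


class TestTanimoto:
    def test_identical_vectors(self):
        assert tanimoto(bits({1, 5}), bits({1, 5})) == 1.0

    def test_set_arithmetic(self):
        assert tanimoto(bits({1, 2, 3}), bits({2, 3, 4})) == 0.5

    def test_disjoint_vectors(self):
        assert tanimoto(bits({1}), bits({2})) == 0.0

    def test_both_empty_defined_as_zero(self):
        assert tanimoto(bits(set()), bits(set())) == 0.0

    def test_length_mismatch_raises(self):
        with pytest.raises(LengthMismatchError):
            tanimoto(bits({1}, 8), bits({1}, 16))


class TestKnnScore:
    def fpset(self, rows):
        return FingerprintSet(tuple(f"t{i}" for i in range(len(rows))),
                              np.vstack(rows), radius=2, n_bits=16)

    def test_identical_training_members_give_mean_one(self):
        train = self.fpset([bits({1, 2})] * 4)
        s = knn_ad_score(bits({1, 2}), train, k=3)
        assert s.mean_knn_tanimoto == 1.0

    def test_three_copies_half_similar(self):
        train = self.fpset([bits({2, 3, 4})] * 3)
        s = knn_ad_score(bits({1, 2, 3}), train, k=3)
        assert s.mean_knn_tanimoto == pytest.approx(0.5)

    def test_train_too_small(self):
        with pytest.raises(TrainTooSmallError):
            knn_ad_score(bits({1}), self.fpset([bits({1})]), k=3)

    def test_neighbors_sorted_descending_mean_consistent(self):
        train = self.fpset([bits({1, 2, 3}), bits({1, 2}), bits({9}),
                            bits({1, 2, 3, 4})])
        s = knn_ad_score(bits({1, 2, 3}), train, k=3)
        sims = [v for _, v in s.neighbors]
        assert sims == sorted(sims, reverse=True)
        assert s.mean_knn_tanimoto == pytest.approx(np.mean(sims))

    def test_matches_bruteforce_scan(self, small_library):
        records, _ = small_library
        train = morgan_fingerprints(records[:40])
        queries = morgan_fingerprints(records[40:])
        for qi in range(len(queries.ids)):
            s = knn_ad_score(queries.bits[qi], train, k=3)
            sims = sorted(
                (tanimoto(queries.bits[qi], train.bits[ti]), train.ids[ti])
                for ti in range(40))
            expected = np.mean([v for v, _ in sims[-3:]])
            assert s.mean_knn_tanimoto == pytest.approx(expected)

    def test_fingerprints_deterministic(self, small_library):
        records, _ = small_library
        a = morgan_fingerprints(records[:10])
        b = morgan_fingerprints(records[:10])
        assert np.array_equal(a.bits, b.bits)


class TestDcThreshold:
    def test_minus_mode_study_statistics(self):
        # a score list constructed to have mean 0.42 and population sd 0.156
        scores = [0.42 - 0.156, 0.42 + 0.156]
        assert round(dc_threshold(scores, z=0.5, mode=DcMode.MINUS), 2) == 0.34

    def test_zero_sigma_returns_mean(self):
        assert dc_threshold([0.4, 0.4, 0.4]) == pytest.approx(0.4)

    def test_plus_mode(self):
        scores = [0.35 - 0.14, 0.35 + 0.14]
        assert dc_threshold(scores, z=0.5, mode=DcMode.PLUS) == pytest.approx(0.42)


class TestCoverageCurve:
    def make_scores(self, sims):
        return [ADScore(f"q{i}", s, ()) for i, s in enumerate(sims)]

    def test_threshold_zero_full_coverage_global_metric(self):
        scores = self.make_scores([0.2, 0.5, 0.9])
        y = [1.0, 2.0, 3.0]
        p = [1.0, 2.0, 4.0]
        rows = coverage_performance_curve(
            scores, y, p, lambda a, b: float(np.mean(np.abs(a - b))), [0.0])
        assert rows[0]["coverage"] == 1.0
        assert rows[0]["metric"] == pytest.approx(1 / 3)

    def test_threshold_above_all_scores_empty(self):
        scores = self.make_scores([0.2, 0.5])
        rows = coverage_performance_curve(
            scores, [1, 2], [1, 2], lambda a, b: 0.0, [0.99])
        assert rows[0]["coverage"] == 0.0 and rows[0]["metric"] is None

    def test_coverage_non_increasing_and_error_shrinks_with_similarity(self):
        rng = np.random.default_rng(8)
        sims = rng.uniform(0, 1, 200)
        y = np.full(200, 10.0)
        p = y + (1 - sims) * rng.normal(1.0, 0.05, 200)  # error ∝ 1 - similarity
        scores = self.make_scores(sims)
        mae_fn = lambda a, b: float(np.mean(np.abs(a - b)))
        rows = coverage_performance_curve(scores, y, p, mae_fn,
                                          np.linspace(0, 1, 50))
        cov = [r["coverage"] for r in rows]
        assert all(a >= b for a, b in zip(cov, cov[1:]))
        dense = [r["metric"] for r in rows if r["coverage"] > 0.2]
        assert dense[-1] < dense[0]


class TestLeverage:
    def test_centroid_query_has_minimal_leverage(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(50, 3))
        x -= x.mean(axis=0)
        h, _ = leverage_ad(x, x.mean(axis=0))
        assert h[0] == pytest.approx(1 / 50)

    def test_far_query_exceeds_warning_threshold(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(40, 3))
        far = np.array([10 * np.max(np.abs(x)), 0.0, 0.0])
        h, h_star = leverage_ad(x, far)
        assert h[0] > h_star
        # agree with the direct matrix computation
        x1 = np.hstack([np.ones((40, 1)), x])
        q1 = np.concatenate([[1.0], far])
        direct = q1 @ np.linalg.inv(x1.T @ x1) @ q1
        assert h[0] == pytest.approx(direct)

    def test_rank_deficient_design_raises(self):
        x = np.ones((10, 2))
        x[:, 1] = 2.0
        with pytest.raises(SingularMatrixError):
            leverage_ad(x, np.array([1.0, 2.0]))
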