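import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.exceptions import NotFittedError
from sklearn.linear_model import LogisticRegression

from twincross import benchmarks, learning
from twincross.thresholds import (
    COARSE_HIGH,
    COARSE_LOW,
    DegeneratePartitionError,
    NoFeasiblePairError,
    ScoredPool,
    ThresholdPair,
    partition_by_thresholds,
    score_patches,
    search_thresholds,
    evaluate_threshold_pair,
)


class TestThresholdPair:
    def test_valid(self):
        ThresholdPair(0.2, 0.9)

    @pytest.mark.parametrize("lo, hi", [(0.5, 0.5), (0.9, 0.2), (-0.1, 0.5),
                                        (0.2, 1.1)])
    def test_invalid(self, lo, hi):
        with pytest.raises(ValueError):
            ThresholdPair(lo, hi)


class TestScorePatches:
    def test_constant_scorer(self):
        class Constant:
            def predict_proba(self, X):
                return np.tile([0.5, 0.5], (len(X), 1))

        scores = score_patches(Constant(), np.zeros((7, 3)))
        assert np.allclose(scores, 0.5)

    def test_unfitted_scorer_raises(self):
        with pytest.raises(NotFittedError):
            score_patches(LogisticRegression(), np.zeros((3, 2)))

    def test_reordering_permutes_scores(self, rng):
        X = rng.random((20, 3))
        y = (rng.random(20) < 0.5).astype(int)
        y[:2] = [0, 1]
        clf = LogisticRegression().fit(X, y)
        perm = rng.permutation(20)
        assert np.allclose(score_patches(clf, X)[perm],
                           score_patches(clf, X[perm]))

    def test_separable_channel_scores_rank_well(
        self, high_contrast_ds, high_contrast_feats
    ):
        from twincross.metrics import roc_auc

        ds, feats = high_contrast_ds, high_contrast_feats
        tr = np.flatnonzero(ds.split == "train")
        te = np.flatnonzero(ds.split == "test")
        clf = LogisticRegression(max_iter=500).fit(
            feats.X_plus[tr], ds.labels[tr]
        )
        auc, _ = roc_auc(score_patches(clf, feats.X_plus[te]), ds.labels[te])
        assert auc >= 0.9


class TestPartition:
    def test_reference_assignment(self):
        # the averaged retrieval pair from the published 8-round search
        part = partition_by_thresholds(
            np.array([0.10, 0.50, 0.99]), ThresholdPair(0.4827, 0.9729)
        )
        assert part.ns.tolist() == [0]
        assert part.uncertain.tolist() == [1]
        assert part.rp.tolist() == [2]

    def test_boundary_semantics(self):
        scores = np.array([0.0, 0.3, 0.6, 1.0])
        part = partition_by_thresholds(scores, ThresholdPair(0.0, 1.0))
        assert part.ns.tolist() == [0]  # only s == 0 at t_low = 0
        assert part.rp.tolist() == [3]  # only s == 1 at t_high = 1
        assert part.uncertain.tolist() == [1, 2]

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=50),
           st.floats(0.0, 0.49), st.floats(0.51, 1.0))
    @settings(max_examples=200, deadline=None)
    def test_exhaustive_and_disjoint_property(self, scores, lo, hi):
        scores = np.array(scores)
        part = partition_by_thresholds(scores, ThresholdPair(lo, hi))
        ids = np.concatenate([part.rp, part.ns, part.uncertain])
        assert len(ids) == len(scores)
        assert len(np.unique(ids)) == len(scores)

    def test_monotonicity(self, rng):
        scores = rng.random(300)
        lows = np.linspace(0.0, 0.45, 10)
        highs = np.linspace(0.55, 1.0, 10)
        ns_sizes = [len(partition_by_thresholds(scores, ThresholdPair(lo, 0.5)).ns)
                    for lo in lows]
        rp_sizes = [len(partition_by_thresholds(scores, ThresholdPair(0.5, hi)).rp)
                    for hi in highs]
        assert all(a <= b for a, b in zip(ns_sizes, ns_sizes[1:]))  # raising t_low grows NS
        assert all(a >= b for a, b in zip(rp_sizes, rp_sizes[1:]))  # raising t_high shrinks RP


class TestEvaluatePair:
    @pytest.fixture(scope="class")
    def pool(self):
        return benchmarks.beta_mixture_pool(n_per_class=300, n_val=150, seed=2)

    def test_good_pair_scores_high(self, pool):
        f1 = evaluate_threshold_pair(
            ThresholdPair(0.3, 0.7), pool, learning.binary_logistic_factory()
        )
        assert f1 >= 0.9

    def test_degenerate_pair_rejected(self, pool):
        hi = float(pool.scores.max())
        if hi >= 1.0:  # pragma: no cover - beta draws never reach 1 exactly
            pytest.skip("scores reach the top of the range")
        with pytest.raises(DegeneratePartitionError):
            evaluate_threshold_pair(
                ThresholdPair(0.1, min(1.0, hi + 1e-6)), pool,
                learning.binary_logistic_factory(),
            )

    def test_deterministic_given_seed(self, pool):
        args = (ThresholdPair(0.25, 0.75), pool,
                learning.binary_logistic_factory())
        assert evaluate_threshold_pair(*args, seed=9) == evaluate_threshold_pair(
            *args, seed=9
        )


def exhaustive_coarse_best(pool, factory, seed):
    """Independent oracle: enumerate every feasible coarse grid pair."""
    best, best_f1 = None, -np.inf
    for lo, hi in itertools.product(COARSE_LOW, COARSE_HIGH):
        if lo >= hi:
            continue
        pair = ThresholdPair(lo, hi)
        try:
            f1 = evaluate_threshold_pair(pair, pool, factory, seed=seed)
        except DegeneratePartitionError:
            continue
        if f1 > best_f1:
            best, best_f1 = pair, f1
    return best, best_f1


class TestSearch:
    def test_parameter_recovery_on_beta_mixture(self):
        pool = benchmarks.beta_mixture_pool(n_per_class=1000, n_val=500, seed=1)
        pair, trace = search_thresholds(
            pool, learning.binary_logistic_factory(), rounds=3, seed=5
        )
        f1 = evaluate_threshold_pair(
            pair, pool, learning.binary_logistic_factory(), seed=123
        )
        assert f1 >= 0.95

    def test_trace_length_and_monotone_best(self):
        pool = benchmarks.beta_mixture_pool(n_per_class=200, n_val=100, seed=3)
        _, trace = search_thresholds(
            pool, learning.binary_logistic_factory(), rounds=4, seed=2
        )
        assert len(trace.rounds) == 4
        perfs = [r["performance"] for r in trace.rounds]
        assert all(a <= b for a, b in zip(perfs, perfs[1:]))

    def test_coarse_stage_matches_exhaustive_oracle(self):
        # <= 200 patches, deterministic backbone: the search's coarse stage
        # must agree with brute-force enumeration of the 0.1 grid
        pool = benchmarks.beta_mixture_pool(n_per_class=100, n_val=80, seed=7)
        factory = learning.binary_logistic_factory()
        pair, trace = search_thresholds(
            pool, factory, rounds=1, fine_window=0.0, fine_step=1.0, seed=0
        )
        from twincross.seeding import subseed

        oracle_pair, oracle_f1 = exhaustive_coarse_best(
            pool, factory, seed=subseed(0, "threshold-search", 1)
        )
        assert trace.rounds[0]["performance"] == pytest.approx(oracle_f1)
        assert (pair.t_low, pair.t_high) == (oracle_pair.t_low, oracle_pair.t_high)

    def test_identical_scores_no_feasible_pair(self):
        pool = ScoredPool(
            X=np.zeros((20, 1)),
            scores=np.full(20, 0.5),
            X_val=np.zeros((4, 1)),
            y_val=np.array([0, 1, 0, 1]),
        )
        with pytest.raises(NoFeasiblePairError):
            search_thresholds(pool, learning.binary_logistic_factory(), rounds=1)

    def test_average_of_rounds_matches_incumbent_when_stationary(self):
        # deterministic backbone + stationary scores: every round retrieves
        # the same pair, so the AVG row equals the incumbent exactly
        pool = benchmarks.beta_mixture_pool(n_per_class=200, n_val=100, seed=9)
        pair, trace = search_thresholds(
            pool, learning.binary_logistic_factory(), rounds=8, seed=4
        )
        avg = trace.averaged_pair()
        assert abs(avg.t_low - pair.t_low) <= 0.001
        assert abs(avg.t_high - pair.t_high) <= 0.001

    def test_search_log_csv(self, tmp_path):
        pool = benchmarks.beta_mixture_pool(n_per_class=100, n_val=50, seed=8)
        _, trace = search_thresholds(
            pool, learning.binary_logistic_factory(), rounds=2, seed=1
        )
        path = tmp_path / "log.csv"
        trace.write_csv(path)
        lines = path.read_text().strip().splitlines()
        assert lines[0].startswith("round,")
        assert len(lines) == 4  # header + 2 rounds + AVG
        assert lines[-1].startswith("AVG")


class TestRpPurityUnderNoise:
    def test_rp_purer_than_unfiltered_positives(self):
        # the high-score RP set should contain a larger fraction of true
        # positives than the raw noisy positive labels do
        from sklearn.linear_model import LogisticRegression

        from twincross.features import feature_matrix

        wins = 0
        for seed in range(10):
            ds = benchmarks.separable_channel(
                60, 60, seed=seed, label_noise_rate=0.2
            )
            X = feature_matrix(ds.patches)
            tr = np.flatnonzero(ds.split == "train")
            clf = LogisticRegression(max_iter=500).fit(
                X[tr], ds.noisy_labels[tr]
            )
            scores = score_patches(clf, X[tr])
            part = partition_by_thresholds(scores, ThresholdPair(0.3, 0.8))
            if len(part.rp) == 0:
                continue
            rp_purity = ds.labels[tr][part.rp].mean()
            raw_purity = ds.labels[tr][ds.noisy_labels[tr] == 1].mean()
            wins += rp_purity > raw_purity
        assert wins >= 8
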