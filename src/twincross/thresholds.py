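"""Double-threshold sample selection and its coarse-to-fine search.

Scored patches are split by a ``(t_low, t_high)`` pair into negative
samples (NS, score <= t_low), reliable positives (RP, score >= t_high) and
an uncertain remainder.  The search tunes the pair round by round: a
coarse grid (step 0.1, t_low over [0, 0.5], t_high over [0.5, 1]) followed
by a fine coordinate scan (step 0.001 in a +/-0.05 window around the round
best, one threshold at a time).  A candidate replaces the incumbent only
when its reward — the scaled performance difference — is positive.

Evaluating a pair means training a backbone on RP (positives) versus NS
(negatives) and measuring F1 on a held-out validation split, so the
search is reward-guided rather than a pure enumeration.  Because the NS/RP
sets are order statistics of the scores, evaluations are cached by set
sizes; the fine scan touches only a few dozen distinct partitions.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from twincross.metrics import confusion_metrics
from twincross.seeding import subseed

COARSE_LOW = tuple(np.round(np.arange(0.0, 0.5001, 0.1), 3))
COARSE_HIGH = tuple(np.round(np.arange(0.5, 1.0001, 0.1), 3))
FINE_STEP = 0.001
FINE_WINDOW = 0.05


class DegeneratePartitionError(ValueError):
    """A threshold pair yields an empty RP or NS set."""


class NoFeasiblePairError(RuntimeError):
    """No grid pair produces a trainable partition."""


@dataclass(frozen=True)
class ThresholdPair:
    t_low: float
    t_high: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.t_low < self.t_high <= 1.0):
            raise ValueError(
                f"need 0 <= t_low < t_high <= 1, got "
                f"({self.t_low}, {self.t_high})"
            )


@dataclass(frozen=True)
class PatchPartition:
    """Disjoint, exhaustive RP / NS / uncertain index sets."""

    rp: np.ndarray
    ns: np.ndarray
    uncertain: np.ndarray

    @property
    def sizes(self) -> tuple[int, int, int]:
        return len(self.rp), len(self.ns), len(self.uncertain)


@dataclass
class SearchTrace:
    """Per-round search log; best-so-far performance is non-decreasing."""

    rounds: list[dict] = field(default_factory=list)
    incumbent: ThresholdPair | None = None

    def add(self, idx: int, best_f1: float, pair: ThresholdPair) -> None:
        self.rounds.append(
            {
                "round": idx,
                "performance": best_f1,
                "t_low": pair.t_low,
                "t_high": pair.t_high,
            }
        )

    def averaged_pair(self) -> ThresholdPair:
        """Mean of the per-round retrieved thresholds (the AVG row)."""
        if not self.rounds:
            raise ValueError("empty trace")
        return ThresholdPair(
            t_low=float(np.mean([r["t_low"] for r in self.rounds])),
            t_high=float(np.mean([r["t_high"] for r in self.rounds])),
        )

    def write_csv(self, path: str | Path) -> None:
        """Search log shaped like the per-round retrieval tables."""
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(
                ["round", "performance", "low_threshold", "high_threshold"]
            )
            for row in self.rounds:
                writer.writerow(
                    [row["round"], row["performance"], row["t_low"],
                     row["t_high"]]
                )
            avg = self.averaged_pair()
            writer.writerow(["AVG", "/", avg.t_low, avg.t_high])


@dataclass(frozen=True)
class ScoredPool:
    """Inputs to pair evaluation: scored training pool + labeled validation."""

    X: np.ndarray  # (n, d) features of the unlabeled/scored pool
    scores: np.ndarray  # (n,) in [0, 1]
    X_val: np.ndarray
    y_val: np.ndarray  # true binary labels of the validation split

    def __post_init__(self) -> None:
        if len(self.X) != len(self.scores):
            raise ValueError("X and scores must have equal length")
        if len(self.X_val) != len(self.y_val):
            raise ValueError("X_val and y_val must have equal length")


def score_patches(scorer, X: np.ndarray) -> np.ndarray:
    """Per-patch lesion scores in [0, 1] from a fitted probabilistic scorer.

    The scorer must expose ``predict_proba`` with the positive class last
    (sklearn convention).  An unfitted scorer raises sklearn's
    ``NotFittedError``.  Scores are a per-patch function: reordering the
    rows of ``X`` permutes the output identically.
    """
    proba = scorer.predict_proba(np.asarray(X))
    return np.clip(proba[:, -1], 0.0, 1.0)


def partition_by_thresholds(
    scores: np.ndarray, pair: ThresholdPair
) -> PatchPartition:
    """NS = {s <= t_low}; RP = {s >= t_high}; uncertain = the rest."""
    scores = np.asarray(scores, dtype=float)
    ns = np.flatnonzero(scores <= pair.t_low)
    rp = np.flatnonzero(scores >= pair.t_high)
    uncertain = np.flatnonzero(
        (scores > pair.t_low) & (scores < pair.t_high)
    )
    return PatchPartition(rp=rp, ns=ns, uncertain=uncertain)


def evaluate_threshold_pair(
    pair: ThresholdPair,
    pool: ScoredPool,
    backbone_factory,
    seed: int = 0,
) -> float:
    """Train a backbone on the RP/NS split and return validation F1.

    ``backbone_factory(seed)`` must return an object with ``fit(X, y)``
    and ``predict(X)``.  Deterministic given the seed.
    """
    part = partition_by_thresholds(pool.scores, pair)
    if len(part.rp) == 0 or len(part.ns) == 0:
        raise DegeneratePartitionError(
            f"degenerate partition for pair ({pair.t_low}, {pair.t_high}): "
            f"|RP|={len(part.rp)}, |NS|={len(part.ns)}"
        )
    X_train = np.vstack([pool.X[part.rp], pool.X[part.ns]])
    y_train = np.r_[np.ones(len(part.rp)), np.zeros(len(part.ns))]
    backbone = backbone_factory(seed)
    backbone.fit(X_train, y_train.astype(int))
    preds = np.asarray(backbone.predict(pool.X_val), dtype=int)
    return confusion_metrics(preds, pool.y_val).f_measure


def _snap(value: float) -> float:
    # keep grid coordinates on exact millesimal ticks
    return float(np.round(value, 3))


def search_thresholds(
    pool: ScoredPool,
    backbone_factory,
    rounds: int = 8,
    init: tuple[float, float] = (0.5, 0.8),
    fine_step: float = FINE_STEP,
    fine_window: float = FINE_WINDOW,
    alpha: float = 100.0,
    seed: int = 0,
) -> tuple[ThresholdPair, SearchTrace]:
    """Coarse-to-fine double-threshold search.

    Per round: exhaustive coarse grid, then a fine coordinate scan around
    the coarse winner (first t_low, then t_high).  The incumbent is
    replaced only when the reward ``alpha * (F1_candidate - F1_incumbent)``
    is positive.  Backbone fits within a round share a per-round sub-seed,
    so a stochastic backbone makes rounds genuinely different draws.
    """
    if rounds < 1:
        raise ValueError("rounds must be >= 1")
    n_scores = np.asarray(pool.scores, dtype=float)

    trace = SearchTrace()
    incumbent: ThresholdPair | None = None
    incumbent_f1 = -np.inf
    best_so_far = -np.inf

    for rnd in range(1, rounds + 1):
        round_seed = subseed(seed, "threshold-search", rnd)
        cache: dict[tuple[int, int], float] = {}

        def evaluate(pair: ThresholdPair) -> float | None:
            key = (
                int(np.sum(n_scores <= pair.t_low)),
                int(np.sum(n_scores >= pair.t_high)),
            )
            if key[0] == 0 or key[1] == 0:
                return None
            if key not in cache:
                cache[key] = evaluate_threshold_pair(
                    pair, pool, backbone_factory, seed=round_seed
                )
            return cache[key]

        # stage 1: coarse grid
        best_pair = None
        best_f1 = -np.inf
        if incumbent is not None:
            f1 = evaluate(incumbent)
            if f1 is not None:
                best_pair, best_f1 = incumbent, f1
        for lo in COARSE_LOW:
            for hi in COARSE_HIGH:
                if lo >= hi:
                    continue
                f1 = evaluate(ThresholdPair(lo, hi))
                if f1 is not None and f1 > best_f1:
                    best_pair, best_f1 = ThresholdPair(lo, hi), f1
        if best_pair is None:
            raise NoFeasiblePairError(
                "every coarse grid pair yields an empty RP or NS set"
            )

        # stage 2: fine coordinate scan, t_low then t_high
        lo, hi = best_pair.t_low, best_pair.t_high
        for coord in ("low", "high"):
            center = lo if coord == "low" else hi
            ticks = np.arange(
                center - fine_window, center + fine_window + fine_step / 2,
                fine_step,
            )
            for tick in ticks:
                tick = _snap(tick)
                if coord == "low":
                    if not 0.0 <= tick < hi:
                        continue
                    cand = ThresholdPair(tick, hi)
                else:
                    if not lo < tick <= 1.0:
                        continue
                    cand = ThresholdPair(lo, tick)
                f1 = evaluate(cand)
                if f1 is not None and f1 > best_f1:
                    best_pair, best_f1 = cand, f1
                    lo, hi = cand.t_low, cand.t_high

        if incumbent is None or alpha * (best_f1 - incumbent_f1) > 0:
            incumbent, incumbent_f1 = best_pair, best_f1
        best_so_far = max(best_so_far, best_f1)
        trace.add(rnd, best_so_far, best_pair)

    trace.incumbent = incumbent
    return incumbent, trace
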