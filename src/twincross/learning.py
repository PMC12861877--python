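"""Positive-only / negative-only twin training with a noise-filter policy.

Each branch (PL trains on reliable positives, NL on selected negatives)
keeps a core training set and an opposite set ten times its size.  Every
epoch a stochastic retain/remove policy filters suspected-noise instances
Psi out of the core set and transfers them to the opposite set; the
backbone is refit on twin four-class examples; validation F1 (after the
policy cleans the validation sets the same way) is appended to a reward
trace; and the policy takes one reward-weighted cross-entropy step —
reinforcing its epoch's decisions when the trailing-mean F1 rose,
discouraging them when it fell.

The default backbone is a small MLP over the 22 GLCM features plus a
branch flag, with a 4-way softmax head — a desk-scale stand-in for a deep
convolutional backbone, which can be plugged in behind the same contract.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.neural_network import MLPClassifier

from twincross.features import feature_matrix
from twincross.fusion import FOUR_CLASSES, fuse_twin_posteriors, twin_transform
from twincross.metrics import confusion_metrics
from twincross.seeding import rng_for, subseed

logger = logging.getLogger(__name__)

REMOVAL_FLOOR = 0.2  # fraction of the core set that is always retained


# ---------------------------------------------------------------------------
# backbones


class FourClassBackbone:
    """Seedable 4-way classifier over branch-flagged feature vectors.

    Wraps any sklearn-style estimator with ``fit``/``predict_proba``.
    Labels are the strings in :data:`twincross.fusion.FOUR_CLASSES`;
    posteriors are returned in that fixed order.
    """

    def __init__(self, estimator):
        self.estimator = estimator
        self._fitted = False

    def fit(self, X: np.ndarray, y: np.ndarray) -> "FourClassBackbone":
        y = np.asarray(y)
        unknown = set(y.tolist()) - set(FOUR_CLASSES)
        if unknown:
            raise ValueError(f"unknown four-class labels: {sorted(unknown)}")
        self.estimator.fit(X, y)
        self._fitted = True
        return self

    def predict_posteriors(self, X: np.ndarray) -> np.ndarray:
        if not self._fitted:
            raise RuntimeError("backbone is not fitted")
        proba = self.estimator.predict_proba(X)
        out = np.zeros((len(X), 4))
        for col, cls in enumerate(self.estimator.classes_):
            out[:, FOUR_CLASSES.index(cls)] = proba[:, col]
        # guard against tiny numerical drift off the simplex
        return out / out.sum(axis=1, keepdims=True)


def mlp_backbone_factory(
    hidden_layer_sizes: tuple[int, ...] = (32, 16),
    learning_rate: float = 1e-3,
    max_iter: int = 150,
):
    """Factory of factories: returns ``f(seed) -> FourClassBackbone``."""

    def factory(seed: int) -> FourClassBackbone:
        return FourClassBackbone(
            MLPClassifier(
                hidden_layer_sizes=hidden_layer_sizes,
                learning_rate_init=learning_rate,
                max_iter=max_iter,
                random_state=int(seed) % (2**32),
                early_stopping=False,
            )
        )

    return factory


def logistic_backbone_factory(C: float = 1.0, max_iter: int = 500):
    """Fast deterministic multinomial-logistic four-class backbone."""

    def factory(seed: int) -> FourClassBackbone:
        return FourClassBackbone(
            LogisticRegression(
                C=C,
                max_iter=max_iter,
                random_state=int(seed) % (2**32),
                class_weight="balanced",  # 1:ratio sets would drown P classes
            )
        )

    return factory


def binary_logistic_factory(C: float = 1.0, max_iter: int = 500):
    """Binary backbone for threshold-pair evaluation (fit/predict)."""

    def factory(seed: int):
        return LogisticRegression(
            C=C, max_iter=max_iter, random_state=int(seed) % (2**32)
        )

    return factory


# ---------------------------------------------------------------------------
# twin feature plumbing


@dataclass(frozen=True)
class TwinFeatures:
    """Standardized per-branch feature matrices for one dataset."""

    X_plus: np.ndarray
    X_minus: np.ndarray

    def __post_init__(self) -> None:
        if self.X_plus.shape != self.X_minus.shape:
            raise ValueError("branch feature matrices must share a shape")

    @classmethod
    def from_patches(cls, patches, **glcm_kwargs) -> "TwinFeatures":
        pairs = [twin_transform(np.asarray(p)) for p in patches]
        xp = feature_matrix([t.x_plus for t in pairs], **glcm_kwargs)
        xm = feature_matrix([t.x_minus for t in pairs], **glcm_kwargs)
        mean = xp.mean(axis=0)
        std = xp.std(axis=0)
        std[std == 0] = 1.0
        return cls(X_plus=(xp - mean) / std, X_minus=(xm - mean) / std)

    def branch_flagged(self, ids: np.ndarray, branch: str) -> np.ndarray:
        X = self.X_plus[ids] if branch == "plus" else self.X_minus[ids]
        flag = 1.0 if branch == "plus" else -1.0
        return np.hstack([X, np.full((len(ids), 1), flag)])


def twin_training_arrays(
    feats: TwinFeatures, pos_ids: np.ndarray, neg_ids: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Stack twin four-class examples for P-labeled and N-labeled ids."""
    blocks, labels = [], []
    for ids, lab in ((pos_ids, "P"), (neg_ids, "N")):
        for branch, suffix in (("plus", "+"), ("minus", "-")):
            if len(ids):
                blocks.append(feats.branch_flagged(np.asarray(ids), branch))
                labels.extend([lab + suffix] * len(ids))
    return np.vstack(blocks), np.asarray(labels)


def fused_predictions(
    backbone: FourClassBackbone, feats: TwinFeatures, ids: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fused binary predictions (1 = P), confidences and positive scores."""
    ids = np.asarray(ids)
    theta = backbone.predict_posteriors(feats.branch_flagged(ids, "plus"))
    psi = backbone.predict_posteriors(feats.branch_flagged(ids, "minus"))
    preds = np.zeros(len(ids), dtype=int)
    confs = np.zeros(len(ids))
    for i in range(len(ids)):
        decision = fuse_twin_posteriors(theta[i], psi[i])
        preds[i] = 1 if decision.label == "P" else 0
        confs[i] = decision.confidence
    pos_score = 0.5 * (
        theta[:, :2].sum(axis=1) + psi[:, :2].sum(axis=1)
    )
    return preds, confs, pos_score


# ---------------------------------------------------------------------------
# training sets


class InsufficientSamplesError(ValueError):
    pass


@dataclass(frozen=True)
class TrainingSets:
    """Per-branch core/opposite train and validation id sets.

    ``branch`` is "PL" (core = positives) or "NL" (core = negatives).
    Invariants: the core set loses exactly ``psi`` (core = core_ori - psi),
    the opposite set gains it, and train/validation ids are disjoint.
    """

    branch: str
    p_t_ori: np.ndarray
    p_v_ori: np.ndarray
    n_t_ori: np.ndarray
    n_v_ori: np.ndarray
    psi: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    ratio: int = 10

    def __post_init__(self) -> None:
        if self.branch not in ("PL", "NL"):
            raise ValueError("branch must be 'PL' or 'NL'")
        core = self.p_t_ori if self.branch == "PL" else self.n_t_ori
        if len(self.psi) and not set(self.psi.tolist()) <= set(core.tolist()):
            raise ValueError("psi must be a subset of the core training set")
        train = set(self.p_t_ori.tolist()) | set(self.n_t_ori.tolist())
        val = set(self.p_v_ori.tolist()) | set(self.n_v_ori.tolist())
        if train & val:
            raise ValueError("train and validation ids must be disjoint")

    @property
    def core_ori(self) -> np.ndarray:
        return self.p_t_ori if self.branch == "PL" else self.n_t_ori

    @property
    def p_t(self) -> np.ndarray:
        """Effective positive training ids for this epoch."""
        if self.branch == "PL":
            return np.setdiff1d(self.p_t_ori, self.psi)
        return np.union1d(self.p_t_ori, self.psi)

    @property
    def n_t(self) -> np.ndarray:
        """Effective negative training ids (removed ids join the opposite set)."""
        if self.branch == "PL":
            return np.union1d(self.n_t_ori, self.psi)
        return np.setdiff1d(self.n_t_ori, self.psi)


def build_pl_nl_sets(
    rp: np.ndarray,
    ns: np.ndarray,
    val_pos: np.ndarray,
    val_neg: np.ndarray,
    ratio: int = 10,
    seed: int = 0,
    shrink_core: bool = False,
) -> tuple[TrainingSets, TrainingSets]:
    """Construct the PL and NL branch sets at the 1:ratio imbalance.

    PL: core positives = all of RP; opposite negatives are ``ratio * |RP|``
    ids drawn uniformly without replacement from NS (insufficient NS is an
    error naming the required count, unless ``shrink_core`` subsamples the
    core down to ``|NS| // ratio`` instead).  NL mirrors the construction
    with a core small enough that ``ratio`` times as many positives exist
    in RP.  Validation sets come from the held-out pool and stay disjoint
    from training.
    """
    rp = np.asarray(rp, dtype=int)
    ns = np.asarray(ns, dtype=int)
    val_pos = np.asarray(val_pos, dtype=int)
    val_neg = np.asarray(val_neg, dtype=int)
    if len(rp) == 0:
        raise InsufficientSamplesError("RP is empty; no positive core set")
    rng = rng_for(seed, "pl-nl-sets")
    rp_pool = rp  # NL mirrors against the full RP pool even if PL shrinks
    if shrink_core and len(ns) < ratio * len(rp):
        core_size = len(ns) // ratio
        if core_size == 0:
            raise InsufficientSamplesError(
                f"NS has {len(ns)} ids; cannot support even one core "
                f"positive at ratio {ratio}"
            )
        rp = rng.choice(rp, size=core_size, replace=False)
    needed = ratio * len(rp)
    if len(ns) < needed:
        raise InsufficientSamplesError(
            f"PL needs {needed} negatives (ratio {ratio} x |RP|={len(rp)}), "
            f"have {len(ns)}"
        )
    pl_neg = rng.choice(ns, size=needed, replace=False)
    n_v = min(ratio * len(val_pos), len(val_neg))
    pl = TrainingSets(
        branch="PL",
        p_t_ori=np.sort(rp),
        p_v_ori=np.sort(val_pos),
        n_t_ori=np.sort(pl_neg),
        n_v_ori=np.sort(rng.choice(val_neg, size=n_v, replace=False)),
        ratio=ratio,
    )

    nl_core_size = min(len(ns), len(rp_pool) // ratio)
    if nl_core_size == 0:
        raise InsufficientSamplesError(
            f"NL needs at least {ratio} reliable positives to mirror the "
            f"1:{ratio} ratio, have {len(rp_pool)}"
        )
    nl_core = rng.choice(ns, size=nl_core_size, replace=False)
    nl_pos = rng.choice(rp_pool, size=ratio * nl_core_size, replace=False)
    p_v = min(ratio * len(val_neg), len(val_pos))
    nl = TrainingSets(
        branch="NL",
        p_t_ori=np.sort(nl_pos),
        p_v_ori=np.sort(rng.choice(val_pos, size=p_v, replace=False)),
        n_t_ori=np.sort(nl_core),
        n_v_ori=np.sort(val_neg),
        ratio=ratio,
    )
    return pl, nl


# ---------------------------------------------------------------------------
# retain/remove policy


class PolicyModel:
    """Logistic retain/remove policy pi(remove | state).

    The state is the patch feature vector concatenated with the current
    backbone's posterior for that patch.  Updates are REINFORCE-style:
    one gradient step on the cross-entropy of the epoch's taken actions,
    scaled by the (signed) reward; a zero reward leaves the parameters
    unchanged.
    """

    #: logit bounds: the cap keeps pi(remove) <= ~0.62 so a run of negative
    #: rewards cannot drive the policy into irreversible mass removal
    Z_MIN = -6.0
    Z_MAX = 0.5
    #: per-update shrinkage toward the origin; spurious drift decays while
    #: genuinely rewarded directions are re-reinforced every epoch
    WEIGHT_DECAY = 0.02

    def __init__(self, n_features: int, lr: float = 5.0, init_bias: float = -1.5):
        # negative initial bias keeps early-epoch removal modest (~18%)
        # while leaving room for exploration
        self.w = np.zeros(n_features)
        self.b = init_bias
        self.lr = lr

    def remove_proba(self, states: np.ndarray) -> np.ndarray:
        z = np.asarray(states) @ self.w + self.b
        return 1.0 / (1.0 + np.exp(-np.clip(z, self.Z_MIN, self.Z_MAX)))

    def sample_actions(
        self, states: np.ndarray, rng: np.random.Generator
    ) -> np.ndarray:
        return (rng.random(len(states)) < self.remove_proba(states)).astype(int)

    def update(
        self, states: np.ndarray, actions: np.ndarray, reward: float
    ) -> None:
        if reward == 0 or len(states) == 0:
            return
        p = self.remove_proba(states)
        err = np.asarray(actions) - p  # d/dz of log pi(taken action)
        self.w = (1 - self.WEIGHT_DECAY) * self.w + self.lr * reward * (
            err @ np.asarray(states)
        ) / len(states)
        self.b = (1 - self.WEIGHT_DECAY) * self.b + self.lr * reward * float(
            err.mean()
        )


@dataclass(frozen=True)
class EpochDecisions:
    states: np.ndarray
    actions: np.ndarray  # 1 = removed


def policy_filter_epoch(
    policy: PolicyModel,
    sets: TrainingSets,
    states: np.ndarray,
    seed: int = 0,
    floor: float = REMOVAL_FLOOR,
) -> tuple[TrainingSets, EpochDecisions]:
    """Sample removals from the core set; enforce the retention floor.

    Each core candidate is removed with probability ``pi(remove|state)``.
    If the sampled removal set would leave fewer than ``floor`` of the
    core set, it is truncated to the highest removal probabilities and a
    warning is logged.  Returns the updated sets (psi recorded) and the
    decisions actually taken.
    """
    core = sets.core_ori
    if len(core) == 0:
        raise ValueError("empty core training set")
    if len(states) != len(core):
        raise ValueError("need one state row per core candidate")
    rng = rng_for(seed, "policy-filter")
    actions = policy.sample_actions(states, rng)
    max_remove = len(core) - math.ceil(floor * len(core))
    if actions.sum() > max_remove:
        logger.warning(
            "%s: policy removal (%d) exceeds the %.0f%% retention floor; "
            "truncating to %d",
            sets.branch, int(actions.sum()), 100 * floor, max_remove,
        )
        probs = policy.remove_proba(states)
        keep_removed = np.argsort(-probs, kind="stable")[:max_remove]
        actions = np.zeros_like(actions)
        actions[keep_removed] = 1
    psi = core[actions.astype(bool)]
    return (
        replace(sets, psi=np.sort(psi)),
        EpochDecisions(states=states, actions=actions),
    )


# ---------------------------------------------------------------------------
# reward


@dataclass
class RewardTrace:
    """Per-epoch F1 history with trailing-mean rewards."""

    alpha: float = 100.0
    window: int = 5
    f1_history: list[float] = field(default_factory=list)
    rewards: list[float] = field(default_factory=list)

    def append(self, f1: float) -> float | None:
        """Record an epoch F1; return the reward once >= 2 epochs exist."""
        self.f1_history.append(float(f1))
        if len(self.f1_history) < 2:
            return None
        r = compute_reward(self.f1_history, alpha=self.alpha, window=self.window)
        self.rewards.append(r)
        return r

    def trailing_mean(self, upto: int | None = None) -> float:
        hist = self.f1_history if upto is None else self.f1_history[:upto]
        w = min(self.window, len(hist))
        return float(np.mean(hist[-w:]))


def compute_reward(
    f1_history, alpha: float = 100.0, window: int = 5
) -> float:
    """``alpha * (Fbar_i - Fbar_{i-1})`` with trailing means over <= ``window``
    epochs.  Requires at least two recorded epochs."""
    f1s = list(f1_history)
    if len(f1s) < 2:
        raise ValueError("need at least 2 epochs to compute a reward")
    w_now = min(window, len(f1s))
    w_prev = min(window, len(f1s) - 1)
    mean_now = float(np.mean(f1s[-w_now:]))
    mean_prev = float(np.mean(f1s[:-1][-w_prev:]))
    return alpha * (mean_now - mean_prev)


def update_policy(
    policy: PolicyModel, decisions: EpochDecisions, reward: float
) -> PolicyModel:
    """One reward-weighted cross-entropy step; no-op when reward is 0."""
    policy.update(decisions.states, decisions.actions, reward)
    return policy


# ---------------------------------------------------------------------------
# epoch training and the branch loop


def train_epoch(
    backbone_factory,
    sets: TrainingSets,
    feats: TwinFeatures,
    policy: PolicyModel | None = None,
    seed: int = 0,
) -> tuple[FourClassBackbone, float]:
    """Fit the backbone on the epoch's effective sets; validation F1.

    Validation instances whose removal probability exceeds 0.5 under the
    current policy are transferred to the opposite validation set before
    scoring (the policy cleans validation the same way it cleans training).
    """
    p_t, n_t = sets.p_t, sets.n_t
    if len(p_t) == 0 or len(n_t) == 0:
        raise ValueError("empty effective training set")
    X, y = twin_training_arrays(feats, p_t, n_t)
    backbone = backbone_factory(seed)
    backbone.fit(X, y)

    p_v, n_v = sets.p_v_ori, sets.n_v_ori
    if policy is not None:
        core_val = p_v if sets.branch == "PL" else n_v
        if len(core_val):
            states = _policy_states(backbone, feats, core_val)
            probs = policy.remove_proba(states)
            move = probs > 0.5
            # same retention floor as training: a runaway policy must not
            # be able to empty the validation set it is scored on
            max_move = len(core_val) - math.ceil(REMOVAL_FLOOR * len(core_val))
            if move.sum() > max_move:
                keep = np.argsort(-probs, kind="stable")[:max_move]
                move = np.zeros(len(core_val), dtype=bool)
                move[keep] = True
            if sets.branch == "PL":
                p_v = core_val[~move]
                n_v = np.union1d(sets.n_v_ori, core_val[move])
            else:
                n_v = core_val[~move]
                p_v = np.union1d(sets.p_v_ori, core_val[move])
    val_ids = np.concatenate([p_v, n_v])
    y_val = np.r_[np.ones(len(p_v), dtype=int), np.zeros(len(n_v), dtype=int)]
    preds, _, _ = fused_predictions(backbone, feats, val_ids)
    f1 = confusion_metrics(preds, y_val).f_measure
    return backbone, f1


def _policy_states(
    backbone: FourClassBackbone | None, feats: TwinFeatures, ids: np.ndarray
) -> np.ndarray:
    """Policy state: standardized features (plus branch) + backbone posterior."""
    ids = np.asarray(ids)
    base = feats.X_plus[ids]
    if backbone is None:
        post = np.full((len(ids), 4), 0.25)
    else:
        post = backbone.predict_posteriors(feats.branch_flagged(ids, "plus"))
    return np.hstack([base, post])


@dataclass
class BranchResult:
    branch: str
    backbone: FourClassBackbone
    policy: PolicyModel
    trace: RewardTrace
    psi_history: list[np.ndarray]
    log_rows: list[dict]


def run_branch_loop(
    feats: TwinFeatures,
    sets: TrainingSets,
    backbone_factory,
    epochs: int,
    alpha: float = 100.0,
    policy_lr: float = 5.0,
    policy_enabled: bool = True,
    floor: float = REMOVAL_FLOOR,
    n_rollouts: int = 5,
    seed: int = 0,
) -> BranchResult:
    """Run one PL or NL loop for ``epochs`` epochs.

    With ``n_rollouts > 1`` each epoch samples that many candidate removal
    sets, trains the backbone on each, rewards each rollout with the same
    trailing-mean rule, aggregates the reward-weighted policy gradients
    into one step, and adopts the best-F1 rollout as the epoch's outcome.
    Rollouts share one baseline (the previous trailing mean), so the
    within-epoch comparison isolates the effect of the removal choices —
    a plain-variance-reduction device; ``n_rollouts=1`` is the bare
    single-sample update.
    """
    n_state = feats.X_plus.shape[1] + 4
    policy = PolicyModel(n_features=n_state, lr=policy_lr)
    trace = RewardTrace(alpha=alpha)
    psi_history: list[np.ndarray] = []
    log_rows: list[dict] = []
    backbone: FourClassBackbone | None = None

    for epoch in range(1, epochs + 1):
        epoch_seed = subseed(seed, sets.branch, epoch)
        if policy_enabled:
            states = _policy_states(backbone, feats, sets.core_ori)
            rollouts = []
            for k in range(n_rollouts):
                sets_k, dec_k = policy_filter_epoch(
                    policy, sets, states,
                    seed=subseed(epoch_seed, "rollout", k), floor=floor,
                )
                backbone_k, f1_k = train_epoch(
                    backbone_factory, sets_k, feats, policy=policy,
                    seed=epoch_seed,
                )
                rollouts.append((sets_k, dec_k, backbone_k, f1_k))
            if len(trace.f1_history) >= 1:
                rewards_k = [
                    compute_reward(
                        trace.f1_history + [f1_k],
                        alpha=alpha / n_rollouts,
                        window=trace.window,
                    )
                    for _, _, _, f1_k in rollouts
                ]
                # mean-center across rollouts (self-critic baseline) so only
                # the relative merit of each removal set moves the policy;
                # with a single rollout this is the bare reward
                baseline = (
                    float(np.mean(rewards_k)) if n_rollouts > 1 else 0.0
                )
                for (_, dec_k, _, _), r_k in zip(rollouts, rewards_k):
                    update_policy(policy, dec_k, r_k - baseline)
            best = max(range(n_rollouts), key=lambda k: rollouts[k][3])
            epoch_sets, _, backbone, f1 = rollouts[best]
        else:
            epoch_sets = replace(sets, psi=np.array([], dtype=int))
            backbone, f1 = train_epoch(
                backbone_factory, epoch_sets, feats, policy=None,
                seed=epoch_seed,
            )
        reward = trace.append(f1)
        psi_history.append(epoch_sets.psi)
        log_rows.append(
            {
                "epoch": epoch,
                "f1": f1,
                "f1_trailing_mean": trace.trailing_mean(),
                "reward": reward if reward is not None else 0.0,
                "n_psi": len(epoch_sets.psi),
            }
        )
    return BranchResult(
        branch=sets.branch,
        backbone=backbone,
        policy=policy,
        trace=trace,
        psi_history=psi_history,
        log_rows=log_rows,
    )


# ---------------------------------------------------------------------------
# multi-channel orchestration


@dataclass
class ChannelInputs:
    """Prepared per-channel data for cross learning."""

    name: str
    feats: TwinFeatures
    rp: np.ndarray
    ns: np.ndarray
    val_pos: np.ndarray
    val_neg: np.ndarray
    test_ids: np.ndarray
    test_labels: np.ndarray


@dataclass
class ChannelResult:
    name: str
    pl: BranchResult
    nl: BranchResult
    learning_rate: float
    metrics: "object"  # MetricsBundle


def run_cross_learning(
    channels: list[ChannelInputs],
    epochs: int = 30,
    alpha: float = 100.0,
    ratio: int = 10,
    eta0: float = 1e-3,
    policy_enabled: bool = True,
    policy_lr: float = 5.0,
    backbone: str = "mlp",
    seed: int = 0,
) -> dict[str, ChannelResult]:
    """Run PL and NL loops for up to four channels in sequence.

    Per-channel learning rates are balanced multirate-style:
    ``eta_c = eta0 * N_min / N_c`` where ``N_c`` is the channel's sample
    count, so the largest channel trains with the smallest rate.  Empty
    channels are skipped with a warning.
    """
    if not 1 <= len(channels) <= 4:
        raise ValueError("need between 1 and 4 channels")
    sizes = {
        ch.name: len(ch.feats.X_plus) for ch in channels if len(ch.feats.X_plus)
    }
    if not sizes:
        raise ValueError("all channels are empty")
    n_min = min(sizes.values())

    results: dict[str, ChannelResult] = {}
    for ch in channels:
        if len(ch.feats.X_plus) == 0:
            logger.warning("channel %s is empty; skipped", ch.name)
            continue
        eta = eta0 * n_min / sizes[ch.name]
        if backbone == "mlp":
            factory = mlp_backbone_factory(learning_rate=eta)
        elif backbone == "logistic":
            factory = logistic_backbone_factory()
        else:
            raise ValueError(f"unknown backbone {backbone!r}")
        ch_seed = subseed(seed, "cross-learning", ch.name)
        pl_sets, nl_sets = build_pl_nl_sets(
            ch.rp, ch.ns, ch.val_pos, ch.val_neg, ratio=ratio, seed=ch_seed,
            shrink_core=True,
        )
        pl = run_branch_loop(
            ch.feats, pl_sets, factory, epochs, alpha=alpha,
            policy_lr=policy_lr, policy_enabled=policy_enabled, seed=ch_seed,
        )
        nl = run_branch_loop(
            ch.feats, nl_sets, factory, epochs, alpha=alpha,
            policy_lr=policy_lr, policy_enabled=policy_enabled, seed=ch_seed,
        )
        preds, _, scores = fused_predictions(pl.backbone, ch.feats, ch.test_ids)
        bundle = confusion_metrics(preds, ch.test_labels, scores=scores)
        results[ch.name] = ChannelResult(
            name=ch.name, pl=pl, nl=nl, learning_rate=eta, metrics=bundle
        )
    return results
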