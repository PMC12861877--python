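import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from twincross import benchmarks, learning
from twincross.learning import (
    EpochDecisions,
    InsufficientSamplesError,
    PolicyModel,
    RewardTrace,
    TrainingSets,
    build_pl_nl_sets,
    compute_reward,
    policy_filter_epoch,
    run_branch_loop,
    run_cross_learning,
    train_epoch,
    update_policy,
)


def make_sets(n_pos=20, ratio=10, branch="PL"):
    pos = np.arange(n_pos)
    neg = np.arange(n_pos, n_pos + ratio * n_pos)
    vp = np.arange(1000, 1010)
    vn = np.arange(1010, 1030)
    if branch == "PL":
        return TrainingSets(branch="PL", p_t_ori=pos, p_v_ori=vp,
                            n_t_ori=neg, n_v_ori=vn, ratio=ratio)
    return TrainingSets(branch="NL", p_t_ori=neg, p_v_ori=vp,
                        n_t_ori=pos, n_v_ori=vn, ratio=ratio)


class TestTrainingSets:
    def test_effective_sets_pl(self):
        sets = make_sets()
        sets = learning.replace(sets, psi=np.array([0, 3]))
        assert set(sets.p_t.tolist()) == set(range(20)) - {0, 3}
        assert {0, 3} <= set(sets.n_t.tolist())
        assert len(sets.p_t) + len(sets.psi) == len(sets.p_t_ori)
        assert not set(sets.psi.tolist()) & set(sets.p_t.tolist())

    def test_effective_sets_nl_mirrored(self):
        sets = make_sets(branch="NL")
        sets = learning.replace(sets, psi=np.array([1]))
        assert 1 not in sets.n_t
        assert 1 in sets.p_t

    def test_psi_must_come_from_core(self):
        with pytest.raises(ValueError):
            learning.replace(make_sets(), psi=np.array([9999]))

    def test_train_val_overlap_rejected(self):
        with pytest.raises(ValueError):
            TrainingSets(branch="PL", p_t_ori=np.array([0, 1]),
                         p_v_ori=np.array([1]), n_t_ori=np.array([2]),
                         n_v_ori=np.array([3]))


class TestBuildSets:
    def test_ratio_enforced(self):
        rp = np.arange(30)
        ns = np.arange(100, 500)
        pl, nl = build_pl_nl_sets(rp, ns, np.arange(600, 610),
                                  np.arange(700, 760), seed=1)
        assert len(pl.n_t_ori) == 10 * len(pl.p_t_ori) == 300
        assert len(nl.p_t_ori) == 10 * len(nl.n_t_ori)

    def test_insufficient_negatives_error_names_count(self):
        with pytest.raises(InsufficientSamplesError, match="300"):
            build_pl_nl_sets(np.arange(30), np.arange(100, 200),
                             np.arange(600, 610), np.arange(700, 760), seed=1)

    def test_shrink_core_downsizes_instead(self):
        pl, _ = build_pl_nl_sets(np.arange(30), np.arange(100, 200),
                                 np.arange(600, 610), np.arange(700, 760),
                                 seed=1, shrink_core=True)
        assert len(pl.p_t_ori) == 10
        assert len(pl.n_t_ori) == 100

    def test_deterministic(self):
        args = (np.arange(20), np.arange(100, 400),
                np.arange(600, 610), np.arange(700, 760))
        a_pl, a_nl = build_pl_nl_sets(*args, seed=9)
        b_pl, b_nl = build_pl_nl_sets(*args, seed=9)
        assert np.array_equal(a_pl.n_t_ori, b_pl.n_t_ori)
        assert np.array_equal(a_nl.p_t_ori, b_nl.p_t_ori)


class TestPolicy:
    def test_probabilities_complementary(self, rng):
        pol = PolicyModel(n_features=3)
        states = rng.normal(size=(10, 3))
        p = pol.remove_proba(states)
        assert np.all((p > 0) & (p < 1))
        # pi(retain) + pi(remove) = 1 by construction of the binary policy
        assert np.allclose(p + (1 - p), 1.0)

    def test_zero_reward_no_update(self, rng):
        pol = PolicyModel(n_features=3)
        w0, b0 = pol.w.copy(), pol.b
        dec = EpochDecisions(states=rng.normal(size=(5, 3)),
                             actions=np.array([1, 0, 1, 0, 0]))
        update_policy(pol, dec, 0.0)
        assert np.array_equal(pol.w, w0) and pol.b == b0

    @pytest.mark.parametrize("reward, direction", [(2.0, 1), (-2.0, -1)])
    def test_reward_moves_taken_action_probability(self, reward, direction):
        # finite-difference oracle on a 2-parameter policy, one decision
        for action in (0, 1):
            pol = PolicyModel(n_features=1, lr=0.1)
            state = np.array([[0.7]])
            p_before = pol.remove_proba(state)[0]
            pi_before = p_before if action == 1 else 1 - p_before
            update_policy(
                pol, EpochDecisions(states=state, actions=np.array([action])),
                reward,
            )
            p_after = pol.remove_proba(state)[0]
            pi_after = p_after if action == 1 else 1 - p_after
            if direction > 0:
                assert pi_after >= pi_before
            else:
                assert pi_after <= pi_before


class TestPolicyFilter:
    @staticmethod
    def _states(n):
        return np.zeros((n, 2))

    def test_identity_policy(self):
        pol = PolicyModel(n_features=2)
        pol.b = -100.0  # pi(remove) ~ 0
        sets = make_sets()
        out, dec = policy_filter_epoch(pol, sets, self._states(20), seed=1)
        assert len(out.psi) == 0
        assert np.array_equal(out.p_t, sets.p_t_ori)

    def test_floor_guard_truncates(self, caplog):
        pol = PolicyModel(n_features=2)
        pol.b = 100.0  # pi(remove) ~ 1 (before the logit cap) -> maximal
        sets = make_sets()
        out, dec = policy_filter_epoch(pol, sets, self._states(20), seed=1)
        assert len(out.psi) <= 16  # 20% of 20 always retained
        assert len(out.p_t) >= 4

    def test_set_conservation_every_epoch(self, rng):
        pol = PolicyModel(n_features=2)
        sets = make_sets()
        for seed in range(10):
            out, _ = policy_filter_epoch(
                pol, sets, rng.normal(size=(20, 2)), seed=seed
            )
            assert len(out.p_t) + len(out.psi) == len(out.p_t_ori)
            assert not set(out.psi.tolist()) & set(out.p_t.tolist())
            assert set(out.psi.tolist()) <= set(out.n_t.tolist())

    def test_state_row_mismatch_rejected(self):
        with pytest.raises(ValueError):
            policy_filter_epoch(PolicyModel(2), make_sets(), self._states(3))


class TestReward:
    def test_arithmetic(self):
        # trailing means move 0.80 -> 0.85 with alpha 10 -> reward 0.5
        assert compute_reward([0.80, 0.85], alpha=10.0, window=1) == \
            pytest.approx(0.5)
        # window shorter than history: means over the last two epochs
        r = compute_reward([0.6, 0.8, 0.9], alpha=100.0, window=2)
        assert r == pytest.approx(100.0 * ((0.8 + 0.9) / 2 - (0.6 + 0.8) / 2))

    def test_constant_history_zero(self):
        assert compute_reward([0.7] * 8, alpha=100.0) == 0.0

    def test_too_short_history_rejected(self):
        with pytest.raises(ValueError):
            compute_reward([0.5])

    @given(st.lists(st.floats(0, 1), min_size=2, max_size=30),
           st.floats(0.1, 200))
    @settings(max_examples=200, deadline=None)
    def test_telescoping_identity(self, f1s, alpha):
        trace = RewardTrace(alpha=alpha)
        for f1 in f1s:
            trace.append(f1)
        total = sum(trace.rewards)
        first_mean = f1s[0]
        last_mean = float(np.mean(f1s[-min(5, len(f1s)):]))
        assert total == pytest.approx(alpha * (last_mean - first_mean),
                                      abs=1e-9 * max(1.0, alpha))


class TestTrainEpoch:
    @pytest.fixture(scope="class")
    def experiment(self):
        return benchmarks.make_noisy_pl_experiment(seed=0, noise_rate=0.0)

    def test_clean_channel_f1(self, experiment):
        backbone, f1 = train_epoch(
            learning.logistic_backbone_factory(), experiment.sets,
            experiment.feats, seed=1,
        )
        assert f1 >= 0.9

    def test_deterministic(self, experiment):
        _, a = train_epoch(learning.logistic_backbone_factory(),
                           experiment.sets, experiment.feats, seed=5)
        _, b = train_epoch(learning.logistic_backbone_factory(),
                           experiment.sets, experiment.feats, seed=5)
        assert a == b

    def test_empty_effective_set_rejected(self, experiment):
        sets = learning.replace(
            experiment.sets, psi=experiment.sets.p_t_ori.copy()
        )
        with pytest.raises(ValueError):
            train_epoch(learning.logistic_backbone_factory(), sets,
                        experiment.feats, seed=1)


class TestBranchLoop:
    def test_loop_records_everything(self):
        res, exp = benchmarks.noise_filter_run(seed=2, epochs=6, n_core=20,
                                               n_val_pos=15, n_val_neg=30)
        assert len(res.trace.f1_history) == 6
        assert len(res.trace.rewards) == 5
        assert len(res.psi_history) == 6
        assert [r["epoch"] for r in res.log_rows] == list(range(1, 7))

    def test_loop_deterministic(self):
        a, _ = benchmarks.noise_filter_run(seed=3, epochs=4, n_core=20,
                                           n_val_pos=15, n_val_neg=30)
        b, _ = benchmarks.noise_filter_run(seed=3, epochs=4, n_core=20,
                                           n_val_pos=15, n_val_neg=30)
        assert a.trace.f1_history == b.trace.f1_history
        assert all(np.array_equal(x, y)
                   for x, y in zip(a.psi_history, b.psi_history))


class TestRunCrossLearning:
    @pytest.fixture(scope="class")
    def channels(self):
        out = []
        for i, name in enumerate(("GU", "GRS")):
            ds = benchmarks.separable_channel(120 + 30 * i, 60, seed=20 + i,
                                              name=name)
            feats = learning.TwinFeatures.from_patches(ds.patches)
            tr = np.flatnonzero(ds.split == "train")
            va = np.flatnonzero(ds.split == "val")
            te = np.flatnonzero(ds.split == "test")
            out.append(learning.ChannelInputs(
                name=name, feats=feats,
                rp=tr[ds.labels[tr] == 1], ns=tr[ds.labels[tr] == 0],
                val_pos=va[ds.labels[va] == 1], val_neg=va[ds.labels[va] == 0],
                test_ids=te, test_labels=ds.labels[te],
            ))
        return out

    def test_contract_and_learning_rates(self, channels):
        results = run_cross_learning(channels, epochs=4, backbone="logistic",
                                     seed=1)
        assert set(results) == {"GU", "GRS"}
        sizes = {c.name: len(c.feats.X_plus) for c in channels}
        largest = max(sizes, key=sizes.get)
        rates = {k: v.learning_rate for k, v in results.items()}
        assert rates[largest] == min(rates.values())
        for res in results.values():
            assert res.metrics.f_measure >= 0.8
            assert res.pl.branch == "PL" and res.nl.branch == "NL"

    def test_channel_count_bounds(self, channels):
        with pytest.raises(ValueError):
            run_cross_learning([], seed=1)
        with pytest.raises(ValueError):
            run_cross_learning(channels * 3, seed=1)
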