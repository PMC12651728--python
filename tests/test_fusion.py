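"""Attention fusion model: softmax contracts, multi-label head, training
determinism, frozen prediction, and permutation equivariance."""

import numpy as np
import pytest

from agfn._autodiff import Tensor
from agfn.evaluate import make_folds
from agfn.fusion import (FusionConfig, bce_loss, neighborhood_attention,
                         predict_heldout, predict_proba)
from agfn.pipeline import StudyConfig, label_matrix, run_fold
from agfn.temporal import LTGRUConfig, STCNNConfig


def small_fusion(seed=0, epochs=4):
    return FusionConfig(max_epochs=epochs, patience=epochs, seed=seed,
                        st=STCNNConfig(window=4, channels=8),
                        lt=LTGRUConfig(hidden=8))


class TestNeighborhoodAttention:
    def test_single_neighbor_passes_its_value_through(self):
        Q = np.array([[1.0]])
        K = np.array([[0.0], [2.0]])
        V = np.array([[5.0], [7.0]])
        out, w = neighborhood_attention(Q, K, V, [np.array([1])])
        np.testing.assert_allclose(out, [[7.0]])
        np.testing.assert_allclose(w[0], [1.0])

    def test_identical_keys_give_uniform_weights(self):
        Q = np.ones((1, 2))
        K = np.tile([0.3, -0.1], (4, 1))
        V = np.arange(8.0).reshape(4, 2)
        out, w = neighborhood_attention(Q, K, V, [np.arange(4)])
        np.testing.assert_allclose(w[0], np.full(4, 0.25))
        np.testing.assert_allclose(out[0], V.mean(axis=0))

    def test_hand_softmax_quarter_three_quarters(self):
        # d_k = 1, logits (0, ln 3) -> weights (0.25, 0.75)
        Q = np.array([[1.0]])
        K = np.array([[0.0], [np.log(3.0)]])
        V = np.array([[1.0], [2.0]])
        _, w = neighborhood_attention(Q, K, V, [np.array([0, 1])])
        np.testing.assert_allclose(w[0], [0.25, 0.75], atol=1e-12)

    def test_weights_sum_to_one(self, rng):
        Q, K, V = rng.normal(size=(3, 6, 4))
        nbs = [rng.choice(6, size=k, replace=False) for k in (1, 3, 5)]
        _, w = neighborhood_attention(Q[:3], K, V, nbs)
        for wi in w:
            assert wi.sum() == pytest.approx(1.0, abs=1e-6)

    def test_empty_neighborhood_rejected(self):
        with pytest.raises(ValueError):
            neighborhood_attention(np.ones((1, 1)), np.ones((1, 1)),
                                   np.ones((1, 1)), [np.array([], int)])


class TestPredict:
    def test_zero_logits_give_half(self):
        p = predict_proba(Tensor(np.zeros((2, 6)))).data
        np.testing.assert_allclose(p, 0.5)

    def test_hand_logistic_value(self):
        p = predict_proba(Tensor(np.array([[2.0]]))).data
        assert p[0, 0] == pytest.approx(0.8808, abs=5e-5)

    def test_monotone_toward_one(self):
        logits = np.array([[1.0], [5.0], [20.0], [200.0]])
        p = predict_proba(Tensor(logits)).data.ravel()
        assert (np.diff(p) >= 0).all() and p[-1] == pytest.approx(1.0)

    def test_probabilities_are_independent_not_simplex(self):
        p = predict_proba(Tensor(np.full((1, 6), 3.0))).data
        assert p.sum() > 1.0  # multi-label: no sum-to-one constraint


def test_bce_warns_when_an_outcome_has_no_positives(small_cohort):
    y = np.zeros((4, 6))
    y[:, 0] = [1, 0, 1, 0]
    loss = bce_loss(Tensor(np.zeros((4, 6))), y,
                    outcome_mask=(y.sum(0) > 0).astype(float))
    assert float(loss.data) == pytest.approx(np.log(2), abs=1e-7)


def test_config_search_space_enforced():
    for bad in (dict(heads=3), dict(hidden=100), dict(dropout=0.05),
                dict(lr=5e-3)):
        with pytest.raises(ValueError):
            FusionConfig(**bad)


def test_random_search_samples_stated_space_and_picks_best(small_cohort):
    from agfn.pipeline import StudyConfig, random_search

    pids, Y = label_matrix(small_cohort)
    plan = make_folds(Y, pids, K=4, seed=0)
    tr, va, _ = plan.split(0)
    base = StudyConfig(seed=0, fusion=small_fusion(epochs=2))
    best, log = random_search(small_cohort, tr, va, base, n_trials=2, seed=1)
    assert len(log) == 2
    for cfg, auc in log:
        assert cfg.heads in (2, 4, 8) and cfg.hidden in (64, 128, 256)
        assert 0.1 <= cfg.dropout <= 0.5 and 1e-5 <= cfg.lr <= 1e-3
    assert max(a for _, a in log) == dict((id(c), a) for c, a in log)[id(best)]


@pytest.fixture(scope="module")
def tiny_fold(small_cohort):
    pids, Y = label_matrix(small_cohort)
    plan = make_folds(Y, pids, K=4, seed=0)
    tr, va, te = plan.split(0)
    cfg = StudyConfig(seed=0, fusion=small_fusion())
    res = run_fold(small_cohort, tr, va, te, cfg)
    return res, tr, va, te, cfg


class TestTraining:
    def test_same_seed_reproduces_run(self, small_cohort, tiny_fold):
        res, tr, va, te, cfg = tiny_fold
        res2 = run_fold(small_cohort, tr, va, te, cfg)
        assert res2.val_auc == res.val_auc
        np.testing.assert_array_equal(res2.p_test, res.p_test)

    def test_training_loss_decreases(self, tiny_fold):
        res, *_ = tiny_fold
        losses = [e["train_loss"] for e in res.state.train_log]
        assert losses[-1] < losses[0]

    def test_predicting_twice_is_identical_and_frozen(self, tiny_fold,
                                                      small_cohort):
        res, tr, *_ = tiny_fold
        state = res.state
        h0 = state.checkpoint_hash()
        trs = state.train_tensors
        pids, _ = label_matrix(small_cohort)
        p1 = predict_heldout(state, trs[:5], trs)
        p2 = predict_heldout(state, trs[:5], trs)
        np.testing.assert_array_equal(p1, p2)
        assert state.checkpoint_hash() == h0

    def test_permuting_patients_permutes_predictions(self, tiny_fold):
        res, *_ = tiny_fold
        trs = res.state.train_tensors
        subset = trs[:6]
        perm = [3, 0, 5, 1, 4, 2]
        p = predict_heldout(res.state, subset, trs)
        pp = predict_heldout(res.state, [subset[i] for i in perm], trs)
        np.testing.assert_allclose(pp, p[perm], atol=1e-10)

    def test_attention_rows_sum_to_one_in_model(self, tiny_fold):
        """The masked softmax inside the layers is a proper distribution."""
        import agfn._autodiff as ad

        res, *_ = tiny_fold
        g = res.state.graph
        n = g.n_nodes
        mask = np.eye(n, dtype=bool)
        for i, nb in enumerate(g.neighbors):
            mask[i, nb] = True
        logits = Tensor(np.random.default_rng(0).normal(size=(n, n)))
        A = ad.softmax(logits, axis=1, mask=mask).data
        np.testing.assert_allclose(A.sum(axis=1), 1.0, atol=1e-6)
        assert np.all(A[~mask] == 0)

    def test_head_columns_are_outcome_separable(self, tiny_fold):
        """With the trunk frozen, perturbing outcome-j labels only moves
        outcome-j predictions (the sigmoid head decouples the losses)."""
        from agfn.fusion import _graph_mask_bias
        from agfn.nn import AdamW
        from agfn.temporal import stack_inputs

        res, *_ = tiny_fold
        state = res.state
        trs = state.train_tensors
        temp, stat = stack_inputs(trs)
        mask, bias = _graph_mask_bias(state.graph)
        y = np.zeros((len(trs), 6))
        y[::2, :] = 1

        def train_head(labels):
            state.model.load_state_dict(start)
            opt = AdamW({k: v for k, v in state.model.parameters().items()
                         if k.startswith("head")}, lr=1e-2)
            for _ in range(3):
                logits = state.model.logits_train(Tensor(temp), Tensor(stat),
                                                  mask, bias)
                loss = bce_loss(logits, labels)
                opt.zero_grad()
                loss.backward()
                opt.step()
            out = state.model.logits_train(Tensor(temp), Tensor(stat),
                                           mask, bias).data
            state.model.load_state_dict(start)
            return out

        start = state.model.state_dict()
        base = train_head(y)
        y2 = y.copy()
        y2[:, 2] = 1 - y2[:, 2]
        flipped = train_head(y2)
        other = [k for k in range(6) if k != 2]
        np.testing.assert_allclose(flipped[:, other], base[:, other],
                                   atol=1e-10)
        assert np.abs(flipped[:, 2] - base[:, 2]).max() > 1e-6
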