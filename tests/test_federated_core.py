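"""Local SGD, federated averaging, scheduling and the recorded history."""

import numpy as np
import pytest

from fedleak import autodiff as ad
from fedleak import synthetic_data as sd
from fedleak.federated_core import (TrainConfig, bce_loss,
                                    federated_average, local_train,
                                    per_sample_gradients, run_federation,
                                    select_clients)
from fedleak.models import ModelConfig, build_model

from conftest import client_arrays


def test_train_config_validation():
    with pytest.raises(ValueError):
        TrainConfig(max_rounds=0)
    with pytest.raises(ValueError):
        TrainConfig(client_fraction=0.0)


def test_bce_loss_matches_closed_form(rng):
    z = rng.normal(size=6)
    y = (rng.random(6) > 0.5).astype(float)
    loss = bce_loss(ad.constant(z), y).data
    expected = np.mean(np.log1p(np.exp(-np.abs(z))) + np.maximum(z, 0)
                       - y * z)
    assert loss == pytest.approx(expected)


class TestLocalTrain:
    def test_zero_learning_rate_gives_zero_delta(self, toy_model_bn, rng):
        model, pset = toy_model_bn
        X, y = rng.random((4, 32, 32)), np.array([0., 1., 0., 1.])
        _, delta = local_train(model, pset, X, y, TrainConfig(), lr=0.0,
                               rng=rng)
        assert all(np.all(d == 0) for d in delta.values())

    def test_single_step_delta_equals_lr_times_gradient(self, toy_model_bn,
                                                        rng):
        """Single sample, single epoch: the shared update is exactly
        lr x the autodiff gradient of the loss at that sample."""
        model, pset = toy_model_bn
        X, y = rng.random((1, 32, 32)), np.array([1.0])
        lr = 0.01
        _, delta = local_train(model, pset, X, y, TrainConfig(), lr=lr,
                               rng=np.random.default_rng(0))
        grads = per_sample_gradients(model, pset, X, y)
        for name, d in delta.items():
            assert np.allclose(d, lr * grads[name][0], atol=1e-12)

    def test_oversized_batch_collapses_to_one_step(self, toy_model_bn, rng):
        model, pset = toy_model_bn
        X = rng.random((3, 32, 32))
        y = np.array([1.0, 0.0, 1.0])
        calls = []

        def hook(psg):
            calls.append(psg)
            return {k: g.mean(axis=0) for k, g in psg.items()}

        local_train(model, pset, X, y, TrainConfig(batch_size=10), lr=0.01,
                    rng=rng, dp_hook=hook)
        assert len(calls) == 1                       # one step per epoch
        assert next(iter(calls[0].values())).shape[0] == 3

    def test_empty_client_rejected(self, toy_model_bn, rng):
        model, pset = toy_model_bn
        with pytest.raises(ValueError):
            local_train(model, pset, np.empty((0, 32, 32)), np.empty(0),
                        TrainConfig(), lr=0.01, rng=rng)

    def test_private_training_requires_locked_batch_norm(self, rng):
        model, pset = build_model(ModelConfig(freezing="none"))
        with pytest.raises(ValueError):
            local_train(model, pset, rng.random((2, 32, 32)),
                        np.array([0., 1.]), TrainConfig(), lr=0.01, rng=rng,
                        dp_hook=lambda g: g)


class TestFederatedAverage:
    def test_single_client_is_identity(self, toy_model_bn):
        _, pset = toy_model_bn
        out = federated_average([(pset, 7)])
        for name in pset.names:
            assert np.array_equal(out[name].array, pset[name].array)

    def test_weighted_mean_value(self, toy_model_bn):
        _, pset = toy_model_bn
        a, b = pset.copy(), pset.copy()
        for e in a:
            e.array = np.zeros_like(e.array)
        for e in b:
            e.array = np.full_like(e.array, 4.0)
        out = federated_average([(a, 1), (b, 3)])
        for name in out.names:
            assert np.allclose(out[name].array, 3.0)

    def test_identical_clients_stay_identical(self, toy_model_bn):
        _, pset = toy_model_bn
        out = federated_average([(pset.copy(), 2), (pset.copy(), 9)])
        for name in pset.names:
            assert np.allclose(out[name].array, pset[name].array)

    def test_mean_is_elementwise_within_client_range(self, toy_model_bn,
                                                     rng):
        _, pset = toy_model_bn
        clients = []
        for k in range(3):
            ps = pset.copy()
            for e in ps:
                e.array = rng.normal(size=e.array.shape)
            clients.append((ps, k + 1))
        out = federated_average(clients)
        for name in out.names:
            stack = np.stack([ps[name].array for ps, _ in clients])
            assert np.all(out[name].array >= stack.min(axis=0) - 1e-12)
            assert np.all(out[name].array <= stack.max(axis=0) + 1e-12)

    def test_empty_or_incongruent_inputs_rejected(self, toy_model_bn):
        _, pset = toy_model_bn
        with pytest.raises(ValueError):
            federated_average([])


class TestSelectClients:
    def test_fraction_03_of_36_selects_eleven(self, rng):
        chosen = select_clients(36, 0.3, [None] * 36, rng)
        assert len(chosen) == 11
        assert len(set(chosen)) == 11

    def test_full_fraction_selects_everyone(self, rng):
        assert select_clients(5, 1.0, [None] * 5, rng) == [0, 1, 2, 3, 4]

    def test_quota_limits_participation(self):
        rng = np.random.default_rng(3)
        quota = [5] * 10
        counts = np.zeros(10, int)
        for _ in range(10):
            for i in select_clients(10, 0.3, quota, rng):
                counts[i] += 1
        assert counts.max() <= 5

    def test_exhausted_quota_raises(self, rng):
        with pytest.raises(ValueError):
            select_clients(3, 0.5, [0, 0, 0], rng)


class TestRunFederation:
    def test_single_round_produces_single_record(self,
                                                 six_client_federation):
        layout, data = six_client_federation
        model, pset = build_model(ModelConfig(freezing="batch_norm"), 0)
        result = run_federation(layout, data, model, pset,
                                TrainConfig(max_rounds=1), seed=0)
        assert len(result.history) == 1
        rec = result.history[0]
        assert set(rec.deltas) == {c.client_id for c in layout.clients}

    def test_learns_separable_synthetic_task(self, six_client_federation):
        """Ten rounds on six small separable clients reach high mean AUC."""
        layout, data = six_client_federation
        model, pset = build_model(ModelConfig(freezing="batch_norm"), 0)
        result = run_federation(layout, data, model, pset,
                                TrainConfig(max_rounds=10), seed=1)
        assert result.best_mean_auc >= 0.9

    def test_replaying_deltas_reproduces_globals_bitwise(self, rng):
        layout = sd.FederationLayout(clients=[
            sd.ClientSpec(f"r{i}", sd.PEDIATRIC, 10, 4, 3, 3)
            for i in range(3)], seed=0)
        data = sd.generate_images(layout, 32, seed=2)
        model, pset = build_model(ModelConfig(freezing="batch_norm"), 0)
        result = run_federation(layout, data, model, pset,
                                TrainConfig(max_rounds=3), seed=5,
                                record_globals=True)
        prev = pset
        for rec, stored in zip(result.history, result.global_snapshots):
            rebuilt = []
            for cid, delta in rec.deltas.items():
                ps = prev.copy()
                for name, d in delta.items():
                    ps[name].array = ps[name].array - d
                for name, b in rec.buffers[cid].items():
                    ps[name].array = b.copy()
                rebuilt.append((ps, rec.train_sizes[cid]))
            replayed = federated_average(rebuilt)
            for name in replayed.names:
                assert np.array_equal(replayed[name].array,
                                      stored[name].array)
            prev = stored

    def test_single_client_matches_centralized_sgd(self):
        layout = sd.FederationLayout(clients=[
            sd.ClientSpec("solo", sd.ADULT, 30, 10, 10, 10)], seed=0)
        data = sd.generate_images(layout, 32, seed=3)
        model, pset = build_model(ModelConfig(freezing="batch_norm"), 0)
        fed = run_federation(layout, data, model, pset,
                             TrainConfig(max_rounds=3), seed=9)

        # centralized: same data order stream, same schedule
        ss = np.random.SeedSequence(9)
        ss.spawn(2)                      # selection / order streams unused
        client_rng = np.random.default_rng(ss.spawn(1)[0])
        X, y = client_arrays(data, "solo")
        params = pset.copy()
        for _ in range(3):
            params, _ = local_train(model, params, X, y, TrainConfig(),
                                    lr=0.01, rng=client_rng)
        for name in params.names:
            assert np.allclose(params[name].array,
                               fed.final_params[name].array, atol=1e-12)

    def test_learning_rate_nonincreasing_and_plateau_driven(
            self, six_client_federation):
        layout, data = six_client_federation
        model, pset = build_model(ModelConfig(freezing="batch_norm"), 0)
        result = run_federation(layout, data, model, pset,
                                TrainConfig(max_rounds=12), seed=1)
        lrs = [rec.lr for rec in result.history]
        assert all(a >= b for a, b in zip(lrs, lrs[1:]))

    def test_best_model_is_earliest_on_ties(self, six_client_federation):
        layout, data = six_client_federation
        model, pset = build_model(ModelConfig(freezing="batch_norm"), 0)
        result = run_federation(layout, data, model, pset,
                                TrainConfig(max_rounds=5), seed=1)
        aucs = [rec.mean_auc for rec in result.history]
        assert result.best_round == int(np.argmax(aucs))
        assert result.best_mean_auc == max(aucs)
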