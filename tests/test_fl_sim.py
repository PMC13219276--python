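"""Federated loop contracts on miniature runs: determinism, degenerate
federation, strategy reduction, history integrity, and partition identity
across strategies."""

from dataclasses import replace

import numpy as np
import pytest

from adaclassfl.aggregation import ClientRoundStats
from adaclassfl.fl_sim import (ClientData, FederatedConfig, local_train,
                               run_federated, _prepare_clients,
                               _stratified_split, compare_strategies)
from adaclassfl.hybrid_models import HybridConfig, build_hybrid
from adaclassfl.partitioning import class_weights
from adaclassfl.synthetic_data import LabeledDataset, SyntheticSpec, generate_dataset


def mini_cfg(**over):
    """4 clients, 4 rounds, 16-px images: seconds-scale run."""
    base = dict(
        n_clients=4, rounds=4, local_epochs=1, seed=0,
        model=HybridConfig(attention_channels=16, n_heads=2, input_size=16),
        apply_preprocess=False, apply_augment=False, eval_every=4,
    )
    base.update(over)
    return FederatedConfig(**base)


@pytest.fixture(scope="module")
def mini_dataset():
    return generate_dataset(SyntheticSpec(n_samples=120, image_size=16, seed=5))


class TestLocalTrain:
    def make_client(self, rng, n=24, C=3):
        imgs = rng.integers(0, 256, (n, 16, 16, 3), dtype=np.uint8)
        labels = rng.integers(0, C, n)
        return ClientData(imgs[:-6], labels[:-6], imgs[-6:], labels[-6:], C)

    def test_zero_epochs_leaves_params_unchanged(self, rng):
        cfg = mini_cfg(local_epochs=0)
        model = build_hybrid(replace(cfg.model, n_classes=3))
        params = model.state_dict()
        client = self.make_client(rng)
        new, stats = local_train(params, client, cfg, model, 1,
                                 np.random.default_rng(0), np.ones(3))
        for k in params:
            np.testing.assert_array_equal(new[k], params[k])
        assert stats.n_samples == client.n_local
        assert stats.f1.shape == (3,)

    def test_deterministic_given_seed(self, rng):
        cfg = mini_cfg()
        model = build_hybrid(replace(cfg.model, n_classes=3))
        params = model.state_dict()
        client = self.make_client(rng)
        a, _ = local_train(params, client, cfg, model, 1,
                           np.random.default_rng(42), np.ones(3))
        b, _ = local_train(params, client, cfg, model, 1,
                           np.random.default_rng(42), np.ones(3))
        for k in a:
            np.testing.assert_array_equal(a[k], b[k])

    def test_training_reduces_local_loss(self):
        """On easy synthetic data one epoch of local training lowers the
        training loss for a majority of 3 seeds."""
        from adaclassfl.nn import Tensor, softmax_cross_entropy
        from adaclassfl.fl_sim import _to_batch
        wins = 0
        for seed in (0, 1, 2):
            ds = generate_dataset(SyntheticSpec(n_samples=60, image_size=16,
                                                seed=seed))
            cfg = mini_cfg(local_epochs=1)
            model = build_hybrid(replace(cfg.model, n_classes=7, seed=seed))
            params = model.state_dict()
            client = ClientData(ds.images[:48], ds.labels[:48],
                                ds.images[48:], ds.labels[48:], 7)

            def loss_of(state):
                model.load_state_dict(state)
                model.eval()
                return float(softmax_cross_entropy(
                    model(Tensor(_to_batch(client.train_images))),
                    client.train_labels).data)

            before = loss_of(params)
            new, _ = local_train(params, client, cfg, model, 1,
                                 np.random.default_rng(seed), np.ones(7))
            wins += int(loss_of(new) < before)
        assert wins >= 2


class TestRunFederated:
    def test_reproducible_history(self, mini_dataset):
        cfg = mini_cfg()
        _, h1 = run_federated(cfg, mini_dataset)
        _, h2 = run_federated(cfg, mini_dataset)
        for a, b in zip(h1.records, h2.records):
            np.testing.assert_array_equal(a.weights, b.weights)
            assert a.accuracy == b.accuracy

    def test_history_complete_and_normalized(self, mini_dataset):
        cfg = mini_cfg(strategy="adaclass")
        _, hist = run_federated(cfg, mini_dataset)
        assert len(hist) == cfg.rounds
        for rec in hist.records:
            assert rec.weights.sum() == pytest.approx(1.0)
        assert hist.records[-1].accuracy is not None

    def test_adaclass_warmup_records_data_proportional_weights(self, mini_dataset):
        cfg = mini_cfg(rounds=4, strategy="adaclass")
        _, hist = run_federated(cfg, mini_dataset)
        cfg_avg = replace(cfg, strategy="fedavg")
        _, hist_avg = run_federated(cfg_avg, mini_dataset)
        for r in range(cfg.adaclass.r_warmup):
            np.testing.assert_array_equal(hist.records[r].weights,
                                          hist_avg.records[r].weights)

    def test_adaclass_reduction_to_fedavg_weights(self, mini_dataset):
        """alpha=1, beta=0, w_min=0: adaptive weights equal the FedAvg run's
        at every round on the same seed."""
        from adaclassfl.aggregation import AdaClassConfig
        cfg = mini_cfg(strategy="adaclass",
                       adaclass=AdaClassConfig(alpha=1.0, beta=0.0, w_min=0.0))
        _, hist = run_federated(cfg, mini_dataset)
        _, hist_avg = run_federated(replace(cfg, strategy="fedavg"), mini_dataset)
        for a, b in zip(hist.records, hist_avg.records):
            np.testing.assert_allclose(a.weights, b.weights, atol=1e-12)

    def test_single_client_equals_sequential_local_training(self, mini_dataset):
        """K=1 federation: the trajectory matches round-by-round local
        training of the same model on that client's data."""
        cfg = mini_cfg(n_clients=1, rounds=2)
        final, _ = run_federated(cfg, mini_dataset)

        # replicate: same preprocessing path (disabled), same splits
        split_rng = np.random.default_rng([cfg.seed, 557])
        train_idx, _ = _stratified_split(mini_dataset.labels,
                                         cfg.test_fraction, split_rng)
        clients = _prepare_clients(mini_dataset, cfg, train_idx)
        counts = np.bincount(mini_dataset.labels[train_idx],
                             minlength=mini_dataset.n_classes)
        loss_w = class_weights(np.maximum(counts, 1)).weights
        seed_model = int(np.random.default_rng([cfg.seed, 11]).integers(2**31))
        model = build_hybrid(replace(cfg.model, n_classes=7, input_size=16,
                                     seed=seed_model))
        state = model.state_dict()
        for r in (1, 2):
            state, _ = local_train(state, clients[0], cfg, model, r,
                                   np.random.default_rng([cfg.seed, r, 0]),
                                   loss_w)
        for k in final:
            np.testing.assert_allclose(final[k], state[k], atol=1e-12)

    def test_partition_identical_across_strategies(self, mini_dataset):
        cfg = mini_cfg()
        split_rng = np.random.default_rng([cfg.seed, 557])
        train_idx, _ = _stratified_split(mini_dataset.labels,
                                         cfg.test_fraction, split_rng)
        base = _prepare_clients(mini_dataset, cfg, train_idx)
        for strat in ("fedprox", "feddyn", "adaclass"):
            other = _prepare_clients(mini_dataset, replace(cfg, strategy=strat),
                                     train_idx)
            for a, b in zip(base, other):
                np.testing.assert_array_equal(a.train_labels, b.train_labels)
                np.testing.assert_array_equal(a.train_images, b.train_images)

    def test_all_strategies_run(self, mini_dataset):
        for strat in ("fedavg", "fedprox", "feddyn", "adaclass"):
            cfg = mini_cfg(strategy=strat, rounds=2, eval_every=2)
            _, hist = run_federated(cfg, mini_dataset)
            assert len(hist) == 2

    def test_config_validation(self, mini_dataset):
        with pytest.raises(ValueError):
            mini_cfg(strategy="magic").validate()
        with pytest.raises(ValueError):
            run_federated(mini_cfg(), LabeledDataset(
                mini_dataset.images[:2], mini_dataset.labels[:2], 7))


class TestCompareStrategies:
    def test_summary_and_effect_sizes(self, mini_dataset):
        cfg = mini_cfg(rounds=2, eval_every=2)
        table, effects = compare_strategies(cfg, mini_dataset,
                                            ["fedavg", "adaclass"], [0, 1])
        # summary means are plain arithmetic means of per-seed finals
        accs = table[(table.strategy == "fedavg")
                     & (table.metric == "accuracy")]
        assert len(accs) == 1
        assert ("adaclass", "fedavg") in effects
        rep = effects[("adaclass", "fedavg")]
        assert rep.n_pairs == 2

    def test_requires_two_seeds_and_strategies(self, mini_dataset):
        with pytest.raises(ValueError):
            compare_strategies(mini_cfg(), mini_dataset, ["fedavg"], [0, 1])
        with pytest.raises(ValueError):
            compare_strategies(mini_cfg(), mini_dataset,
                               ["fedavg", "adaclass"], [0])
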