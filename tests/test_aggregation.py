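"""Aggregation-rule unit and property tests, checked against an independent
scalar transcription of the weighting pipeline."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from adaclassfl.aggregation import (
    AdaClassConfig, AggregationState, ClientRoundStats, FedDynServerState,
    adaclass_round_weights, combine_weights, confidence_weighted_f1,
    fedavg_weights, feddyn_penalty, feddyn_server_step,
    feddyn_update_client_state, fedprox_penalty, floor_and_normalize,
    momentum_smooth, perf_softmax, performance_scores, struggling_classes,
    weighted_average,
)
from _oracles import adaclass_scalar, interpolated_percentile
from conftest import random_round_stats


def stats_fixture():
    """3 clients, 4 classes, full availability, hand-set F1 values."""
    return [
        ClientRoundStats(0, 100, np.array([0.9, 0.8, 0.5, 0.6]), np.ones(4, bool)),
        ClientRoundStats(1, 300, np.array([0.7, 0.9, 0.4, 0.8]), np.ones(4, bool)),
        ClientRoundStats(2, 50, np.array([0.6, 0.6, 0.9, 0.7]), np.ones(4, bool)),
    ]


class TestComponents:
    def test_fedavg_weights(self):
        np.testing.assert_allclose(fedavg_weights([100, 100]), [0.5, 0.5])
        np.testing.assert_allclose(fedavg_weights([0, 50]), [0.0, 1.0])
        np.testing.assert_allclose(fedavg_weights([1140, 2575, 830]),
                                   np.array([1140, 2575, 830]) / 4545.0)
        with pytest.raises(ValueError):
            fedavg_weights([0, 0])

    def test_weighted_average(self):
        p = [{"a": np.array([0.0])}, {"a": np.array([1.0])}]
        assert weighted_average(p, [0.25, 0.75])["a"][0] == pytest.approx(0.75)
        assert weighted_average(p, [0.0, 1.0])["a"][0] == 1.0
        same = [{"a": np.arange(3.0)}] * 2
        np.testing.assert_array_equal(weighted_average(same, [0.5, 0.5])["a"],
                                      np.arange(3.0))

    def test_confidence_weighted_f1(self):
        s = [ClientRoundStats(0, 100, np.array([0.8]), np.ones(1, bool)),
             ClientRoundStats(1, 300, np.array([0.4]), np.ones(1, bool))]
        assert confidence_weighted_f1(s)[0] == pytest.approx(0.25 * 0.8 + 0.75 * 0.4)
        one = [ClientRoundStats(0, 10, np.array([0.3, 0.7]), np.ones(2, bool))]
        np.testing.assert_allclose(confidence_weighted_f1(one), [0.3, 0.7])

    def test_struggling_classes_interpolated_percentile(self):
        fbar = np.array([0.9, 0.8, 0.7, 0.6])
        assert interpolated_percentile(fbar, 0.25) == pytest.approx(0.675)
        assert struggling_classes(fbar, 0.25) == {3}

    def test_struggling_all_equal_gives_empty(self):
        assert struggling_classes(np.full(7, 0.5), 0.25) == set()

    def test_struggling_seven_distinct_flags_one_or_two(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            fbar = rng.permutation(np.linspace(0.3, 0.95, 7))
            assert len(struggling_classes(fbar, 0.25)) in (1, 2)

    def test_performance_scores(self):
        s = [ClientRoundStats(0, 10, np.array([0.5, 0.9]), np.ones(2, bool))]
        # f_low = 0.5 (class 0 struggling), f_overall = 0.7
        assert performance_scores(s, {0})[0] == pytest.approx(0.4 * 0.5 + 0.6 * 0.7)
        # no samples in the struggling set -> overall only
        s2 = [ClientRoundStats(0, 10, np.array([0.0, 0.9]),
                               np.array([False, True]))]
        assert performance_scores(s2, {0})[0] == pytest.approx(0.9)
        # empty struggling set -> overall for everyone
        assert performance_scores(s, set())[0] == pytest.approx(0.7)

    def test_perf_softmax(self):
        np.testing.assert_allclose(perf_softmax(np.array([0.3, 0.3]), 2.0),
                                   [0.5, 0.5])
        w = perf_softmax(np.array([0.5, 0.9]), 2.0)
        expect = np.exp([0.25, 0.45]) / np.exp([0.25, 0.45]).sum()
        np.testing.assert_allclose(w, expect)
        big_t = perf_softmax(np.array([0.1, 0.9]), 1e6)
        np.testing.assert_allclose(big_t, [0.5, 0.5], atol=1e-6)

    def test_combine_weights(self):
        wd, wp = np.array([0.8, 0.2]), np.array([0.5, 0.5])
        np.testing.assert_allclose(combine_weights(wd, wp, 1.0), wd)
        np.testing.assert_allclose(combine_weights(wd, wp, 0.0), wp)
        np.testing.assert_allclose(combine_weights(wd, wp, 0.7), [0.71, 0.29])

    def test_momentum_smooth(self):
        w = np.array([0.6, 0.4])
        prev = AggregationState(round=5, w_prev=np.array([0.2, 0.8]))
        np.testing.assert_allclose(momentum_smooth(w, prev, 0.0), w)
        np.testing.assert_allclose(
            momentum_smooth(w, AggregationState(5, w.copy()), 0.3), w)
        out = momentum_smooth(w, prev, 0.3)
        for o, a, b in zip(out, w, prev.w_prev):
            assert min(a, b) <= o <= max(a, b)
        # absent previous weights: unchanged
        np.testing.assert_allclose(
            momentum_smooth(w, AggregationState(4, None), 0.3), w)

    def test_floor_and_normalize(self):
        np.testing.assert_allclose(
            floor_and_normalize(np.array([0.5, 0.5]), 0.05), [0.5, 0.5])
        out = floor_and_normalize(np.array([0.01, 0.99]), 0.05)
        np.testing.assert_allclose(out, np.array([0.05, 0.99]) / 1.04)
        np.testing.assert_allclose(
            floor_and_normalize(np.full(4, 0.25), 0.05), np.full(4, 0.25))
        with pytest.raises(ValueError):
            floor_and_normalize(np.array([0.5, 0.5]), 0.6)

    def test_fedprox_penalty(self):
        t = {"w": np.array([1.0])}
        g = {"w": np.array([0.0])}
        assert fedprox_penalty(t, t, 0.01) == 0.0
        assert fedprox_penalty(t, g, 0.0) == 0.0
        assert fedprox_penalty(t, g, 0.01) == pytest.approx(0.005)


class TestAdaClassRound:
    def test_warmup_is_exact_fedavg(self):
        cfg = AdaClassConfig()
        stats = stats_fixture()
        st_ = AggregationState(round=1)
        n = np.array([s.n_samples for s in stats], float)
        for r in range(1, cfg.r_warmup + 1):
            w, st_, low = adaclass_round_weights(stats, st_, cfg)
            np.testing.assert_array_equal(w, n / n.sum())
            assert low == set()
        assert st_.round == cfg.r_warmup + 1
        assert st_.w_prev is None

    def test_first_adaptive_round_matches_scalar_oracle(self):
        cfg = AdaClassConfig()
        stats = stats_fixture()
        w, _, low = adaclass_round_weights(stats, AggregationState(round=4), cfg)
        expect, low_expect = adaclass_scalar(
            [s.n_samples for s in stats], [s.f1.tolist() for s in stats],
            [s.available.tolist() for s in stats])
        np.testing.assert_allclose(w, expect, atol=1e-12)
        assert low == low_expect

    def test_oracle_equivalence_100_random_fixtures(self, rng):
        """Two adaptive rounds per fixture, including momentum, against the
        independent scalar transcription."""
        cfg = AdaClassConfig()
        for _ in range(100):
            stats = random_round_stats(rng, int(rng.integers(2, 8)),
                                       int(rng.integers(2, 8)))
            st_ = AggregationState(round=cfg.r_warmup + 1)
            w1, st_, _ = adaclass_round_weights(stats, st_, cfg)
            e1, _ = adaclass_scalar([s.n_samples for s in stats],
                                    [s.f1.tolist() for s in stats],
                                    [s.available.tolist() for s in stats])
            np.testing.assert_allclose(w1, e1, atol=1e-10)
            w2, st_, _ = adaclass_round_weights(stats, st_, cfg)
            e2, _ = adaclass_scalar([s.n_samples for s in stats],
                                    [s.f1.tolist() for s in stats],
                                    [s.available.tolist() for s in stats],
                                    w_prev=e1)
            np.testing.assert_allclose(w2, e2, atol=1e-10)

    def test_identical_clients_get_uniform_weights(self):
        f1 = np.array([0.8, 0.6, 0.9])
        stats = [ClientRoundStats(i, 200, f1.copy(), np.ones(3, bool))
                 for i in range(4)]
        w, _, _ = adaclass_round_weights(stats, AggregationState(round=4),
                                         AdaClassConfig())
        np.testing.assert_allclose(w, np.full(4, 0.25))

    def test_reduces_to_fedavg(self, rng):
        """alpha=1, beta=0, w_min=0 collapses the adaptive rule onto plain
        data-proportional weighting for every round and fixture."""
        cfg = AdaClassConfig(alpha=1.0, beta=0.0, w_min=0.0)
        for _ in range(20):
            stats = random_round_stats(rng, 6, 5)
            st_ = AggregationState(round=1)
            n = np.array([s.n_samples for s in stats], float)
            for _ in range(6):
                w, st_, _ = adaclass_round_weights(stats, st_, cfg)
                np.testing.assert_allclose(w, n / n.sum(), atol=1e-12)

    def test_weights_normalized_and_nonnegative(self, rng):
        cfg = AdaClassConfig()
        for _ in range(100):
            stats = random_round_stats(rng, int(rng.integers(2, 12)),
                                       int(rng.integers(2, 8)))
            w, _, _ = adaclass_round_weights(stats,
                                             AggregationState(round=5), cfg)
            assert abs(w.sum() - 1.0) < 1e-9
            assert (w >= 0).all()

    def test_raising_f1_on_struggling_class_never_lowers_weight(self, rng):
        cfg = AdaClassConfig()
        for _ in range(30):
            stats = random_round_stats(rng, 5, 6)
            w0, _, low = adaclass_round_weights(
                stats, AggregationState(round=4), cfg)
            if not low:
                continue
            c = next(iter(low))
            target = next((s for s in stats if s.available[c]), None)
            if target is None:
                continue
            bumped = ClientRoundStats(
                target.client_id, target.n_samples,
                np.where(np.arange(6) == c,
                         np.minimum(target.f1 + 0.2, 1.0), target.f1),
                target.available)
            stats2 = [bumped if s is target else s for s in stats]
            w1, _, low1 = adaclass_round_weights(
                stats2, AggregationState(round=4), cfg)
            if low1 == low:     # flag set unchanged -> clean monotonicity
                i = stats.index(target)
                assert w1[i] >= w0[i] - 1e-12


class TestFedDyn:
    def one_param(self, v):
        return {"w": np.array([float(v)])}

    def test_zero_coefficient_reduces_to_plain_average(self):
        thetas = [self.one_param(1.0), self.one_param(3.0)]
        out, state = feddyn_server_step(thetas, self.one_param(0.0),
                                        FedDynServerState(), 0.0)
        assert out["w"][0] == pytest.approx(2.0)
        assert state.h["w"][0] == 0.0

    def test_scalar_recurrence_matches_oracle(self):
        alpha = 0.01
        theta_g = self.one_param(0.5)
        thetas = [self.one_param(1.0), self.one_param(2.0)]
        out, state = feddyn_server_step(thetas, theta_g,
                                        FedDynServerState(), alpha)
        mean = (1.0 + 2.0) / 2
        h = 0.0 - alpha * (mean - 0.5)
        assert state.h["w"][0] == pytest.approx(h)
        assert out["w"][0] == pytest.approx(mean - h / alpha)
        # client-side state recurrence
        h_i = feddyn_update_client_state(self.one_param(0.0),
                                         self.one_param(2.0), theta_g, alpha)
        assert h_i["w"][0] == pytest.approx(-alpha * 1.5)
        # penalty value: -<h, theta> + (alpha/2)||theta - theta_g||^2
        pen = feddyn_penalty(self.one_param(2.0), theta_g, h_i, alpha)
        assert pen == pytest.approx(-h_i["w"][0] * 2.0 + 0.5 * alpha * 1.5**2)

    def test_state_shapes_match_model(self):
        thetas = [{"a": np.zeros((2, 3)), "b": np.ones(4)} for _ in range(3)]
        _, state = feddyn_server_step(thetas, thetas[0],
                                      FedDynServerState(), 0.01)
        assert state.h["a"].shape == (2, 3) and state.h["b"].shape == (4,)


@settings(derandomize=True, max_examples=50)
@given(st.lists(st.floats(0.01, 1e6), min_size=2, max_size=10))
def test_fedavg_weights_always_normalized(ns):
    w = fedavg_weights(np.array(ns))
    assert abs(w.sum() - 1.0) < 1e-9
    assert (w >= 0).all()


def test_client_round_stats_validation():
    with pytest.raises(ValueError):
        ClientRoundStats(0, 10, np.array([0.5]), np.array([False]))
    with pytest.raises(ValueError):
        ClientRoundStats(0, 10, np.array([1.5]), np.array([True]))
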