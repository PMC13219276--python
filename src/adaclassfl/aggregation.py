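"""Server-side aggregation rules for federated training.

The centerpiece is AdaClass, a class-aware adaptive weighting scheme: after a
FedAvg warm-up, each round the server (1) forms a data-proportion-weighted
global per-class F1 estimate, (2) flags the bottom-percentile "struggling"
classes, (3) scores each client by blending its F1 on those classes (40%)
with its overall F1 (60%), (4) softmaxes the scores at temperature T,
(5) mixes the result with data-proportional weights at ratio alpha,
(6) smooths across rounds with EMA momentum beta, and (7) floors at w_min
and renormalizes.  FedAvg weighting and the FedProx / FedDyn client-side
objectives are provided alongside for comparison runs.

Model parameters travel as plain ``dict[str, np.ndarray]`` state dicts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AdaClassConfig", "ClientRoundStats", "AggregationState", "FedDynServerState",
    "fedavg_weights", "weighted_average", "confidence_weighted_f1",
    "struggling_classes", "performance_scores", "perf_softmax",
    "combine_weights", "momentum_smooth", "floor_and_normalize",
    "adaclass_round_weights", "fedprox_penalty",
    "feddyn_penalty", "feddyn_update_client_state", "feddyn_server_step",
]

ModelParameters = dict[str, np.ndarray]


@dataclass(frozen=True)
class AdaClassConfig:
    """Hyperparameters of the adaptive weighting rule.

    Defaults are the recommended operating point: alpha 0.7 keeps data
    reliability dominant, tau 0.25 flags the bottom quartile of classes
    (one to two classes out of seven), beta 0.3 smooths across rounds,
    temperature 2.0 spreads the performance softmax, w_min 0.05 keeps every
    client in play, and three warm-up rounds let F1 estimates stabilize.
    """

    alpha: float = 0.7
    tau: float = 0.25
    beta: float = 0.3
    temperature: float = 2.0
    w_min: float = 0.05
    r_warmup: int = 3

    def validate(self, n_clients: int | None = None) -> None:
        for name in ("alpha", "tau", "beta"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.w_min < 0:
            raise ValueError("w_min must be non-negative")
        if n_clients is not None and self.w_min * n_clients > 1.0 + 1e-12:
            raise ValueError("w_min * n_clients must not exceed 1")
        if self.r_warmup < 0:
            raise ValueError("r_warmup must be non-negative")


@dataclass
class ClientRoundStats:
    """One client's contribution to a round: local sample count and the
    per-class F1 vector measured on its local validation data, with a mask
    of which classes the client actually holds samples for."""

    client_id: int
    n_samples: int
    f1: np.ndarray
    available: np.ndarray

    def __post_init__(self):
        self.f1 = np.asarray(self.f1, float)
        self.available = np.asarray(self.available, bool)
        if self.f1.shape != self.available.shape:
            raise ValueError("f1 and availability mask must have equal length")
        if ((~self.available) & (self.f1 != 0)).any():
            raise ValueError("unavailable classes must carry F1 = 0")
        if ((self.f1 < 0) | (self.f1 > 1)).any():
            raise ValueError("F1 values must lie in [0, 1]")


@dataclass
class AggregationState:
    """Carried between rounds: the 1-based round counter and the previous
    weight vector (absent until the first adaptive round has produced one)."""

    round: int = 1
    w_prev: np.ndarray | None = None


def fedavg_weights(n: np.ndarray) -> np.ndarray:
    n = np.asarray(n, float)
    if (n < 0).any():
        raise ValueError("sample counts must be non-negative")
    total = n.sum()
    if total <= 0:
        raise ValueError("at least one client must hold samples")
    return n / total


def weighted_average(params: list[ModelParameters], w: np.ndarray) -> ModelParameters:
    w = np.asarray(w, float)
    if len(params) != len(w):
        raise ValueError("one weight per client required")
    keys = params[0].keys()
    for p in params[1:]:
        if p.keys() != keys:
            raise ValueError("clients must share parameter names")
    out: ModelParameters = {}
    for k in keys:
        acc = np.zeros_like(np.asarray(params[0][k], float))
        for wi, p in zip(w, params):
            acc += wi * np.asarray(p[k], float)
        out[k] = acc
    return out


def confidence_weighted_f1(stats: list[ClientRoundStats]) -> np.ndarray:
    """Global per-class F1 estimate: clients vote in proportion to their
    local sample counts."""
    n = np.array([s.n_samples for s in stats], float)
    N = n.sum()
    if N <= 0:
        raise ValueError("total sample count must be positive")
    f1 = np.stack([s.f1 for s in stats])
    return (n[:, None] / N * f1).sum(axis=0)


def struggling_classes(f_bar: np.ndarray, tau: float) -> set[int]:
    """Classes whose global F1 falls at or below the tau-percentile
    (linear interpolation between order statistics).  When every class
    performs identically there is nothing to single out: empty set."""
    f_bar = np.asarray(f_bar, float)
    if f_bar.size == 0:
        raise ValueError("need at least one class")
    if np.ptp(f_bar) == 0:
        return set()
    thresh = np.percentile(f_bar, 100.0 * tau)
    return {int(c) for c in np.flatnonzero(f_bar <= thresh)}


def performance_scores(stats: list[ClientRoundStats], low: set[int]) -> np.ndarray:
    """Blend of a client's mean F1 on the struggling classes it holds (40%)
    and its mean F1 over all classes it holds (60%); clients without samples
    in any struggling class are scored on overall F1 alone."""
    scores = np.empty(len(stats))
    for i, s in enumerate(stats):
        if not s.available.any():
            raise ValueError(f"client {s.client_id} has no available classes")
        f_overall = s.f1[s.available].mean()
        in_low = [c for c in low if s.available[c]]
        if in_low:
            f_low = s.f1[list(in_low)].mean()
            scores[i] = 0.4 * f_low + 0.6 * f_overall
        else:
            scores[i] = f_overall
    return scores


def perf_softmax(p: np.ndarray, temperature: float) -> np.ndarray:
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    z = np.asarray(p, float) / temperature
    e = np.exp(z - z.max())
    return e / e.sum()


def combine_weights(w_data: np.ndarray, w_perf: np.ndarray, alpha: float) -> np.ndarray:
    w_data, w_perf = np.asarray(w_data, float), np.asarray(w_perf, float)
    if w_data.shape != w_perf.shape:
        raise ValueError("weight vectors must have equal length")
    return alpha * w_data + (1.0 - alpha) * w_perf


def momentum_smooth(w: np.ndarray, state: AggregationState, beta: float) -> np.ndarray:
    if state.w_prev is None:
        return np.asarray(w, float)
    w_prev = np.asarray(state.w_prev, float)
    w = np.asarray(w, float)
    if w.shape != w_prev.shape:
        raise ValueError("weight vector length changed between rounds")
    return (1.0 - beta) * w + beta * w_prev


def floor_and_normalize(w: np.ndarray, w_min: float) -> np.ndarray:
    """Single clamp-then-normalize pass.  Renormalization may push a floored
    entry slightly below w_min again; that is accepted behavior."""
    w = np.asarray(w, float)
    if w_min * len(w) > 1.0 + 1e-12:
        raise ValueError("floor infeasible: w_min * n_clients exceeds 1")
    w = np.maximum(w, w_min)
    return w / w.sum()


def adaclass_round_weights(
    stats: list[ClientRoundStats],
    state: AggregationState,
    config: AdaClassConfig,
) -> tuple[np.ndarray, AggregationState, set[int]]:
    """One round of AdaClass weighting.

    Rounds 1..r_warmup return plain data-proportional (FedAvg) weights and
    leave the momentum state untouched; afterwards the seven-step adaptive
    composition runs, with EMA momentum active from the second adaptive
    round onward (no previous weights exist on the first).
    """
    config.validate(n_clients=len(stats))
    if state.round < 1:
        raise ValueError("round counter is 1-based")
    n = np.array([s.n_samples for s in stats], float)
    w_data = fedavg_weights(n)
    if state.round <= config.r_warmup:
        return w_data, AggregationState(round=state.round + 1, w_prev=state.w_prev), set()

    f_bar = confidence_weighted_f1(stats)
    low = struggling_classes(f_bar, config.tau)
    p = performance_scores(stats, low)
    w_perf = perf_softmax(p, config.temperature)
    w = combine_weights(w_data, w_perf, config.alpha)
    w = momentum_smooth(w, state, config.beta)
    w = floor_and_normalize(w, config.w_min)
    return w, AggregationState(round=state.round + 1, w_prev=w.copy()), low


# ---------------------------------------------------------------------------
# client-side objectives of the comparison strategies

def _check_shapes(a: ModelParameters, b: ModelParameters) -> None:
    if a.keys() != b.keys():
        raise ValueError("parameter name sets differ")
    for k in a:
        if np.shape(a[k]) != np.shape(b[k]):
            raise ValueError(f"shape mismatch for {k!r}")


def fedprox_penalty(theta: ModelParameters, theta_global: ModelParameters,
                    mu: float) -> float:
    """Proximal term (mu/2)||theta - theta_global||^2 added to the local loss."""
    _check_shapes(theta, theta_global)
    sq = sum(float(((np.asarray(theta[k], float) - np.asarray(theta_global[k], float)) ** 2).sum())
             for k in theta)
    return 0.5 * mu * sq


@dataclass
class FedDynServerState:
    """Running correction h maintained by the FedDyn server."""

    h: ModelParameters = field(default_factory=dict)

    def initialized_like(self, params: ModelParameters) -> "FedDynServerState":
        if not self.h:
            return FedDynServerState({k: np.zeros_like(np.asarray(v, float))
                                      for k, v in params.items()})
        return self


def feddyn_penalty(theta: ModelParameters, theta_global: ModelParameters,
                   h_i: ModelParameters, alpha_dyn: float) -> float:
    """FedDyn client regularizer: -<h_i, theta> + (alpha_dyn/2)||theta - theta_g||^2."""
    _check_shapes(theta, theta_global)
    _check_shapes(theta, h_i)
    lin = sum(float((np.asarray(h_i[k], float) * np.asarray(theta[k], float)).sum())
              for k in theta)
    quad = sum(float(((np.asarray(theta[k], float) - np.asarray(theta_global[k], float)) ** 2).sum())
               for k in theta)
    return -lin + 0.5 * alpha_dyn * quad


def feddyn_update_client_state(h_i: ModelParameters, theta_i: ModelParameters,
                               theta_global: ModelParameters,
                               alpha_dyn: float) -> ModelParameters:
    """h_i <- h_i - alpha_dyn (theta_i - theta_global), after local training."""
    _check_shapes(theta_i, theta_global)
    _check_shapes(theta_i, h_i)
    return {k: np.asarray(h_i[k], float)
            - alpha_dyn * (np.asarray(theta_i[k], float) - np.asarray(theta_global[k], float))
            for k in h_i}


def feddyn_server_step(client_params: list[ModelParameters],
                       theta_global: ModelParameters,
                       state: FedDynServerState,
                       alpha_dyn: float) -> tuple[ModelParameters, FedDynServerState]:
    """Average client models, update the running correction
    h <- h - alpha_dyn * mean(theta_i - theta_global), and apply
    theta <- mean(theta_i) - h / alpha_dyn.  With alpha_dyn = 0 this is
    exactly FedAvg with uniform weights."""
    m = len(client_params)
    mean = weighted_average(client_params, np.full(m, 1.0 / m))
    state = state.initialized_like(mean)
    new_h = {k: state.h[k] - alpha_dyn * (mean[k] - np.asarray(theta_global[k], float))
             for k in mean}
    if alpha_dyn > 0:
        theta = {k: mean[k] - new_h[k] / alpha_dyn for k in mean}
    else:
        theta = mean
    return theta, FedDynServerState(new_h)
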