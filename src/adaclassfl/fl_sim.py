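"""Federated training loop: broadcast, local training under the shared
optimizer protocol (AdamW, class-weighted cross-entropy, gradient clipping,
warm-up + step-decay schedule), per-client metric extraction, strategy-driven
aggregation, and round-by-round history logging.

Every source of randomness descends from the run seed; the Dirichlet client
partition depends only on that seed, so every aggregation strategy sees
byte-identical client datasets — the precondition for fair comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from sklearn.metrics import f1_score

from .aggregation import (
    AdaClassConfig, AggregationState, ClientRoundStats, FedDynServerState,
    ModelParameters, adaclass_round_weights, confidence_weighted_f1,
    fedavg_weights, feddyn_server_step, feddyn_update_client_state,
    weighted_average,
)
from .hybrid_models import HybridClassifier, HybridConfig, build_hybrid
from .imaging import AugmentConfig, PreprocessConfig, augment, preprocess
from .metrics import ClassificationReport, EffectSizeReport, classification_metrics, confusion, cohens_d_paired, rank_biserial
from .nn import AdamW, Tensor, clip_grad_norm, softmax_cross_entropy, warmup_step_lr
from .partitioning import class_weights, dirichlet_partition
from .synthetic_data import LabeledDataset, SyntheticSpec, generate_dataset

__all__ = [
    "FederatedConfig", "RoundRecord", "RoundHistory", "ClientData",
    "local_train", "run_federated", "compare_strategies", "evaluate_model",
]

STRATEGIES = ("fedavg", "fedprox", "feddyn", "adaclass")


@dataclass(frozen=True)
class FederatedConfig:
    n_clients: int = 10
    rounds: int = 18
    local_epochs: int = 2
    strategy: str = "adaclass"
    learning_rate: float = 1e-3
    weight_decay: float = 0.01
    train_batch: int = 32
    eval_batch: int = 64
    clip_norm: float = 1.0
    mu: float = 0.01                     # FedProx proximal coefficient
    alpha_dyn: float = 0.01              # FedDyn regularization coefficient
    adaclass: AdaClassConfig = field(default_factory=AdaClassConfig)
    dirichlet_alpha: float = 1.0
    val_fraction: float = 0.1
    test_fraction: float = 0.2
    seed: int = 0
    model: HybridConfig = field(default_factory=HybridConfig)
    apply_preprocess: bool = True
    apply_augment: bool = True
    augment_config: AugmentConfig = field(default_factory=AugmentConfig)
    preprocess_config: PreprocessConfig = field(default_factory=PreprocessConfig)
    eval_every: int = 1

    def validate(self) -> None:
        if self.rounds < 1 or self.n_clients < 1 or self.local_epochs < 0:
            raise ValueError("rounds >= 1, n_clients >= 1, local_epochs >= 0")
        if self.strategy not in STRATEGIES:
            raise ValueError(f"strategy must be one of {STRATEGIES}")
        self.adaclass.validate(self.n_clients)

    @classmethod
    def three_client_preset(cls, **over) -> "FederatedConfig":
        """The controlled low-heterogeneity setup: 3 clients, 30 rounds of one
        local epoch, Dirichlet alpha = 0.3."""
        base = dict(n_clients=3, rounds=30, local_epochs=1, dirichlet_alpha=0.3)
        base.update(over)
        return cls(**base)

    @classmethod
    def from_dict(cls, d: dict) -> "FederatedConfig":
        d = dict(d)
        if "adaclass" in d and isinstance(d["adaclass"], dict):
            d["adaclass"] = AdaClassConfig(**d["adaclass"])
        if "model" in d and isinstance(d["model"], dict):
            d["model"] = HybridConfig(**d["model"])
        if "augment_config" in d and isinstance(d["augment_config"], dict):
            d["augment_config"] = AugmentConfig(**d["augment_config"])
        if "preprocess_config" in d and isinstance(d["preprocess_config"], dict):
            d["preprocess_config"] = PreprocessConfig(**d["preprocess_config"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "FederatedConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})


@dataclass
class ClientData:
    train_images: np.ndarray
    train_labels: np.ndarray
    val_images: np.ndarray
    val_labels: np.ndarray
    n_classes: int

    @property
    def n_local(self) -> int:
        return len(self.train_labels) + len(self.val_labels)

    @property
    def availability(self) -> np.ndarray:
        counts = (np.bincount(self.train_labels, minlength=self.n_classes)
                  + np.bincount(self.val_labels, minlength=self.n_classes))
        return counts > 0


@dataclass
class RoundRecord:
    round: int
    weights: np.ndarray
    struggling: tuple[int, ...]
    f_bar: np.ndarray                   # confidence-weighted global per-class F1
    accuracy: float | None
    macro_f1: float | None
    weighted_f1: float | None
    per_class_f1: np.ndarray | None


@dataclass
class RoundHistory:
    records: list[RoundRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def weights_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            for cid, w in enumerate(r.weights):
                rows.append({"round": r.round, "client": cid, "weight": w,
                             "struggling_classes": ";".join(map(str, r.struggling))})
        return pd.DataFrame(rows)

    def metrics_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "round": r.round, "accuracy": r.accuracy, "macro_f1": r.macro_f1,
            "weighted_f1": r.weighted_f1,
        } for r in self.records])

    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.metrics_frame().to_csv(out / "history.csv", index=False)
        self.weights_frame().to_csv(out / "weights.csv", index=False)


# ---------------------------------------------------------------------------

def _to_batch(images: np.ndarray) -> np.ndarray:
    """uint8 HWC images -> float CHW in [-1, 1]."""
    x = images.astype(np.float64) / 255.0
    return ((x - 0.5) / 0.5).transpose(0, 3, 1, 2)


def _forward_logits(model: HybridClassifier, images: np.ndarray,
                    batch: int) -> np.ndarray:
    outs = []
    for i in range(0, len(images), batch):
        outs.append(model(Tensor(_to_batch(images[i:i + batch]))).data)
    return np.concatenate(outs, axis=0)


def evaluate_model(model: HybridClassifier, images: np.ndarray,
                   labels: np.ndarray, n_classes: int,
                   batch: int = 64) -> tuple[ClassificationReport, np.ndarray]:
    """Deterministic evaluation pass; returns the metric report and the
    per-sample softmax score matrix."""
    model.eval()
    logits = _forward_logits(model, images, batch)
    z = logits - logits.max(axis=1, keepdims=True)
    scores = np.exp(z) / np.exp(z).sum(axis=1, keepdims=True)
    pred = logits.argmax(axis=1)
    report = classification_metrics(confusion(labels, pred, n_classes))
    return report, scores


def _round_lr(config: FederatedConfig, round_idx: int, epoch_idx: int) -> float:
    step = (round_idx - 1) * max(config.local_epochs, 1) + epoch_idx
    total = config.rounds * max(config.local_epochs, 1)
    return warmup_step_lr(config.learning_rate, step, total)


def local_train(
    params: ModelParameters,
    client: ClientData,
    config: FederatedConfig,
    model: HybridClassifier,
    round_idx: int,
    rng: np.random.Generator,
    loss_class_weights: np.ndarray,
    h_i: ModelParameters | None = None,
) -> tuple[ModelParameters, ClientRoundStats]:
    """Train the broadcast model on one client for ``local_epochs`` epochs and
    measure per-class F1 on the client's local validation split.

    FedProx / FedDyn penalties enter through their exact parameter-space
    gradients (mu(theta - theta_g), and -h_i + alpha_dyn(theta - theta_g)),
    added before clipping.
    """
    if client.n_local == 0:
        raise ValueError("client holds no samples")
    model.load_state_dict(params)
    trainable = dict(model.named_parameters())
    global_ref = {k: params[k].copy() for k in trainable}

    if config.local_epochs > 0 and len(client.train_labels) > 0:
        model.train()
        model.dropout.set_rng(rng)
        opt = AdamW(model.parameters(), lr=config.learning_rate,
                    weight_decay=config.weight_decay)
        n = len(client.train_labels)
        for epoch in range(config.local_epochs):
            opt.lr = _round_lr(config, round_idx, epoch)
            order = rng.permutation(n)
            for s in range(0, n, config.train_batch):
                idx = order[s:s + config.train_batch]
                imgs = client.train_images[idx]
                if config.apply_augment:
                    imgs = np.stack([augment(im, config.augment_config, rng)
                                     for im in imgs])
                logits = model(Tensor(_to_batch(imgs)))
                loss = softmax_cross_entropy(logits, client.train_labels[idx],
                                             loss_class_weights)
                model.zero_grad()
                loss.backward()
                for name, p in trainable.items():
                    if config.strategy == "fedprox":
                        p.grad = (0.0 if p.grad is None else p.grad) \
                            + config.mu * (p.data - global_ref[name])
                    elif config.strategy == "feddyn" and h_i is not None:
                        p.grad = (0.0 if p.grad is None else p.grad) \
                            - h_i[name] \
                            + config.alpha_dyn * (p.data - global_ref[name])
                clip_grad_norm(model.parameters(), config.clip_norm)
                opt.step()

    # per-class F1 on the local validation split (train split if val empty)
    model.eval()
    v_imgs, v_labs = client.val_images, client.val_labels
    if len(v_labs) == 0:
        v_imgs, v_labs = client.train_images, client.train_labels
    logits = _forward_logits(model, v_imgs, config.eval_batch)
    pred = logits.argmax(axis=1)
    f1 = f1_score(v_labs, pred, labels=np.arange(client.n_classes),
                  average=None, zero_division=0)
    avail = client.availability
    f1 = np.where(avail, f1, 0.0)
    stats = ClientRoundStats(client_id=-1, n_samples=client.n_local,
                             f1=f1, available=avail)
    return model.state_dict(), stats


def _stratified_split(labels: np.ndarray, fraction: float,
                      rng: np.random.Generator,
                      min_per_class: int = 1) -> tuple[np.ndarray, np.ndarray]:
    """Indices (kept, held_out) with at least ``min_per_class`` held out per
    present class."""
    held = []
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        idx = rng.permutation(idx)
        k = max(min_per_class, int(round(fraction * idx.size)))
        k = min(k, idx.size)
        held.append(idx[:k])
    held = np.concatenate(held)
    mask = np.ones(labels.size, bool)
    mask[held] = False
    return np.flatnonzero(mask), np.sort(held)


def _prepare_clients(dataset: LabeledDataset, config: FederatedConfig,
                     train_idx: np.ndarray) -> list[ClientData]:
    labels = dataset.labels[train_idx]
    plan = dirichlet_partition(labels, config.n_clients,
                               config.dirichlet_alpha, seed=config.seed)
    clients = []
    for cid in range(config.n_clients):
        local = train_idx[plan.client_indices(cid)]
        if local.size == 0:
            clients.append(ClientData(
                dataset.images[:0], np.empty(0, int),
                dataset.images[:0], np.empty(0, int), dataset.n_classes))
            continue
        loc_labels = dataset.labels[local]
        rng_split = np.random.default_rng([config.seed, 971, cid])
        keep, held = _stratified_split(loc_labels, config.val_fraction, rng_split)
        clients.append(ClientData(
            dataset.images[local[keep]], loc_labels[keep],
            dataset.images[local[held]], loc_labels[held], dataset.n_classes))
    return clients


def run_federated(config: FederatedConfig,
                  dataset: LabeledDataset) -> tuple[ModelParameters, RoundHistory]:
    """Run the full federated protocol and return the final-round global
    model state (no early stopping) plus the per-round history."""
    config.validate()
    if len(dataset) < config.n_clients:
        raise ValueError("dataset smaller than the number of clients")

    if config.apply_preprocess:
        images = np.stack([preprocess(im, config.preprocess_config)
                           for im in dataset.images])
        dataset = LabeledDataset(images, dataset.labels, dataset.n_classes)

    split_rng = np.random.default_rng([config.seed, 557])
    train_idx, test_idx = _stratified_split(dataset.labels,
                                            config.test_fraction, split_rng)
    test_images = dataset.images[test_idx]
    test_labels = dataset.labels[test_idx]

    clients = _prepare_clients(dataset, config, train_idx)
    active = [c for c in clients if c.n_local > 0]
    if not active:
        raise ValueError("infeasible partition: all clients empty")

    global_counts = np.bincount(dataset.labels[train_idx],
                                minlength=dataset.n_classes)
    loss_w = class_weights(np.maximum(global_counts, 1)).weights

    model_cfg = replace(config.model, n_classes=dataset.n_classes,
                        input_size=dataset.images.shape[1],
                        seed=int(np.random.default_rng([config.seed, 11]).integers(2**31)))
    model = build_hybrid(model_cfg)
    global_state = model.state_dict()
    trainable_keys = {name for name, _ in model.named_parameters()}

    agg_state = AggregationState(round=1)
    dyn_server = FedDynServerState()
    dyn_clients = [{k: np.zeros_like(global_state[k]) for k in trainable_keys}
                   for _ in clients]

    history = RoundHistory()
    for r in range(1, config.rounds + 1):
        states, stats = [], []
        for cid, client in enumerate(clients):
            if client.n_local == 0:
                continue
            rng_c = np.random.default_rng([config.seed, r, cid])
            h_i = dyn_clients[cid] if config.strategy == "feddyn" else None
            st, cs = local_train(global_state, client, config, model, r,
                                 rng_c, loss_w, h_i=h_i)
            cs.client_id = cid
            states.append(st)
            stats.append(cs)
            if config.strategy == "feddyn":
                theta_i = {k: st[k] for k in trainable_keys}
                theta_g = {k: global_state[k] for k in trainable_keys}
                dyn_clients[cid] = feddyn_update_client_state(
                    dyn_clients[cid], theta_i, theta_g, config.alpha_dyn)

        low: set[int] = set()
        if config.strategy == "adaclass":
            w, agg_state, low = adaclass_round_weights(stats, agg_state,
                                                       config.adaclass)
            global_state = weighted_average(states, w)
        elif config.strategy == "feddyn":
            m = len(states)
            w = np.full(m, 1.0 / m)
            theta_list = [{k: s[k] for k in trainable_keys} for s in states]
            theta_g = {k: global_state[k] for k in trainable_keys}
            theta_new, dyn_server = feddyn_server_step(
                theta_list, theta_g, dyn_server, config.alpha_dyn)
            buf_avg = weighted_average(
                [{k: s[k] for k in s if k not in trainable_keys} for s in states], w)
            global_state = {**theta_new, **buf_avg}
        else:                                   # fedavg and fedprox
            w = fedavg_weights(np.array([s.n_samples for s in stats], float))
            global_state = weighted_average(states, w)

        acc = mf1 = wf1 = None
        pcf1 = None
        if r % config.eval_every == 0 or r == config.rounds:
            model.load_state_dict(global_state)
            report, _ = evaluate_model(model, test_images, test_labels,
                                       dataset.n_classes, config.eval_batch)
            acc, mf1, wf1 = report.accuracy, report.macro_f1, report.weighted_f1
            pcf1 = report.per_class_f1
        history.records.append(RoundRecord(r, w, tuple(sorted(low)),
                                           confidence_weighted_f1(stats),
                                           acc, mf1, wf1, pcf1))
    return global_state, history


def desk_scale_experiment(seed: int) -> tuple[LabeledDataset, FederatedConfig]:
    """The package's reference desk-scale experiment: 10 clients over a
    Dirichlet(1.0) split of 1,400 procedurally generated 7-class images
    (class priors follow the published maize imbalance) at 32 px, 18 rounds
    of 2 local epochs with the shared optimizer protocol — sized so one run
    completes in about three minutes on a single CPU core."""
    dataset = generate_dataset(SyntheticSpec(n_samples=1400, image_size=32,
                                             seed=seed))
    config = FederatedConfig(seed=seed, model=HybridConfig(input_size=32),
                             eval_every=6)
    return dataset, config


def compare_strategies(config: FederatedConfig, dataset: LabeledDataset,
                       strategies: list[str], seeds: list[int],
                       ) -> tuple[pd.DataFrame, dict[tuple[str, str], EffectSizeReport]]:
    """Run every strategy on identical per-seed partitions; summarize final
    test metrics as mean +- sample std over seeds and report pairwise paired
    effect sizes on accuracy.  Self-comparisons and zero-spread pairs are
    degenerate and reported as NaN."""
    if len(strategies) < 2:
        raise ValueError("need at least two strategies")
    if len(seeds) < 2:
        raise ValueError("need at least two seeds for a spread estimate")
    per = {s: {"accuracy": [], "macro_f1": [], "weighted_f1": []}
           for s in strategies}
    for seed in seeds:
        for s in strategies:
            cfg = replace(config, strategy=s, seed=seed)
            _, hist = run_federated(cfg, dataset)
            last = hist.records[-1]
            per[s]["accuracy"].append(last.accuracy)
            per[s]["macro_f1"].append(last.macro_f1)
            per[s]["weighted_f1"].append(last.weighted_f1)
    rows = []
    for s in strategies:
        for metric, vals in per[s].items():
            v = np.array(vals, float)
            rows.append({"strategy": s, "metric": metric,
                         "mean": v.mean(), "std": v.std(ddof=1)})
    table = pd.DataFrame(rows)
    effects: dict[tuple[str, str], EffectSizeReport] = {}
    for a in strategies:
        for b in strategies:
            if a >= b:
                continue
            x = np.array(per[a]["accuracy"])
            y = np.array(per[b]["accuracy"])
            try:
                d = cohens_d_paired(x, y)
            except ValueError:
                d = float("nan")
            try:
                rrb = rank_biserial(x, y)
            except ValueError:
                rrb = float("nan")
            effects[(a, b)] = EffectSizeReport(d, rrb, len(seeds))
    return table, effects
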