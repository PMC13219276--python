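"""Dirichlet label-skew partitioning of a dataset across simulated clients,
with the heterogeneity diagnostics reported for such splits (per-client
sample counts, dominant class share, Jensen-Shannon divergence against the
global label distribution) and class-balanced loss weights."""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import jensenshannon

__all__ = [
    "PartitionPlan", "ClientReportRow", "PartitionReport", "ClassWeights",
    "dirichlet_partition", "js_divergence", "partition_report",
    "class_weights", "summary_stats",
]


@dataclass
class PartitionPlan:
    n_clients: int
    alpha: float
    seed: int
    assignment: np.ndarray      # sample index -> client id

    def client_indices(self, client: int) -> np.ndarray:
        return np.flatnonzero(self.assignment == client)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "n_clients": self.n_clients, "alpha": self.alpha, "seed": self.seed,
            "assignment": self.assignment.tolist()}))

    @classmethod
    def from_json(cls, path: str | Path) -> "PartitionPlan":
        d = json.loads(Path(path).read_text())
        return cls(d["n_clients"], d["alpha"], d["seed"], np.array(d["assignment"]))


def _largest_remainder(props: np.ndarray, total: int) -> np.ndarray:
    """Integer quotas matching ``props`` with exact sum ``total``; leftover
    units go to the largest fractional remainders (ties to lower index)."""
    raw = props * total
    quotas = np.floor(raw).astype(int)
    short = total - quotas.sum()
    order = np.argsort(-(raw - quotas), kind="stable")
    quotas[order[:short]] += 1
    return quotas


def dirichlet_partition(labels, n_clients: int, alpha: float, seed: int) -> PartitionPlan:
    """Allocate each class's samples to clients by a Dirichlet(alpha)
    proportion vector.

    Per class, in ascending class order: draw one Dirichlet(alpha * 1_K)
    vector, convert it to integer quotas by largest-remainder rounding,
    shuffle that class's sample indices, and deal them out in client order.
    Empty clients are permitted.  Identical seeds yield identical plans.
    """
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("labels must be nonempty")
    if n_clients < 1:
        raise ValueError("need at least one client")
    if alpha <= 0:
        raise ValueError("Dirichlet concentration must be positive")
    rng = np.random.default_rng(seed)
    assignment = np.empty(labels.size, dtype=int)
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        props = rng.dirichlet(np.full(n_clients, alpha))
        quotas = _largest_remainder(props, idx.size)
        rng.shuffle(idx)
        bounds = np.cumsum(quotas)[:-1]
        for client, chunk in enumerate(np.split(idx, bounds)):
            assignment[chunk] = client
    return PartitionPlan(n_clients, alpha, seed, assignment)


def js_divergence(p, q) -> float:
    """Jensen-Shannon divergence with base-2 logarithm, bounded in [0, 1]."""
    p, q = np.asarray(p, float), np.asarray(q, float)
    if p.shape != q.shape:
        raise ValueError("distributions must have equal length")
    if (p < 0).any() or (q < 0).any():
        raise ValueError("probabilities must be non-negative")
    for v in (p, q):
        if abs(v.sum() - 1.0) > 1e-9:
            raise ValueError("inputs must sum to 1")
    return float(jensenshannon(p, q, base=2) ** 2)


@dataclass
class ClientReportRow:
    client_id: int
    n_samples: int
    class_histogram: np.ndarray
    dominant_class: int
    dominant_share_pct: float
    js_div: float
    classes_present: int


@dataclass
class PartitionReport:
    clients: list[ClientReportRow]
    mean_samples: float
    std_samples: float
    mean_js: float
    std_js: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "client": r.client_id, "samples": r.n_samples,
            "dominant_class": r.dominant_class,
            "dominant_share_pct": r.dominant_share_pct,
            "js_divergence": r.js_div, "classes_present": r.classes_present,
        } for r in self.clients])

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    def summary_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "mean_samples": self.mean_samples, "std_samples": self.std_samples,
            "mean_js": self.mean_js, "std_js": self.std_js}, indent=2))


def summary_stats(values) -> tuple[float, float]:
    """Mean and population standard deviation (denominator n)."""
    v = np.asarray(values, float)
    return float(v.mean()), float(v.std())


def partition_report(plan: PartitionPlan, labels) -> PartitionReport:
    """Per-client histograms and JS divergence against the global training
    label distribution; summary dispersion uses the population form."""
    labels = np.asarray(labels)
    if labels.size != plan.assignment.size:
        raise ValueError("plan does not cover the label sequence")
    n_classes = int(labels.max()) + 1
    global_hist = np.bincount(labels, minlength=n_classes).astype(float)
    global_dist = global_hist / global_hist.sum()
    rows = []
    for k in range(plan.n_clients):
        sub = labels[plan.assignment == k]
        hist = np.bincount(sub, minlength=n_classes)
        if sub.size:
            dist = hist / hist.sum()
            js = js_divergence(dist, global_dist)
            dom = int(hist.argmax())
            share = 100.0 * hist[dom] / sub.size
        else:
            js, dom, share = 0.0, -1, 0.0
        rows.append(ClientReportRow(k, int(sub.size), hist, dom, share, js,
                                    int((hist > 0).sum())))
    mean_n, std_n = summary_stats([r.n_samples for r in rows])
    mean_js, std_js = summary_stats([r.js_div for r in rows])
    return PartitionReport(rows, mean_n, std_n, mean_js, std_js)


@dataclass
class ClassWeights:
    weights: np.ndarray

    def __post_init__(self):
        self.weights = np.asarray(self.weights, float)


def class_weights(class_counts) -> ClassWeights:
    """Balanced weighting w_c = N / (C * n_c): the weighted count
    sum_c w_c n_c equals the dataset size N for any positive counts."""
    counts = np.asarray(class_counts, float)
    if (counts <= 0).any():
        raise ValueError("every class needs at least one sample "
                         "(zero counts make the weight undefined)")
    N, C = counts.sum(), len(counts)
    return ClassWeights(N / (C * counts))
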