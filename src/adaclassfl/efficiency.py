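"""Deployment profiling: model memory footprint and a warm-up/measure
inference-latency protocol with nearest-rank percentiles."""

from __future__ import annotations

import time
from dataclasses import dataclass

import numpy as np

from .nn import Module

__all__ = ["SizeReport", "LatencyStats", "model_size_mb", "latency_stats",
           "summarize_timings"]


@dataclass
class SizeReport:
    param_bytes: int
    buffer_bytes: int

    @property
    def total_mb(self) -> float:
        return (self.param_bytes + self.buffer_bytes) / 1024 ** 2


def model_size_mb(model: Module, dtype_bytes: int = 4) -> SizeReport:
    """Sum element counts times element byte-width over parameters and
    persistent buffers.  ``dtype_bytes`` defaults to 4 — the 32-bit precision
    models are serialized at for deployment, independent of the wider
    precision used during simulation."""
    p = sum(int(t.data.size) for _, t in model.named_parameters())
    b = sum(int(arr.size) for _, arr in model.named_buffers())
    return SizeReport(p * dtype_bytes, b * dtype_bytes)


@dataclass
class LatencyStats:
    mean_ms: float
    std_ms: float
    p95_ms: float
    p99_ms: float
    n_measure: int

    def as_dict(self) -> dict[str, float]:
        return {"mean_ms": self.mean_ms, "std_ms": self.std_ms,
                "p95_ms": self.p95_ms, "p99_ms": self.p99_ms,
                "n_measure": self.n_measure}


def _nearest_rank(sorted_vals: np.ndarray, q: float) -> float:
    n = sorted_vals.size
    rank = max(1, int(np.ceil(q * n)))
    return float(sorted_vals[rank - 1])


def summarize_timings(timings_ms) -> LatencyStats:
    """Mean, standard deviation, and nearest-rank 95th/99th percentiles of a
    list of millisecond timings."""
    t = np.asarray(timings_ms, float)
    if t.size < 1:
        raise ValueError("need at least one measurement")
    s = np.sort(t)
    return LatencyStats(float(t.mean()), float(t.std()),
                        _nearest_rank(s, 0.95), _nearest_rank(s, 0.99),
                        int(t.size))


def latency_stats(inference, n_warmup: int = 20, n_measure: int = 200) -> LatencyStats:
    """Run ``inference()`` untimed ``n_warmup`` times, then time ``n_measure``
    calls with a monotonic clock."""
    if n_measure < 1:
        raise ValueError("n_measure must be >= 1")
    for _ in range(n_warmup):
        inference()
    timings = []
    for _ in range(n_measure):
        t0 = time.perf_counter()
        inference()
        timings.append((time.perf_counter() - t0) * 1000.0)
    return summarize_timings(timings)
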