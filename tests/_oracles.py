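"""Independent reference implementations used as test oracles.

Everything here is written in plain loops against the published formulas,
deliberately sharing no code with the package: scalar transcription of the
adaptive weighting pipeline, a reference Dirichlet dealer, brute-force
Jensen-Shannon divergence, interpolated percentiles, pairwise-comparison
AUC, and a pixel-by-pixel single-tile CLAHE.
"""

import math

import numpy as np


def interpolated_percentile(values, q):
    """Linear interpolation between order statistics, q in [0, 1]."""
    srt = sorted(values)
    h = (len(srt) - 1) * q
    lo = math.floor(h)
    if lo + 1 >= len(srt):
        return srt[lo]
    return srt[lo] + (h - lo) * (srt[lo + 1] - srt[lo])


def adaclass_scalar(ns, f1s, avails, *, alpha=0.7, tau=0.25, beta=0.3,
                    temperature=2.0, w_min=0.05, w_prev=None):
    """Scalar transcription of the seven-step adaptive weighting rule.

    Returns (weights, struggling_class_set).
    """
    K, C = len(ns), len(f1s[0])
    N = float(sum(ns))
    fbar = [sum(ns[i] / N * f1s[i][c] for i in range(K)) for c in range(C)]
    if max(fbar) == min(fbar):
        low = set()
    else:
        thresh = interpolated_percentile(fbar, tau)
        low = {c for c in range(C) if fbar[c] <= thresh}
    w_data = [n / N for n in ns]
    p = []
    for i in range(K):
        av = [c for c in range(C) if avails[i][c]]
        f_overall = sum(f1s[i][c] for c in av) / len(av)
        in_low = [c for c in low if avails[i][c]]
        if in_low:
            f_low = sum(f1s[i][c] for c in in_low) / len(in_low)
            p.append(0.4 * f_low + 0.6 * f_overall)
        else:
            p.append(f_overall)
    ex = [math.exp(x / temperature) for x in p]
    w_perf = [e / sum(ex) for e in ex]
    w = [alpha * a + (1 - alpha) * b for a, b in zip(w_data, w_perf)]
    if w_prev is not None:
        w = [(1 - beta) * x + beta * y for x, y in zip(w, w_prev)]
    w = [max(x, w_min) for x in w]
    s = sum(w)
    return [x / s for x in w], low


def reference_dirichlet_partition(labels, n_clients, alpha, seed):
    """Reference dealer: per ascending class, one Dirichlet draw, quotas by
    largest remainder (ties to the lower client id), shuffled deal."""
    rng = np.random.default_rng(seed)
    assign = {}
    for c in sorted(set(int(l) for l in labels)):
        idx = [i for i, l in enumerate(labels) if l == c]
        props = rng.dirichlet([alpha] * n_clients)
        raw = [p * len(idx) for p in props]
        quota = [math.floor(r) for r in raw]
        order = sorted(range(n_clients), key=lambda k: (-(raw[k] - quota[k]), k))
        for k in order[:len(idx) - sum(quota)]:
            quota[k] += 1
        arr = np.array(idx)
        rng.shuffle(arr)
        pos = 0
        for k in range(n_clients):
            for i in arr[pos:pos + quota[k]]:
                assign[int(i)] = k
            pos += quota[k]
    return assign


def js_formula(p, q):
    """Direct evaluation of JS(p, q) with base-2 logs, 0 log 0 = 0."""
    m = [(a + b) / 2.0 for a, b in zip(p, q)]

    def kl(a, b):
        return sum(x * math.log2(x / y) for x, y in zip(a, b) if x > 0)

    return 0.5 * kl(p, m) + 0.5 * kl(q, m)


def pairwise_auc(scores, labels01):
    """Probability a random positive outscores a random negative, ties 1/2."""
    pos = [s for s, l in zip(scores, labels01) if l == 1]
    neg = [s for s, l in zip(scores, labels01) if l == 0]
    total = 0.0
    for a in pos:
        for b in neg:
            total += 1.0 if a > b else (0.5 if a == b else 0.0)
    return total / (len(pos) * len(neg))


def single_tile_clahe(channel, clip):
    """Pixel-by-pixel CLAHE when the whole image is one tile."""
    area = channel.size
    hist = [0.0] * 256
    for v in channel.ravel():
        hist[int(v)] += 1.0
    limit = clip * area / 256.0
    excess = sum(max(h - limit, 0.0) for h in hist)
    hist = [min(h, limit) + excess / 256.0 for h in hist]
    cdf, run = [], 0.0
    for h in hist:
        run += h
        cdf.append(run)
    lut = [min(255, max(0, round(255.0 * (cdf[v] - hist[v] / 2.0) / area)))
           for v in range(256)]
    out = np.empty_like(channel)
    for i in range(channel.shape[0]):
        for j in range(channel.shape[1]):
            out[i, j] = lut[int(channel[i, j])]
    return out


def gamma_map(v, gamma):
    return min(255, max(0, round(255.0 * (v / 255.0) ** (1.0 / gamma))))
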