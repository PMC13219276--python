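# adaclassfl

Federated learning for leaf-disease image classification with **AdaClass**,
a class-aware adaptive aggregation rule, plus everything needed to study it
at desk scale on one CPU: a seeded procedural leaf-disease image generator,
Dirichlet label-skew client partitioning with heterogeneity diagnostics, a
hybrid convolution/attention classifier built on a bundled numpy autodiff
toolkit, the full evaluation protocol (weighted metrics, paired effect
sizes, micro-averaged ROC/AUC), and deployment profiling.

## Who this is for

Researchers and students studying aggregation strategies under non-IID
(label-skewed) federated conditions — the situation of distributed farms
that each see different mixes of crop diseases — who want a reproducible,
dependency-light simulation rather than a GPU cluster.

## The aggregation rule

Federated averaging combines client updates with weights `w_i = n_i / Σ n_j`
based purely on local data volume. AdaClass instead adapts the weights each
round to the classes the *global* model is currently failing on:

1. **Warm-up** — rounds `1..r_warmup` use plain FedAvg weights.
2. **Global class estimate** — `F̄(c) = Σ_i (n_i/N) · F_i(c)`, each client's
   local per-class F1 weighted by its data share.
3. **Struggling classes** — `L = {c : F̄(c) ≤ P_τ(F̄)}`, the bottom
   τ-percentile (τ = 0.25 flags one to two of seven classes).
4. **Client scores** — `p_i = 0.4·f_i^low + 0.6·f_i^overall` when client *i*
   holds samples of some class in `L`, else `p_i = f_i^overall`.
5. **Performance weights** — temperature softmax
   `w_i^perf ∝ exp(p_i / T)`, `T = 2.0`.
6. **Mixing** — `w_i = α·w_i^data + (1−α)·w_i^perf`, `α = 0.7`.
7. **Momentum, floor, normalization** —
   `w ← (1−β)·w + β·w_prev` (β = 0.3, from the second adaptive round),
   `w ← max(w, w_min)` (`w_min = 0.05`), then `w ← w / Σ w`.

FedAvg, FedProx (proximal term `(μ/2)‖θ−θ_g‖²`, μ = 0.01) and FedDyn
(dynamic regularizer, α_dyn = 0.01) are implemented alongside for paired
comparisons on identical partitions.

## Worked example

```python
from adaclassfl.fl_sim import desk_scale_experiment, run_federated

dataset, config = desk_scale_experiment(seed=1)   # 1,400 images, 10 clients
params, history = run_federated(config, dataset)
last = history.records[-1]
print(f"final accuracy {last.accuracy:.3f}, macro F1 {last.macro_f1:.3f}")
print("round-18 client weights:", last.weights.round(3))
print("struggling classes flagged:", last.struggling)
```

On one CPU core this takes about three minutes and prints (seed 1):

```
final accuracy 0.921, macro F1 0.865
round-18 client weights: [0.089 0.151 0.087 0.088 0.092 0.089 0.119 0.121 0.087 0.078]
struggling classes flagged: (1, 2)
```

Final test accuracy clears 0.9 on the imbalanced 7-class synthetic task.
The flagged classes (here 1 and 2 — the brown-spot and necrotic-patch
motifs) are the bottom-quartile entries of that round's data-share-weighted
global per-class F1 vector; the weight vector sums to 1 and no client falls
meaningfully below the 5% floor.

The same pipeline is scriptable from the shell:

```bash
adaclass-fl synth --n-samples 500 --out data/
adaclass-fl partition --data data/ --n-clients 10 --alpha 1.0 --seed 0 --out part/
adaclass-fl train --config run.yaml --data data/ --out run/
adaclass-fl profile --checkpoint run/checkpoint.pkl
```

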