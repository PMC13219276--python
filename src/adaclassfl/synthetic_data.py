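"""Seeded procedural leaf-disease imagery and per-client F1 fixtures.

The generator renders an elliptical leaf on a soil background and stamps one
of seven disease motifs onto it — the visual vocabulary of field-captured
maize disease photographs (spots, blight patches, streaks, rings, marginal
necrosis, mottle), at a controllable lesion contrast.  Classes are separable
by design: each motif has a distinct characteristic color and coverage, so a
simple mean-color classifier already does well at full contrast, and
difficulty degrades gracefully toward zero contrast.

Everything is driven by one explicit ``numpy.random.Generator`` per call;
equal seeds give byte-identical output.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

from .aggregation import ClientRoundStats
from .datatables import maize_priors

__all__ = [
    "SyntheticSpec", "LabeledDataset", "F1FixtureProfile",
    "generate_dataset", "generate_f1_fixture",
    "save_dataset", "load_dataset", "MOTIF_NAMES",
]

MOTIF_NAMES = (
    "healthy", "brown_spots", "necrotic_patch", "yellow_streaks",
    "concentric_rings", "marginal_necrosis", "mottle",
)

# characteristic lesion color per motif (index 0 = healthy, no lesion)
_MOTIF_COLORS = {
    1: (125.0, 62.0, 22.0),
    2: (110.0, 32.0, 28.0),
    3: (218.0, 202.0, 70.0),
    4: (205.0, 122.0, 38.0),
    5: (72.0, 46.0, 16.0),
    6: (196.0, 196.0, 116.0),
}


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for one procedurally generated labeled image set."""

    n_samples: int = 500
    n_classes: int = 7
    image_size: int = 64
    class_priors: tuple[float, ...] | None = None
    difficulty: float = 1.0
    seed: int = 0

    def resolved_priors(self) -> np.ndarray:
        if self.class_priors is None:
            if self.n_classes == 7:
                return maize_priors()
            return np.full(self.n_classes, 1.0 / self.n_classes)
        return np.asarray(self.class_priors, float)

    def validate(self) -> None:
        if not 2 <= self.n_classes <= len(MOTIF_NAMES):
            raise ValueError(f"n_classes must be in 2..{len(MOTIF_NAMES)} "
                             "(one rendering motif per class)")
        priors = self.resolved_priors()
        if len(priors) != self.n_classes:
            raise ValueError("class_priors length must equal n_classes")
        if abs(priors.sum() - 1.0) > 1e-9 or (priors < 0).any():
            raise ValueError("class_priors must be a probability vector")
        if not 0.0 < self.difficulty <= 1.0:
            raise ValueError("difficulty must lie in (0, 1]")
        if self.n_samples < 1 or self.image_size < 16:
            raise ValueError("need n_samples >= 1 and image_size >= 16")


@dataclass
class LabeledDataset:
    images: np.ndarray          # (N, H, W, 3) uint8
    labels: np.ndarray          # (N,) int
    n_classes: int

    @property
    def class_counts(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.n_classes)

    def __len__(self) -> int:
        return len(self.labels)

    def subset(self, idx) -> "LabeledDataset":
        return LabeledDataset(self.images[idx], self.labels[idx], self.n_classes)


def _disk(h, w, cy, cx, r):
    yy, xx = np.ogrid[0:h, 0:w]
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r


def _render(label: int, size: int, difficulty: float,
            rng: np.random.Generator) -> np.ndarray:
    h = w = size
    sc = size / 64.0
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    cy, cx = h / 2.0, w / 2.0
    ang = rng.uniform(-0.5, 0.5)
    ca, sa = np.cos(ang), np.sin(ang)
    u = (xx - cx) * ca + (yy - cy) * sa      # leaf major axis
    v = -(xx - cx) * sa + (yy - cy) * ca
    a, b = 0.46 * w, 0.34 * h
    ell = (u / a) ** 2 + (v / b) ** 2
    leaf = ell <= 1.0

    img = np.empty((h, w, 3))
    img[...] = (62.0, 48.0, 36.0)                       # soil background
    base = np.array([52.0, 122.0, 42.0]) + rng.uniform(-4, 4, 3)
    shade = 1.0 - 0.25 * ell
    leaf_rgb = base[None, None, :] * shade[..., None]
    img[leaf] = leaf_rgb[leaf]
    vein = leaf & (np.abs(v) < max(1.0, 0.8 * sc))
    img[vein] = np.clip(base * 1.25, 0, 255)

    m = np.zeros((h, w), bool)
    if label == 1:                                      # circular brown spots
        for _ in range(rng.integers(8, 13)):
            r = rng.uniform(2.5, 4.5) * sc
            t = rng.uniform(0, 2 * np.pi)
            rad = rng.uniform(0, 0.75)
            m |= _disk(h, w, cy + rad * b * np.sin(t), cx + rad * a * np.cos(t), r)
    elif label == 2:                                    # one irregular patch
        py = cy + rng.uniform(-0.3, 0.3) * b
        px = cx + rng.uniform(-0.3, 0.3) * a
        for _ in range(10):
            m |= _disk(h, w, py + rng.normal(0, 3 * sc), px + rng.normal(0, 3 * sc),
                       rng.uniform(3.5, 6.0) * sc)
    elif label == 3:                                    # parallel streaks
        n = rng.integers(3, 6)
        offs = np.linspace(-0.7, 0.7, n) * b + rng.uniform(-2, 2, n) * sc
        wdt = rng.uniform(1.0, 2.0) * sc
        for o in offs:
            m |= np.abs(v - o) < wdt
    elif label == 4:                                    # concentric rings
        for _ in range(rng.integers(2, 4)):
            t = rng.uniform(0, 2 * np.pi)
            rad = rng.uniform(0, 0.5)
            py = cy + rad * b * np.sin(t)
            px = cx + rad * a * np.cos(t)
            rr = np.sqrt((yy - py) ** 2 + (xx - px) ** 2)
            for k in (3.0, 6.0, 9.0):
                m |= np.abs(rr - k * sc) < 1.3 * sc
    elif label == 5:                                    # marginal necrosis
        m = (ell > rng.uniform(0.55, 0.65)) & (ell <= 1.0)
    elif label == 6:                                    # mottling
        for _ in range(rng.integers(14, 22)):
            t = rng.uniform(0, 2 * np.pi)
            rad = rng.uniform(0, 0.85)
            m |= _disk(h, w, cy + rad * b * np.sin(t), cx + rad * a * np.cos(t),
                       rng.uniform(1.5, 3.0) * sc)
    m &= leaf
    if label > 0 and m.any():
        col = np.array(_MOTIF_COLORS[label])
        img[m] += difficulty * (col[None, :] - img[m])
    img += rng.normal(0, 3.0, img.shape)
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def generate_dataset(spec: SyntheticSpec) -> LabeledDataset:
    """Render a seeded labeled image set; deterministic for a fixed spec."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    priors = spec.resolved_priors()
    labels = rng.choice(spec.n_classes, size=spec.n_samples, p=priors)
    images = np.stack([_render(int(l), spec.image_size, spec.difficulty, rng)
                       for l in labels])
    return LabeledDataset(images, labels.astype(int), spec.n_classes)


# ---------------------------------------------------------------------------
# per-client F1 fixtures (inputs to the aggregation rule, no training needed)

@dataclass(frozen=True)
class F1FixtureProfile:
    n_clients: int
    n_classes: int
    f1_means: tuple[float, ...]
    availability_rate: float = 1.0
    f1_spread: float = 50.0          # Beta concentration; inf = no noise
    n_range: tuple[int, int] = (50, 500)
    seed: int = 0

    def validate(self) -> None:
        if len(self.f1_means) != self.n_classes:
            raise ValueError("f1_means length must equal n_classes")
        if not all(0.0 <= m <= 1.0 for m in self.f1_means):
            raise ValueError("f1_means entries must lie in [0, 1]")
        if not 0.0 < self.availability_rate <= 1.0:
            raise ValueError("availability_rate must lie in (0, 1]")
        if self.n_clients < 1:
            raise ValueError("need at least one client")


def generate_f1_fixture(profile: F1FixtureProfile) -> list[ClientRoundStats]:
    """Draw per-client sample counts, class-availability masks, and noisy
    per-class F1 values centered on ``f1_means``."""
    profile.validate()
    rng = np.random.default_rng(profile.seed)
    means = np.asarray(profile.f1_means, float)
    out = []
    for cid in range(profile.n_clients):
        n_i = int(rng.integers(profile.n_range[0], profile.n_range[1] + 1))
        avail = rng.random(profile.n_classes) < profile.availability_rate
        if not avail.any():
            avail[rng.integers(profile.n_classes)] = True
        if np.isinf(profile.f1_spread):
            f1 = means.copy()
        else:
            kappa = profile.f1_spread
            aa = np.clip(means, 1e-3, 1 - 1e-3) * kappa
            bb = kappa - aa
            f1 = rng.beta(aa, bb)
        f1 = np.where(avail, f1, 0.0)
        out.append(ClientRoundStats(client_id=cid, n_samples=n_i,
                                    f1=f1, available=avail))
    return out


# ---------------------------------------------------------------------------
# disk layout: class_<k>/ PNG directories plus a (path,label) manifest

def save_dataset(ds: LabeledDataset, root: str | Path) -> Path:
    root = Path(root)
    rows = []
    for i, (img, lab) in enumerate(zip(ds.images, ds.labels)):
        d = root / f"class_{lab}"
        d.mkdir(parents=True, exist_ok=True)
        p = d / f"img_{i:05d}.png"
        Image.fromarray(img).save(p)
        rows.append((str(p.relative_to(root)), int(lab)))
    manifest = root / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["path", "label"])
        w.writerows(rows)
    return manifest


def load_dataset(root: str | Path, n_classes: int | None = None) -> LabeledDataset:
    root = Path(root)
    with open(root / "manifest.csv") as fh:
        rows = list(csv.DictReader(fh))
    images = np.stack([np.asarray(Image.open(root / r["path"]).convert("RGB"))
                       for r in rows])
    labels = np.array([int(r["label"]) for r in rows])
    return LabeledDataset(images, labels, n_classes or int(labels.max()) + 1)
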