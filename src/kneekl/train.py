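"""Training loop for the Siamese grading network.

The recipe: class balancing by oversampling with replacement (bootstrapping),
on-the-fly augmentation in random operation order followed by the fixed-size
physical crop, Adam with L2 weight decay on a cross-entropy loss, periodic
validation scored by quadratic weighted kappa, and per-seed snapshot
selection.  An ensemble is produced by repeating the run for each seed
(default 21, 42, 84) and keeping each run's best validation snapshot.

Defaults follow the full-scale recipe (lr 1e-2, weight decay 1e-4, batch 64,
50,000 iterations evaluated every 500); desk-scale runs shrink
``max_iters``/``batch_size``/``base_width`` through :class:`TrainConfig`.
Everything is seeded — weight initialisation, sampling, augmentation and
dropout — so single-threaded runs are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

import numpy as np
from scipy.ndimage import rotate as _nd_rotate

from .ensemble import EnsembleBundle
from .evaluate import quadratic_kappa
from .model import BranchSpec, SiameseNet, build, standardize
from .nn import Adam, cross_entropy
from .patches import PatchGeometry, PatchPair, extract_pair, resize_to_grid
from .preprocess import NormalizedImage, center_crop_mm

__all__ = ["AugmentConfig", "TrainConfig", "Snapshot", "balanced_sampler",
           "augment", "image_to_pair", "train_one", "select_snapshot",
           "train_bundle"]

N_GRADES = 5


@dataclass(frozen=True)
class AugmentConfig:
    """Ranges of the on-the-fly augmentations; each range contains the identity.

    rotation in degrees, brightness additive in 8-bit units, contrast as a
    multiplicative factor about the image mean, jitter as integer pixel
    translation, gamma as a power-law exponent.
    """

    rotation_deg: tuple[float, float] = (-10.0, 10.0)
    brightness: tuple[float, float] = (-30.0, 30.0)
    contrast: tuple[float, float] = (0.8, 1.2)
    jitter_px: tuple[int, int] = (-15, 15)
    gamma: tuple[float, float] = (0.8, 1.25)

    def __post_init__(self) -> None:
        for name, (lo, hi), ident in (
            ("rotation_deg", self.rotation_deg, 0.0),
            ("brightness", self.brightness, 0.0),
            ("contrast", self.contrast, 1.0),
            ("jitter_px", self.jitter_px, 0),
            ("gamma", self.gamma, 1.0),
        ):
            if not lo <= ident <= hi:
                raise ValueError(f"{name} range {lo}..{hi} excludes the identity")


@dataclass(frozen=True)
class TrainConfig:
    lr: float = 1e-2
    weight_decay: float = 1e-4
    batch_size: int = 64
    max_iters: int = 50_000
    eval_every: int = 500
    seeds: tuple[int, ...] = (21, 42, 84)
    dropout: float = 0.2
    augmentation: AugmentConfig | None = field(default_factory=AugmentConfig)
    crop_mm: float = 130.0
    geometry: PatchGeometry = field(default_factory=PatchGeometry.default)
    base_width: int = 64

    def __post_init__(self) -> None:
        if min(self.batch_size, self.max_iters, self.eval_every) <= 0:
            raise ValueError("batch_size, max_iters and eval_every must be positive")
        if self.lr < 0:  # lr = 0 is allowed as a no-update diagnostic run
            raise ValueError("lr must be non-negative")
        if self.weight_decay < 0 or not 0 <= self.dropout < 1:
            raise ValueError("invalid weight_decay or dropout")
        if self.eval_every > self.max_iters:
            raise ValueError("eval_every must not exceed max_iters")
        if not self.seeds:
            raise ValueError("at least one seed is required")

    def scaled(self, **kw) -> "TrainConfig":
        return replace(self, **kw)


@dataclass
class Snapshot:
    iteration: int
    state: dict[str, np.ndarray]
    val_kappa: float
    val_loss: float
    train_loss: float


def balanced_sampler(labels: Sequence[int], seed: int) -> Iterator[int]:
    """Infinite index stream with equal expected frequency per KL grade.

    Each draw picks a grade uniformly and then an example of that grade with
    replacement, i.e. oversampling with bootstrapping.  Deterministic for a
    given seed.
    """
    labels = np.asarray(labels, dtype=int)
    by_grade = [np.flatnonzero(labels == g) for g in range(N_GRADES)]
    missing = [g for g, idx in enumerate(by_grade) if idx.size == 0]
    if missing:
        raise ValueError(f"grades absent from the data: {missing}")
    rng = np.random.default_rng(seed)
    while True:
        g = int(rng.integers(N_GRADES))
        yield int(by_grade[g][rng.integers(by_grade[g].size)])


def _shift(a: np.ndarray, dy: int, dx: int) -> np.ndarray:
    """Integer translation with edge replication."""
    h, w = a.shape
    py, px = abs(dy), abs(dx)
    padded = np.pad(a, ((py, py), (px, px)), mode="edge")
    return padded[py - dy : py - dy + h, px - dx : px - dx + w]


def augment(img: NormalizedImage, cfg: AugmentConfig,
            rng: np.random.Generator, crop_mm: float = 130.0) -> NormalizedImage:
    """Apply the five augmentations in random order, then centre-crop.

    Rotation, brightness, contrast, jitter and gamma parameters are drawn
    uniformly from their configured ranges; the fixed-physical-size crop is
    taken after augmentation so rotation/jitter edge effects stay outside it.
    """
    v = img.pixels.astype(np.float64)

    def rot(a):
        angle = rng.uniform(*cfg.rotation_deg)
        if angle == 0.0:
            return a
        return _nd_rotate(a, angle, reshape=False, order=1, mode="nearest")

    def bright(a):
        return a + rng.uniform(*cfg.brightness)

    def contrast(a):
        f = rng.uniform(*cfg.contrast)
        return (a - a.mean()) * f + a.mean()

    def jitter(a):
        dy = int(rng.integers(cfg.jitter_px[0], cfg.jitter_px[1] + 1))
        dx = int(rng.integers(cfg.jitter_px[0], cfg.jitter_px[1] + 1))
        return _shift(a, dy, dx)

    def gamma(a):
        g = rng.uniform(*cfg.gamma)
        return 255.0 * np.clip(a / 255.0, 0.0, 1.0) ** g

    ops = [rot, bright, contrast, jitter, gamma]
    for k in rng.permutation(len(ops)):
        v = ops[k](v)
    out = NormalizedImage(np.clip(np.rint(v), 0, 255).astype(np.uint8),
                          img.spacing_mm, img.source_id)
    return center_crop_mm(out, crop_mm)


def image_to_pair(img: NormalizedImage, geom: PatchGeometry,
                  crop_mm: float | None = 130.0) -> PatchPair:
    """Deterministic image -> patch-pair pipeline (crop, resize, extract)."""
    if crop_mm is not None:
        img = center_crop_mm(img, crop_mm)
    resized = resize_to_grid(img, geom.resized_px)
    return extract_pair(resized, geom, img.source_id)


def _pairs_to_arrays(pairs: Sequence[PatchPair]):
    lat = np.stack([p.lateral for p in pairs]).astype(np.float32)
    med = np.stack([p.medial for p in pairs]).astype(np.float32)
    return lat, med


def _validate(model: SiameseNet, lat, med, truth):
    logits_all = []
    for start in range(0, lat.shape[0], 128):
        logits, _ = model.forward_batch(lat[start : start + 128],
                                        med[start : start + 128])
        logits_all.append(logits)
    logits = np.concatenate(logits_all)
    loss, _ = cross_entropy(logits, truth)
    kappa = quadratic_kappa(truth, logits.argmax(axis=1))
    return kappa, loss


def train_one(model: SiameseNet,
              train_data: Sequence[tuple[NormalizedImage, int]],
              cfg: TrainConfig, seed: int,
              val_data: Sequence[tuple[NormalizedImage, int]]) -> list[Snapshot]:
    """Optimise one model; returns every evaluated snapshot with its metrics.

    ``train_data``/``val_data`` are (normalised 140 mm image, grade) pairs; the
    crop/resize/patch pipeline runs inside the loop so augmentation happens
    upstream of the crop.  Aborts with a diagnostic on a non-finite loss.
    """
    rng = np.random.default_rng(seed)
    labels = [g for _, g in train_data]
    sampler = balanced_sampler(labels, int(rng.integers(2**31)))

    val_lat, val_med = _pairs_to_arrays(
        [image_to_pair(img, cfg.geometry, cfg.crop_mm) for img, _ in val_data])
    val_lat, val_med = standardize(val_lat), standardize(val_med)
    val_truth = np.asarray([g for _, g in val_data], dtype=int)

    pre_lat = pre_med = None
    if cfg.augmentation is None:  # static pipeline: precompute all pairs once
        pre_lat, pre_med = _pairs_to_arrays(
            [image_to_pair(img, cfg.geometry, cfg.crop_mm) for img, _ in train_data])

    optim = Adam(model.params(), lr=cfg.lr, weight_decay=cfg.weight_decay)
    history: list[Snapshot] = []
    running_loss = float("nan")
    for it in range(1, cfg.max_iters + 1):
        idx = [next(sampler) for _ in range(cfg.batch_size)]
        if pre_lat is not None:
            lat, med = pre_lat[idx], pre_med[idx]
        else:
            pairs = [image_to_pair(augment(train_data[i][0], cfg.augmentation,
                                           rng, cfg.crop_mm),
                                   cfg.geometry, crop_mm=None) for i in idx]
            lat, med = _pairs_to_arrays(pairs)
        batch_truth = np.asarray([labels[i] for i in idx], dtype=int)

        logits, cache = model.forward_batch(standardize(lat), standardize(med),
                                            train=True, rng=rng)
        loss, dlogits = cross_entropy(logits, batch_truth)
        if not np.isfinite(loss):
            raise RuntimeError(
                f"non-finite training loss at iteration {it} (seed {seed}); "
                "lower the learning rate or check the input normalisation")
        running_loss = loss if np.isnan(running_loss) else 0.9 * running_loss + 0.1 * loss
        optim.zero_grad()
        model.backward(dlogits, cache)
        optim.step()

        if it % cfg.eval_every == 0 or it == cfg.max_iters:
            kappa, val_loss = _validate(model, val_lat, val_med, val_truth)
            history.append(Snapshot(iteration=it, state=model.copy_state(),
                                    val_kappa=kappa, val_loss=val_loss,
                                    train_loss=running_loss))
    return history


def select_snapshot(history: Sequence[Snapshot]) -> Snapshot:
    """Snapshot with the best validation kappa; earliest iteration wins ties."""
    if not history:
        raise ValueError("empty snapshot history")
    best = history[0]
    for snap in history[1:]:
        if snap.val_kappa > best.val_kappa:
            best = snap
    return best


def train_bundle(train_data, val_data, cfg: TrainConfig,
                 spec: BranchSpec | None = None):
    """Train one model per seed and assemble their best snapshots.

    Returns ``(bundle, histories)``; ``histories`` maps seed -> snapshot list.
    """
    spec = spec or BranchSpec.default(cfg.base_width)
    members, histories = [], {}
    for seed in cfg.seeds:
        net = build(spec, dropout=cfg.dropout, seed=seed)
        history = train_one(net, train_data, cfg, seed, val_data)
        best = select_snapshot(history)
        net.load_state(best.state)
        members.append(net)
        histories[seed] = history
    return EnsembleBundle(members, seeds=list(cfg.seeds)), histories
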