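"""Shared-weight Siamese network for Kellgren-Lawrence grading.

Each of the two branches is a stack of exactly five valid (unpadded) 3x3
convolutions — the first with stride 2 — each followed by batch normalisation
and ReLU, with 2x2 max-pooling interleaved, and ends in global average
pooling.  Both branches use *literally the same* layer objects, so the lateral
and the flipped medial patch are processed with one set of weights: the
anatomical symmetry of the joint is encoded as weight sharing, halving the
branch parameter count.  The head concatenates the two pooled descriptors,
applies dropout, and a single linear layer produces the 5-way grade logits.

With the default geometry (128x128 patches) the activation map entering the
global average pooling is 10x10 pixels per branch, which keeps the attention
maps comparatively high-resolution.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .errors import ArchitectureError
from .patches import PatchPair

__all__ = ["BranchSpec", "SiameseNet", "build", "spatial_trace", "standardize",
           "parameter_count", "save_checkpoint", "load_checkpoint"]

CHECKPOINT_SCHEMA = 1


@dataclass(frozen=True)
class BranchSpec:
    """Structure of one (shared) convolutional branch.

    ``widths`` are the five convolution channel counts, ``pool_after`` the
    1-based indices of convolutions followed by a 2x2 max-pool.  The default
    follows ``base_width N``: widths [N/2, N/2, N, N, N] with pools after the
    second and third convolution, giving the spatial trace
    128 -> 63 -> 61 -> 30 -> 28 -> 14 -> 12 -> 10 for a 128-pixel patch.
    """

    widths: tuple[int, ...] = (32, 32, 64, 64, 64)
    strides: tuple[int, ...] = (2, 1, 1, 1, 1)
    pool_after: frozenset[int] = field(default_factory=lambda: frozenset({2, 3}))
    base_width: int = 64

    def __post_init__(self) -> None:
        if len(self.widths) != 5:
            raise ArchitectureError(
                f"a branch has exactly five convolutions, got {len(self.widths)}")
        if len(self.strides) != 5:
            raise ArchitectureError("strides must list one value per convolution")
        if self.strides[0] != 2 or any(s != 1 for s in self.strides[1:]):
            raise ArchitectureError("first convolution has stride 2, the rest stride 1")
        if any(w < 1 for w in self.widths):
            raise ArchitectureError("channel widths must be positive")
        if not set(self.pool_after) <= {1, 2, 3, 4, 5}:
            raise ArchitectureError("pool_after indices must be in 1..5")

    @classmethod
    def default(cls, base_width: int = 64) -> "BranchSpec":
        n = base_width
        return cls(widths=(n // 2, n // 2, n, n, n), base_width=n)


def spatial_trace(spec: BranchSpec, input_px: int = 128) -> list[int]:
    """Spatial side length after every conv/pool, ending at the pre-GAP size.

    Raises :class:`ArchitectureError` naming the offending convolution if the
    trace collapses to a non-positive size.
    """
    sizes = [input_px]
    n = input_px
    for i, stride in enumerate(spec.strides, start=1):
        n = (n - 3) // stride + 1
        if n <= 0:
            raise ArchitectureError(
                f"convolution {i} reduces the spatial size to {n} "
                f"for a {input_px}-pixel input")
        sizes.append(n)
        if i in spec.pool_after:
            n = n // 2
            if n <= 0:
                raise ArchitectureError(
                    f"max-pool after convolution {i} reduces the spatial size to {n}")
            sizes.append(n)
    return sizes


class SiameseNet:
    """Two weight-shared conv branches, concatenated and linearly classified."""

    def __init__(self, spec: BranchSpec, dropout: float = 0.2, n_classes: int = 5,
                 input_px: int = 128, seed: int = 0):
        trace = spatial_trace(spec, input_px)
        self.spec = spec
        self.input_px = input_px
        self.n_classes = n_classes
        self.dropout_rate = dropout
        self.seed = seed
        self.feature_px = trace[-1]
        rng = np.random.default_rng(seed)

        self.branch: list = []  # one sequence of layers, applied to both patches
        in_ch = 1
        for i, (w, s) in enumerate(zip(spec.widths, spec.strides), start=1):
            self.branch.append(nn.Conv2d(in_ch, w, kernel=3, stride=s, rng=rng))
            self.branch.append(nn.BatchNorm2d(w))
            self.branch.append(nn.ReLU())
            if i in spec.pool_after:
                self.branch.append(nn.MaxPool2d())
            in_ch = w
        self.gap = nn.GlobalAvgPool()
        self.descriptor_dim = 2 * spec.widths[-1]
        self.drop = nn.Dropout(dropout)
        self.head = nn.Linear(self.descriptor_dim, n_classes, rng=rng)

    # -- parameters ------------------------------------------------------
    def params(self) -> list[nn.Param]:
        out: list[nn.Param] = []
        for layer in self.branch:
            out.extend(layer.params())
        out.extend(self.head.params())
        return out

    # -- forward / backward ---------------------------------------------
    def _branch_forward(self, x: np.ndarray, train: bool):
        caches = []
        for layer in self.branch:
            x, c = layer.forward(x, train=train)
            caches.append(c)
        maps = x  # post-ReLU pre-GAP activation maps
        pooled, gap_cache = self.gap.forward(x, train=train)
        return maps, pooled, caches, gap_cache

    def forward_batch(self, lateral: np.ndarray, medial: np.ndarray,
                      train: bool = False, rng: np.random.Generator | None = None):
        """Run a batch of patch pairs; returns (logits, cache).

        ``lateral``/``medial`` are (B, S, S) standardised float arrays.
        """
        lat = lateral[:, None].astype(np.float32)
        med = medial[:, None].astype(np.float32)
        _, pl, cl, gl = self._branch_forward(lat, train)
        _, pm, cm, gm = self._branch_forward(med, train)
        concat = np.concatenate([pl, pm], axis=1)
        dropped, dc = self.drop.forward(concat, train=train, rng=rng)
        logits, hc = self.head.forward(dropped, train=train)
        return logits, (cl, gl, cm, gm, dc, hc)

    def backward(self, dlogits: np.ndarray, cache) -> None:
        cl, gl, cm, gm, dc, hc = cache
        d = self.head.backward(dlogits, hc)
        d = self.drop.backward(d, dc)
        half = self.descriptor_dim // 2
        for dpool, caches, gcache in ((d[:, :half], cl, gl), (d[:, half:], cm, gm)):
            dx = self.gap.backward(dpool, gcache)
            for layer, c in zip(reversed(self.branch), reversed(caches)):
                dx = layer.backward(dx, c)

    # -- inference -------------------------------------------------------
    def predict_batch(self, lateral: np.ndarray, medial: np.ndarray) -> np.ndarray:
        logits, _ = self.forward_batch(standardize(lateral), standardize(medial))
        return logits

    def predict_pair(self, pair: PatchPair) -> np.ndarray:
        """Deterministic evaluation-mode logits for one patch pair."""
        return self.predict_batch(pair.lateral[None], pair.medial[None])[0]

    def branch_features(self, patch: np.ndarray):
        """Pre-GAP activation maps (C, X, Y) and pooled descriptor (C,) of one patch."""
        x = standardize(patch[None])[:, None].astype(np.float32)
        maps, pooled, _, _ = self._branch_forward(x, train=False)
        return maps[0], pooled[0]

    # -- state -----------------------------------------------------------
    def state_arrays(self) -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        for i, layer in enumerate(self.branch):
            for j, p in enumerate(layer.params()):
                out[f"branch.{i}.{j}"] = p.value
            if isinstance(layer, nn.BatchNorm2d):
                out[f"branch.{i}.running_mean"] = layer.running_mean
                out[f"branch.{i}.running_var"] = layer.running_var
        for j, p in enumerate(self.head.params()):
            out[f"head.{j}"] = p.value
        return out

    def load_state(self, arrays: dict[str, np.ndarray]) -> None:
        for i, layer in enumerate(self.branch):
            for j, p in enumerate(layer.params()):
                p.value = np.array(arrays[f"branch.{i}.{j}"], dtype=np.float32)
            if isinstance(layer, nn.BatchNorm2d):
                layer.running_mean = np.array(arrays[f"branch.{i}.running_mean"],
                                              dtype=np.float32)
                layer.running_var = np.array(arrays[f"branch.{i}.running_var"],
                                             dtype=np.float32)
        for j, p in enumerate(self.head.params()):
            p.value = np.array(arrays[f"head.{j}"], dtype=np.float32)

    def copy_state(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.state_arrays().items()}


def build(spec: BranchSpec, dropout: float = 0.2, n_classes: int = 5,
          input_px: int = 128, seed: int = 0) -> SiameseNet:
    """Construct a :class:`SiameseNet`, validating the branch's spatial trace."""
    return SiameseNet(spec, dropout=dropout, n_classes=n_classes,
                      input_px=input_px, seed=seed)


def standardize(patches: np.ndarray) -> np.ndarray:
    """Per-sample zero-mean/unit-variance standardisation at tensor conversion."""
    p = np.asarray(patches, dtype=np.float32)
    axes = tuple(range(1, p.ndim))
    mean = p.mean(axis=axes, keepdims=True)
    std = p.std(axis=axes, keepdims=True)
    return (p - mean) / (std + 1e-8)


def parameter_count(net: SiameseNet, shared: bool = True) -> int:
    """Learnable parameter count; ``shared=False`` counts the unshared twin."""
    branch = sum(p.value.size for layer in net.branch for p in layer.params())
    head = sum(p.value.size for p in net.head.params())
    return branch * (1 if shared else 2) + head


def save_checkpoint(net: SiameseNet, path, extra: dict | None = None) -> None:
    """Single-file npz checkpoint: weights, running stats, spec and seed."""
    meta = {
        "schema": CHECKPOINT_SCHEMA,
        "widths": list(net.spec.widths),
        "strides": list(net.spec.strides),
        "pool_after": sorted(net.spec.pool_after),
        "base_width": net.spec.base_width,
        "dropout": net.dropout_rate,
        "n_classes": net.n_classes,
        "input_px": net.input_px,
        "seed": net.seed,
        "extra": extra or {},
    }
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **net.state_arrays())


def load_checkpoint(path) -> SiameseNet:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        arrays = {k: data[k] for k in data.files if k != "__meta__"}
    spec = BranchSpec(widths=tuple(meta["widths"]), strides=tuple(meta["strides"]),
                      pool_after=frozenset(meta["pool_after"]),
                      base_width=meta["base_width"])
    net = SiameseNet(spec, dropout=meta["dropout"], n_classes=meta["n_classes"],
                     input_px=meta["input_px"], seed=meta["seed"])
    net.load_state(arrays)
    return net
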