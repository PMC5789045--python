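"""Class-discriminating attention maps for Siamese ensembles (Grad-CAM).

For a target grade c, each branch i contributes an attention map

    A_bar_ci = ReLU( sum_k  w_ik^c * A_i[k] ),

where A_i[k] are the post-ReLU activation maps entering the global average
pooling and w_ik^c is the gradient of the class score y_c with respect to the
k-th pooled feature of branch i.  Because the maps sit immediately before the
GAP, this pooled-feature gradient equals the spatially averaged per-pixel
gradient of the classic formulation — the averaging is absorbed by the
pooling.  (The gradient path from the maps to the score crosses no further
rectifications, so guided backpropagation would produce identical weights at
this layer; plain backpropagation is used.)

For an M-member ensemble, y_c is the fused pre-softmax score; by linearity of
the gradient the ensemble map is the entrywise sum of the member maps, branch
by branch.  Rendering upsamples each map to patch size, un-flips the medial
one, pastes both at their patch origins (max where they overlap) and min-max
normalises the canvas.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates

from .ensemble import EnsembleBundle
from .model import SiameseNet
from .patches import PatchGeometry, PatchPair

__all__ = ["AttentionPair", "AttentionOverlay", "branch_cam", "ensemble_cam",
           "render_overlay"]


@dataclass
class AttentionPair:
    """Per-branch attention maps for one target class, plus patch geometry."""

    lateral_map: np.ndarray
    medial_map: np.ndarray
    target_class: int
    geometry: PatchGeometry

    def __post_init__(self) -> None:
        if (self.lateral_map < 0).any() or (self.medial_map < 0).any():
            raise ValueError("attention maps are rectified and must be non-negative")
        if self.lateral_map.shape != self.medial_map.shape:
            raise ValueError("lateral and medial maps must have equal shape")


@dataclass
class AttentionOverlay:
    """Min-max normalised heatmap in the resized joint-image frame."""

    heatmap: np.ndarray
    target_class: int


def _head_weights(net: SiameseNet, c: int) -> tuple[np.ndarray, np.ndarray]:
    """Gradient of logit c w.r.t. the two pooled branch descriptors.

    Backpropagation through the head: dropout is identity in evaluation mode
    and the linear layer's input-gradient for a one-hot output is its weight
    row, split between the lateral and medial halves of the concatenation.
    """
    if not 0 <= c < net.n_classes:
        raise ValueError(f"class index {c} outside [0, {net.n_classes})")
    row = net.head.W.value[c].astype(np.float64)
    half = net.descriptor_dim // 2
    return row[:half], row[half:]


def branch_cam(net: SiameseNet, pair: PatchPair, c: int) -> AttentionPair:
    """Single-model gradient-weighted attention maps for class ``c``."""
    w_lat, w_med = _head_weights(net, c)
    maps = []
    for patch, w in ((pair.lateral, w_lat), (pair.medial, w_med)):
        acts, _ = net.branch_features(patch)
        cam = np.tensordot(w, acts.astype(np.float64), axes=([0], [0]))
        maps.append(np.maximum(cam, 0.0))
    return AttentionPair(maps[0], maps[1], c, pair.geometry)


def ensemble_cam(bundle: EnsembleBundle, pair: PatchPair, c: int) -> AttentionPair:
    """Ensemble attention: entrywise sum of member maps, branch by branch."""
    members = [branch_cam(net, pair, c) for net in bundle.members]
    shapes = {m.lateral_map.shape for m in members}
    if len(shapes) > 1:
        raise ValueError(f"members produce mixed map sizes: {sorted(shapes)}")
    lat = np.sum([m.lateral_map for m in members], axis=0)
    med = np.sum([m.medial_map for m in members], axis=0)
    return AttentionPair(lat, med, c, pair.geometry)


def _upsample(cam: np.ndarray, size: int) -> np.ndarray:
    """Endpoint-aligned bilinear upsampling of a small map to ``size`` pixels."""
    h, w = cam.shape
    ys = np.linspace(0.0, h - 1.0, size)
    xs = np.linspace(0.0, w - 1.0, size)
    grid = np.meshgrid(ys, xs, indexing="ij")
    return map_coordinates(cam, grid, order=1, mode="nearest")


def render_overlay(maps: AttentionPair, geom: PatchGeometry | None = None,
                   resized_px: int | None = None) -> AttentionOverlay:
    """Project both maps back onto the resized joint image.

    The medial map is horizontally flipped back into image orientation.  Where
    the two patches overlap the pointwise maximum is kept so the canvas stays
    interpretable after min-max normalisation.  An identically zero raw map
    yields an all-zero overlay.
    """
    geom = geom or maps.geometry
    resized_px = resized_px or geom.resized_px
    s = geom.S
    canvas = np.zeros((resized_px, resized_px))
    lat = _upsample(maps.lateral_map, s)
    med = np.fliplr(_upsample(maps.medial_map, s))
    for patch_map, (ox, oy) in ((lat, geom.lateral_origin),
                                (med, geom.medial_origin)):
        region = canvas[oy : oy + s, ox : ox + s]
        np.maximum(region, patch_map, out=region)
    lo, hi = canvas.min(), canvas.max()
    if hi > lo:
        canvas = (canvas - lo) / (hi - lo)
    else:
        canvas = np.zeros_like(canvas)
    return AttentionOverlay(canvas, maps.target_class)
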