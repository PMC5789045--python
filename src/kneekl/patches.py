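"""Symmetric lateral/medial patch-pair extraction.

The normalised 130x130 mm joint image is resampled to a fixed pixel grid
(default 300x300) and two square S x S patches are cut: one at the lateral
edge and one at the medial edge of the joint.  The medial patch is stored
horizontally flipped so that both patches present the joint margin in the same
orientation — this is what lets the two network branches share weights.

Default geometry: S = 128, shared vertical offset K = 100, lateral patch at
x = 0, medial patch right-aligned at x = resized_px - S.  A "literal" variant
with the medial origin at x = S - K is also constructible (see
:meth:`PatchGeometry.default`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import resize as _sk_resize

from .errors import GeometryError
from .preprocess import NormalizedImage

__all__ = ["PatchGeometry", "PatchPair", "resize_to_grid", "extract_pair",
           "project_patch_to_image"]


@dataclass(frozen=True)
class PatchGeometry:
    """Placement of the two S x S patches on the resized joint image."""

    resized_px: int = 300
    S: int = 128
    K: int = 100
    lateral_origin: tuple[int, int] = (0, 100)   # (x, y)
    medial_origin: tuple[int, int] = (172, 100)  # (x, y)

    def __post_init__(self) -> None:
        if self.S > self.resized_px:
            raise GeometryError("patch side S exceeds the resized image")
        if self.lateral_origin[0] != 0:
            raise GeometryError("lateral patch must start at x = 0")
        for name, (x, y) in (("lateral", self.lateral_origin),
                             ("medial", self.medial_origin)):
            if x < 0 or y < 0 or x + self.S > self.resized_px or y + self.S > self.resized_px:
                raise GeometryError(f"{name} patch at ({x}, {y}) leaves the image")

    @classmethod
    def default(cls, resized_px: int = 300, S: int = 128, K: int = 100,
                medial: str = "right_aligned") -> "PatchGeometry":
        """Build the standard geometry.

        ``medial="right_aligned"`` places the medial patch flush with the right
        edge (x = resized_px - S), covering the medial joint margin;
        ``medial="literal"`` uses x = S - K instead, which overlaps the lateral
        half — kept constructible for comparison.
        """
        if medial == "right_aligned":
            mx = resized_px - S
        elif medial == "literal":
            mx = S - K
        else:
            raise ValueError("medial must be 'right_aligned' or 'literal'")
        return cls(resized_px=resized_px, S=S, K=K,
                   lateral_origin=(0, K), medial_origin=(mx, K))


@dataclass
class PatchPair:
    """Lateral and (already flipped) medial patches forming one network input."""

    lateral: np.ndarray
    medial: np.ndarray
    geometry: PatchGeometry
    source_id: str = ""

    def __post_init__(self) -> None:
        s = self.geometry.S
        if self.lateral.shape != (s, s) or self.medial.shape != (s, s):
            raise GeometryError(
                f"patches must be {s}x{s}, got {self.lateral.shape} and {self.medial.shape}"
            )


def resize_to_grid(img: NormalizedImage | np.ndarray, resized_px: int = 300) -> np.ndarray:
    """Bilinear resample to a square ``resized_px`` grid; output stays in [0, 255]."""
    pixels = img.pixels if isinstance(img, NormalizedImage) else np.asarray(img)
    if pixels.shape == (resized_px, resized_px):
        return pixels.astype(np.float64)
    out = _sk_resize(pixels.astype(np.float64), (resized_px, resized_px),
                     order=1, mode="edge", anti_aliasing=False, preserve_range=True)
    return np.clip(out, 0.0, 255.0)


def extract_pair(img: np.ndarray, geom: PatchGeometry, source_id: str = "") -> PatchPair:
    """Cut the lateral and medial patches; the medial one is stored flipped."""
    img = np.asarray(img)
    if img.shape != (geom.resized_px, geom.resized_px):
        raise GeometryError(
            f"image shape {img.shape} does not match geometry grid "
            f"{geom.resized_px}x{geom.resized_px}"
        )
    s = geom.S
    lx, ly = geom.lateral_origin
    mx, my = geom.medial_origin
    lateral = img[ly : ly + s, lx : lx + s].copy()
    medial = np.fliplr(img[my : my + s, mx : mx + s])
    return PatchPair(lateral, medial, geom, source_id)


def project_patch_to_image(patch_coords: tuple[int, int], which: str,
                           geom: PatchGeometry) -> tuple[int, int]:
    """Map (x, y) in a patch frame back to the resized-image frame.

    Inverse of :func:`extract_pair`'s coordinate mapping; for the medial patch
    this includes undoing the horizontal flip: x -> medial_x + (S - 1 - x).
    """
    x, y = patch_coords
    if not (0 <= x < geom.S and 0 <= y < geom.S):
        raise GeometryError(f"({x}, {y}) lies outside an S={geom.S} patch")
    if which == "lateral":
        ox, oy = geom.lateral_origin
        return (ox + x, oy + y)
    if which == "medial":
        ox, oy = geom.medial_origin
        return (ox + (geom.S - 1 - x), oy + y)
    raise ValueError("which must be 'lateral' or 'medial'")
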