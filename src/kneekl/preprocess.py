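"""Intensity and geometry normalisation of localised knee-joint radiograph regions.

Raw inputs are 16-bit region-of-interest crops of the knee joint with a known
physical pixel spacing (mm/px) and a side label.  The pipeline implemented here
turns them into 8-bit images of a fixed physical extent:

1. left knees are mirrored so that every joint is in right-knee orientation,
2. intensities are clipped to inner percentiles (default 5th-99th) and affinely
   rescaled to the full 8-bit range,
3. a centred crop of fixed physical size (default 130 mm) is taken,
4. optionally, over-/under-exposed images are gamma corrected at test time.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import DegenerateImageError, GeometryError

__all__ = [
    "KneeROI",
    "NormalizedImage",
    "truncate_and_rescale",
    "flip_if_left",
    "center_crop_mm",
    "gamma_correct",
    "auto_exposure_gamma",
    "EXPOSURE_BAND",
    "EXPOSURE_GAMMA_GRID",
]

#: Mean-intensity band considered well exposed (8-bit units).
EXPOSURE_BAND = (60.0, 180.0)
#: Candidate gammas tried, in order, when the mean falls outside the band.
EXPOSURE_GAMMA_GRID = (0.5, 0.67, 1.5, 2.0)


@dataclass
class KneeROI:
    """One localised knee-joint image.

    Parameters
    ----------
    pixels
        2-D intensity array in 16-bit range.
    spacing_mm
        Physical size of one pixel in millimetres.
    side
        ``"left"`` or ``"right"``; left knees are mirrored downstream so a
        single right-oriented model serves both.
    kl_grade
        Optional Kellgren-Lawrence grade 0-4.
    source_id
        Opaque identifier carried through the pipeline.
    margin_mask
        Optional boolean mask of the joint-margin (osteophyte) region, same
        shape as ``pixels``; populated by the phantom generator for attention
        localisation checks.
    """

    pixels: np.ndarray
    spacing_mm: float
    side: str
    kl_grade: int | None = None
    source_id: str = ""
    margin_mask: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or min(self.pixels.shape) < 8:
            raise ValueError("pixels must be 2-D with both dimensions >= 8")
        if not self.spacing_mm > 0:
            raise ValueError("spacing_mm must be positive")
        if self.side not in ("left", "right"):
            raise ValueError(f"side must be 'left' or 'right', got {self.side!r}")
        if self.kl_grade is not None:
            if int(self.kl_grade) != self.kl_grade or not 0 <= self.kl_grade <= 4:
                raise ValueError("kl_grade must be an integer in [0, 4]")
            self.kl_grade = int(self.kl_grade)


@dataclass
class NormalizedImage:
    """8-bit image with its physical extent.

    ``pixels`` is a uint8 array; the physical size follows from the stored
    pixel spacing.
    """

    pixels: np.ndarray
    spacing_mm: float
    source_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be 2-D")
        if self.pixels.min() < 0 or self.pixels.max() > 255:
            raise ValueError("intensities must lie within [0, 255]")
        if not self.spacing_mm > 0:
            raise ValueError("spacing_mm must be positive")

    @property
    def physical_size_mm(self) -> tuple[float, float]:
        h, w = self.pixels.shape
        return (h * self.spacing_mm, w * self.spacing_mm)


def _to_uint8(values: np.ndarray) -> np.ndarray:
    # round-half-to-even (np.rint), then clip: the one rounding rule used
    # everywhere an intensity goes back to 8 bits
    return np.clip(np.rint(values), 0, 255).astype(np.uint8)


def truncate_and_rescale(
    roi: KneeROI, lo_pct: float = 5.0, hi_pct: float = 99.0
) -> NormalizedImage:
    """Clip to inner percentiles and affinely map to the 8-bit range.

    The ``lo_pct`` and ``hi_pct`` percentile values of the input become 0 and
    255; intensities outside are saturated.  This suppresses detector noise in
    the histogram tails before quantisation to 8 bits.

    Raises
    ------
    DegenerateImageError
        If the two percentile values coincide (constant image).
    """
    if not lo_pct < hi_pct:
        raise ValueError("lo_pct must be smaller than hi_pct")
    img = np.asarray(roi.pixels, dtype=np.float64)
    lo, hi = np.percentile(img, [lo_pct, hi_pct])
    if hi <= lo:
        raise DegenerateImageError(
            f"percentiles {lo_pct} and {hi_pct} coincide at {lo}; image has no contrast"
        )
    scaled = (np.clip(img, lo, hi) - lo) / (hi - lo) * 255.0
    return NormalizedImage(_to_uint8(scaled), roi.spacing_mm, roi.source_id)


def flip_if_left(roi: KneeROI) -> KneeROI:
    """Mirror left knees about the vertical axis and relabel them right.

    Right knees pass through unchanged, so a single right-knee-oriented model
    serves both sides.  The margin mask, when present, is mirrored alongside.
    """
    if roi.side == "right":
        return roi
    mask = None if roi.margin_mask is None else np.fliplr(roi.margin_mask)
    return replace(roi, pixels=np.fliplr(roi.pixels), side="right", margin_mask=mask)


def center_crop_mm(img: NormalizedImage, target_mm: float) -> NormalizedImage:
    """Centred square crop of physical side ``target_mm``.

    The crop size in pixels is ``round(target_mm / spacing)``.  When the margin
    is odd the extra pixel is dropped from the top/left, i.e. the crop sits one
    pixel toward the bottom/right — a fixed convention so crops are
    deterministic.
    """
    target_px = int(round(target_mm / img.spacing_mm))
    h, w = img.pixels.shape
    if target_px > h or target_px > w:
        raise GeometryError(
            f"crop of {target_mm} mm ({target_px} px) exceeds image {h}x{w} px"
        )
    top = (h - target_px) // 2
    left = (w - target_px) // 2
    out = img.pixels[top : top + target_px, left : left + target_px]
    return NormalizedImage(out, img.spacing_mm, img.source_id)


def gamma_correct(img: NormalizedImage, gamma: float) -> NormalizedImage:
    """Power-law contrast change ``v -> 255 * (v / 255) ** gamma``.

    Monotone for every ``gamma > 0``; 0 and 255 are fixed points.  ``gamma < 1``
    brightens (lifts mid-tones), ``gamma > 1`` darkens.
    """
    if not gamma > 0:
        raise ValueError("gamma must be positive")
    v = img.pixels.astype(np.float64) / 255.0
    return NormalizedImage(_to_uint8(255.0 * v**gamma), img.spacing_mm, img.source_id)


def auto_exposure_gamma(
    img: NormalizedImage,
    band: tuple[float, float] = EXPOSURE_BAND,
    gamma_grid: tuple[float, ...] = EXPOSURE_GAMMA_GRID,
) -> NormalizedImage:
    """Gamma-correct over-/under-exposed images at test time.

    If the mean intensity already lies inside ``band`` the image is returned
    unchanged.  Otherwise the gammas in ``gamma_grid`` are tried in order and
    the first one whose corrected mean lands inside the band is applied; if
    none lands inside, the gamma bringing the mean closest to the band is used.
    """
    lo, hi = band
    mean = float(img.pixels.mean())
    if lo <= mean <= hi:
        return img
    best = None
    best_dist = np.inf
    for g in gamma_grid:
        corrected = gamma_correct(img, g)
        m = float(corrected.pixels.mean())
        if lo <= m <= hi:
            return corrected
        dist = lo - m if m < lo else m - hi
        if dist < best_dist:
            best, best_dist = corrected, dist
    return best if best is not None else img
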