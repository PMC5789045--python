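"""Grade-labelled phantom knee radiographs.

The phantom is a two-bone construct on a soft-tissue background: a femoral
band above and a tibial band below a joint gap whose width shrinks with KL
grade (joint-space narrowing).  Marginal osteophytes are modelled as bony
bump profiles protruding into the gap at the lateral and medial image edges,
with grade-dependent amplitude, and subchondral sclerosis as a brightness
gain in bands just inside the two joint surfaces.  Gaussian noise, a random
global intensity offset, a small joint-line tilt and a random side (left
phantoms are mirrored) complete the image.

Each phantom carries a ground-truth joint-margin mask (the osteophyte zone)
so attention maps can be checked for anatomical localisation.  The generator
emulates the radiographic KL features the grading model keys on; it makes no
attempt at realistic trabecular texture, patellar shadow or implants.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.transform import resize as _sk_resize

from .preprocess import KneeROI

__all__ = ["PhantomConfig", "make_phantom", "make_dataset", "measure_gap_mm",
           "project_mask_to_resized"]


@dataclass(frozen=True)
class PhantomConfig:
    """Phantom geometry and per-grade feature strengths.

    ``joint_space_mm`` must decrease strictly with grade, ``osteophyte_amp_mm``
    must be non-decreasing; both are in millimetres.  ``noise_sd`` is in 16-bit
    intensity units.
    """

    image_px: int = 280
    spacing_mm: float = 0.5
    joint_space_mm: tuple[float, ...] = (6.0, 5.0, 4.0, 2.5, 1.0)
    osteophyte_amp_mm: tuple[float, ...] = (0.0, 0.4, 1.0, 1.8, 2.8)
    sclerosis_gain: tuple[float, ...] = (0.0, 0.04, 0.10, 0.20, 0.32)
    noise_sd: float = 600.0
    gap_jitter_mm: float = 0.25
    seed: int = 0

    #: intensity levels, 16-bit units
    soft_tissue: float = 9000.0
    bone: float = 26000.0

    def __post_init__(self) -> None:
        js = self.joint_space_mm
        if any(b >= a for a, b in zip(js, js[1:])):
            raise ValueError("joint_space_mm must decrease strictly with grade")
        oa = self.osteophyte_amp_mm
        if any(b < a for a, b in zip(oa, oa[1:])):
            raise ValueError("osteophyte_amp_mm must be non-decreasing")
        for t in (js, oa, self.sclerosis_gain):
            if len(t) != 5:
                raise ValueError("per-grade tuples need exactly five entries")


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


def make_phantom(grade: int, cfg: PhantomConfig | None = None,
                 rng: np.random.Generator | int | None = None,
                 source_id: str = "") -> KneeROI:
    """Render one phantom of the given KL grade.

    Deterministic for a fixed rng state (or integer seed).  The returned ROI
    has ``kl_grade`` set and ``margin_mask`` marking the joint-margin zones.
    """
    if not 0 <= grade <= 4:
        raise ValueError("grade must be in 0..4")
    cfg = cfg or PhantomConfig()
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(cfg.seed if rng is None else int(rng))

    n = cfg.image_px
    extent = n * cfg.spacing_mm
    x_mm = (np.arange(n) + 0.5) * cfg.spacing_mm
    y_mm = ((np.arange(n) + 0.5) * cfg.spacing_mm)[:, None]

    center = extent / 2.0 + rng.uniform(-2.0, 2.0)
    tilt = rng.uniform(-0.03, 0.03)  # mm of joint-line drop per mm across
    gap = cfg.joint_space_mm[grade] + float(
        np.clip(rng.normal(0.0, cfg.gap_jitter_mm), -0.5, 0.5))

    line = center + tilt * (x_mm - extent / 2.0)
    femur_edge = line - gap / 2.0
    tibia_edge = line + gap / 2.0

    # marginal osteophytes: exponential bump profiles anchored at both edges
    amp = cfg.osteophyte_amp_mm[grade]
    profile = np.exp(-x_mm / 6.0) + np.exp(-(extent - x_mm) / 6.0)
    femur_edge = femur_edge + amp * profile
    tibia_edge = tibia_edge - amp * profile
    mid = (femur_edge + tibia_edge) / 2.0
    femur_edge = np.minimum(femur_edge, mid - 0.15)  # keep a sliver of gap
    tibia_edge = np.maximum(tibia_edge, mid + 0.15)

    w = 0.35  # edge softness, mm
    f_femur = _sigmoid((femur_edge - y_mm) / w) * _sigmoid((y_mm - 5.0) / 1.5)
    f_tibia = _sigmoid((y_mm - tibia_edge) / w) * _sigmoid((extent - 5.0 - y_mm) / 1.5)
    bone_frac = np.clip(f_femur + f_tibia, 0.0, 1.0)
    img = cfg.soft_tissue + bone_frac * (cfg.bone - cfg.soft_tissue)

    # subchondral sclerosis: brighten 3 mm bands inside both joint surfaces
    gain = cfg.sclerosis_gain[grade]
    if gain > 0:
        scl = (((femur_edge - y_mm) > 0) & ((femur_edge - y_mm) < 3.0)) * f_femur \
            + (((y_mm - tibia_edge) > 0) & ((y_mm - tibia_edge) < 3.0)) * f_tibia
        img = img * (1.0 + gain * np.clip(scl, 0.0, 1.0))

    img = img + rng.uniform(-800.0, 800.0)
    if cfg.noise_sd > 0:
        img = img + rng.normal(0.0, cfg.noise_sd, img.shape)
    pixels = np.clip(img, 0, 65535).astype(np.uint16)

    near_edge = (np.abs(y_mm - femur_edge) < 4.0) | (np.abs(y_mm - tibia_edge) < 4.0)
    margin_zone = (x_mm < 40.0) | (x_mm > extent - 40.0)
    mask = near_edge & margin_zone

    side = str(rng.choice(["left", "right"]))
    if side == "left":
        pixels = np.fliplr(pixels)
        mask = np.fliplr(mask)
    return KneeROI(pixels=pixels, spacing_mm=cfg.spacing_mm, side=side,
                   kl_grade=grade, source_id=source_id, margin_mask=mask)


def make_dataset(n_per_grade: int, cfg: PhantomConfig | None = None,
                 split: tuple[float, float, float] = (0.6, 0.2, 0.2)):
    """Balanced labelled phantom set with a train/val/test split by phantom id.

    Returns ``(rois, manifest)`` where the manifest records id, grade,
    per-phantom seed and split, and is identical across runs with the same
    master seed.
    """
    if n_per_grade < 1:
        raise ValueError("n_per_grade must be at least 1")
    if abs(sum(split) - 1.0) > 1e-9:
        raise ValueError("split fractions must sum to 1")
    cfg = cfg or PhantomConfig()
    master = np.random.default_rng(cfg.seed)

    rois: list[KneeROI] = []
    rows = []
    for grade in range(5):
        n_train = int(round(split[0] * n_per_grade))
        n_val = int(round(split[1] * n_per_grade))
        splits = (["train"] * n_train + ["val"] * n_val
                  + ["test"] * (n_per_grade - n_train - n_val))
        order = master.permutation(n_per_grade)
        for i in range(n_per_grade):
            seed = int(master.integers(2**31))
            sid = f"ph{cfg.seed}_g{grade}_{i:04d}"
            roi = make_phantom(grade, cfg, rng=seed, source_id=sid)
            rois.append(roi)
            rows.append({"source_id": sid, "kl_grade": grade, "seed": seed,
                         "side": roi.side, "split": splits[order[i]]})
    manifest = pd.DataFrame(rows)
    return rois, manifest


def measure_gap_mm(roi: KneeROI, band_mm: float = 5.0) -> float:
    """Hand-crafted joint-space width: threshold the central column profile.

    Averages a central vertical band, thresholds at the mid-intensity, and
    returns the length of the longest soft-tissue run between the two bone
    bands.  Used to check grade separability of the generator, independent of
    any learned model.
    """
    img = roi.pixels.astype(np.float64)
    n = img.shape[1]
    half = max(1, int(band_mm / roi.spacing_mm / 2))
    profile = img[:, n // 2 - half : n // 2 + half].mean(axis=1)
    thresh = 0.5 * (profile.min() + profile.max())
    is_bone = profile > thresh
    bone_rows = np.flatnonzero(is_bone)
    if bone_rows.size == 0:
        return float("nan")
    lo, hi = bone_rows[0], bone_rows[-1]
    best = cur = 0
    for v in is_bone[lo : hi + 1]:
        cur = 0 if v else cur + 1
        best = max(best, cur)
    return best * roi.spacing_mm


def project_mask_to_resized(mask: np.ndarray, spacing_mm: float,
                            crop_mm: float = 130.0,
                            resized_px: int = 300) -> np.ndarray:
    """Carry an ROI-frame boolean mask through centre-crop and grid resize.

    Mirrors the geometric part of the preprocessing pipeline (same crop
    convention, nearest-neighbour resampling) so phantom feature masks can be
    compared against attention overlays in the resized-image frame.
    """
    target_px = int(round(crop_mm / spacing_mm))
    h, w = mask.shape
    top, left = (h - target_px) // 2, (w - target_px) // 2
    cropped = mask[top : top + target_px, left : left + target_px]
    out = _sk_resize(cropped.astype(float), (resized_px, resized_px),
                     order=0, anti_aliasing=False, preserve_range=True)
    return out > 0.5
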