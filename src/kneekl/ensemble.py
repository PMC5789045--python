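"""Seed-ensemble fusion of Siamese grading models.

M models trained from different random seeds imitate a committee of readers.
Their *pre-softmax* score vectors are summed and the sum is passed through a
single softmax, yielding one probability distribution over the five KL grades:

    P(y = j | x) = exp(sum_m z_mj) / sum_k exp(sum_m z_mk)

where z_m is member m's unnormalised score vector.  Note the normalising sum
in the denominator runs over the class index k — summing the member scores
inside a single exponential without that per-class sum would not normalise.
Averaging per-member softmax outputs is a different (also valid) fusion rule;
the one implemented here fuses *before* the softmax, which acts like a
temperature-sharpened committee vote.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import SiameseNet, standardize
from .nn import softmax
from .patches import PatchPair

__all__ = ["GradeDistribution", "EnsembleBundle", "fuse", "fuse_batch",
           "fuse_logits", "oa_probability"]


@dataclass
class GradeDistribution:
    """Probability vector over KL grades 0..4."""

    probs: np.ndarray

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=np.float64)
        if self.probs.shape != (5,):
            raise ValueError("a grade distribution has exactly five entries")
        if (self.probs < 0).any() or abs(self.probs.sum() - 1.0) > 1e-6:
            raise ValueError("entries must be non-negative and sum to 1")

    @property
    def argmax_grade(self) -> int:
        return int(self.probs.argmax())


@dataclass
class EnsembleBundle:
    """M trained models plus the seeds they were initialised with."""

    members: list[SiameseNet]
    seeds: list[int] = field(default_factory=lambda: [21, 42, 84])

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("an ensemble needs at least one member")
        spec = self.members[0].spec
        if any(m.spec != spec for m in self.members[1:]):
            raise ValueError("all ensemble members must share one branch spec")

    def __len__(self) -> int:
        return len(self.members)


def fuse_logits(member_logits: np.ndarray) -> np.ndarray:
    """Core fusion rule: softmax over the member-summed pre-softmax scores.

    ``member_logits`` has shape (M, ..., K); the sum runs over the leading
    member axis and the softmax (max-subtracted for stability) over the last.
    """
    stacked = np.asarray(member_logits, dtype=np.float64)
    if stacked.ndim < 2 or stacked.shape[0] < 1:
        raise ValueError("member_logits must be (M, ..., K) with M >= 1")
    return softmax(stacked.sum(axis=0), axis=-1)


def fuse_batch(bundle: EnsembleBundle, lateral: np.ndarray,
               medial: np.ndarray) -> np.ndarray:
    """Fused (n, 5) grade probabilities for a batch of raw patch arrays."""
    lat, med = standardize(lateral), standardize(medial)
    logits = [net.forward_batch(lat, med)[0] for net in bundle.members]
    return fuse_logits(np.stack(logits))


def fuse(bundle: EnsembleBundle, pair: PatchPair) -> GradeDistribution:
    """Softmax of the summed member scores for one patch pair."""
    probs = fuse_batch(bundle, pair.lateral[None], pair.medial[None])[0]
    return GradeDistribution(probs)


def oa_probability(dist: GradeDistribution) -> float:
    """Radiographic-OA score: probability mass on grades >= 2."""
    return float(dist.probs[2:].sum())
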