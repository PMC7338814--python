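"""Semi-automated gold-standard protocol and rater consensus.

The protocol thresholds FLAIR at a percentage of the median whole-brain
intensity — a high cut for fuzzy/confluent hyperintensities and a lower cut
for well-defined punctate lesions — grows lesions from rater-placed seeds,
and admits manual voxel edits. Scanner-specific percentages compensate for
vendor intensity behaviour (GE scans run hotter posteriorly, so both cuts
sit higher). Four raters are fused by nested majority voting: each
leave-one-out triplet votes 2-of-3 per voxel, then the four triplet maps
are combined by an overall majority.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .utils import connectivity_structure

__all__ = [
    "ThresholdConfig",
    "SCANNER_THRESHOLDS",
    "RaterSegmentation",
    "median_brain_intensity",
    "threshold_map",
    "grow_from_seed",
    "apply_edits",
    "consensus",
    "volume_difference_ok",
]


@dataclass(frozen=True)
class ThresholdConfig:
    """Scanner-specific protocol thresholds, as % of median brain intensity."""

    scanner: str
    high_pct: float
    low_pct: float
    view_max_pct: float

    def __post_init__(self):
        if not (self.high_pct > self.low_pct > 100.0):
            raise ValueError(
                f"need high_pct > low_pct > 100, got {self.high_pct}/{self.low_pct}"
            )


#: Default protocol table. Siemens and Philips share 130/120; GE scans show
#: a hyperintense posterior region, so both cuts are raised to 145/130.
SCANNER_THRESHOLDS = {
    "Siemens": ThresholdConfig("Siemens", 130.0, 120.0, 238.0),
    "Philips": ThresholdConfig("Philips", 130.0, 120.0, 238.0),
    "GE": ThresholdConfig("GE", 145.0, 130.0, 340.0),
}


@dataclass
class RaterSegmentation:
    mask: np.ndarray
    rater_id: str

    def __post_init__(self):
        self.mask = np.asarray(self.mask, bool)


def median_brain_intensity(flair, brain_mask) -> float:
    """Median FLAIR intensity over the brain mask (mean of the central pair
    for an even voxel count)."""
    brain_mask = np.asarray(brain_mask, bool)
    if not brain_mask.any():
        raise ValueError("brain mask is empty")
    return float(np.median(np.asarray(flair, float)[brain_mask]))


def threshold_map(flair, median, pct, brain_mask=None, strict_gt=False):
    """Voxels at or above ``pct`` % of the median brain intensity.

    The protocol wording is "exceeds"; the default here is inclusive (>=),
    with ``strict_gt=True`` switching to a strict comparison.
    """
    if not median > 0:
        raise ValueError("median must be positive")
    flair = np.asarray(flair, float)
    cut = median * pct / 100.0
    out = flair > cut if strict_gt else flair >= cut
    if brain_mask is not None:
        out = out & np.asarray(brain_mask, bool)
    return out


def grow_from_seed(thresh_map, seed, connectivity=6):
    """Connected component of the threshold map containing the seed voxel;
    empty if the seed is below threshold."""
    thresh_map = np.asarray(thresh_map, bool)
    seed = tuple(int(s) for s in seed)
    if len(seed) != 3 or any(
        s < 0 or s >= n for s, n in zip(seed, thresh_map.shape)
    ):
        raise ValueError(f"seed {seed} outside grid {thresh_map.shape}")
    if not thresh_map[seed]:
        return np.zeros_like(thresh_map)
    labels, _ = ndimage.label(
        thresh_map, structure=connectivity_structure(connectivity)
    )
    return labels == labels[seed]


def apply_edits(mask, additions=(), removals=(), rater_id="manual"):
    """Manual interventions: mask union additions minus removals; a voxel in
    both sets is removed (removals take precedence)."""
    out = np.asarray(mask, bool).copy()
    for v in additions:
        out[tuple(v)] = True
    for v in removals:
        out[tuple(v)] = False
    return RaterSegmentation(out, rater_id)


def consensus(raters, overall_majority=3):
    """Nested majority vote over exactly four raters.

    Each of the four leave-one-out triplets votes a voxel positive when at
    least 2 of its 3 raters marked it; the overall consensus requires at
    least ``overall_majority`` (default 3, strict majority) of the four
    triplet votes. With the default rule this is equivalent to direct
    >= 3-of-4 voting.
    """
    masks = [
        np.asarray(r.mask if isinstance(r, RaterSegmentation) else r, bool)
        for r in raters
    ]
    if len(masks) != 4:
        raise ValueError(f"consensus needs exactly 4 raters, got {len(masks)}")
    shape = masks[0].shape
    if any(m.shape != shape for m in masks):
        raise ValueError("rater masks must share one grid")
    triplets = [(0, 1, 2), (0, 1, 3), (1, 2, 3), (0, 2, 3)]
    votes = np.zeros(shape, dtype=np.int8)
    for t in triplets:
        s = sum(masks[i].astype(np.int8) for i in t)
        votes += (s >= 2).astype(np.int8)
    return votes >= overall_majority


def volume_difference_ok(vol_a_ml, vol_b_ml, tolerance=0.15):
    """Helper mirroring the rater-acceptance check: relative volume
    difference within ``tolerance`` (default 15%) of the mean volume."""
    mean = 0.5 * (vol_a_ml + vol_b_ml)
    if mean <= 0:
        return vol_a_ml == vol_b_ml
    return abs(vol_a_ml - vol_b_ml) / mean <= tolerance
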