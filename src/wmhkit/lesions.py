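"""From fitted mixture to final WMH mask.

Candidate lesion voxels come from the outlier part of the tissue model,
scored by their "outlierness": the squared Mahalanobis distance to healthy
(inlier) white matter, restricted to voxels that are both better explained
by an outlier component than by any inlier and hyperintense on FLAIR
relative to white matter. A high threshold T captures the bulk of the
lesions; a second pass at 2T/3 rescues small clusters (< 60 voxels, where
partial-volume dilution lowers the score) that are disjoint from the
primary detections. Connected components are classified first at
18-neighbourhood then re-partitioned at 6-neighbourhood, so false-positive
rules act on the finer 6-subcomponents without discarding mixed-origin
regions wholesale. Surviving voxels carry their outlier responsibility as a
probability, and volumes are integrals of that probabilistic map.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from sklearn.base import BaseEstimator, clone

from .mixture import (
    GaussianTissueMixture,
    ModelFitResult,
    _mahalanobis_sq,
    estimate_bias_field,
    fit_em,
    init_model,
)
from .utils import connectivity_structure
from .volumes import LesionMask, MultimodalVolume

__all__ = [
    "ComponentLabels",
    "CandidateSet",
    "classify_components",
    "compute_outlierness",
    "select_candidates",
    "rescue_small_clusters",
    "correct_false_positives",
    "integrate_volume",
    "WMHSegmenter",
]


@dataclass
class ComponentLabels:
    """Two-stage connected components: 18-neighbourhood parents, then a
    6-neighbourhood re-partition of each parent."""

    labels18: np.ndarray
    labels6: np.ndarray
    parent: dict  # 6-subcomponent id -> 18-component id

    @property
    def n18(self):
        return int(self.labels18.max())

    @property
    def n6(self):
        return int(self.labels6.max())


def classify_components(mask) -> ComponentLabels:
    """Group lesion voxels under 18-connectivity, then re-partition each
    component under 6-connectivity, keeping the parent link."""
    mask = np.asarray(mask, bool)
    if mask.ndim != 3:
        raise ValueError("expected a 3-D binary mask")
    labels18, _ = ndimage.label(mask, structure=connectivity_structure(18))
    labels6, n6 = ndimage.label(mask, structure=connectivity_structure(6))
    parent = {}
    if n6:
        idx = labels6 > 0
        pairs = np.unique(
            np.column_stack([labels6[idx], labels18[idx]]), axis=0
        )
        parent = {int(a): int(b) for a, b in pairs}
    return ComponentLabels(labels18, labels6, parent)


@dataclass
class CandidateSet:
    """Suprathreshold lesion candidates with provenance per component."""

    labels: np.ndarray  # dense positive component ids; 0 = background
    passes: dict  # component id -> "primary" | "rescued"
    scores: np.ndarray  # the outlierness field the candidates came from
    threshold: float

    @property
    def mask(self):
        return self.labels > 0

    def table(self) -> pd.DataFrame:
        ids = [i for i in np.unique(self.labels) if i > 0]
        rows = []
        for i in ids:
            sel = self.labels == i
            rows.append(
                {
                    "id": int(i),
                    "size": int(sel.sum()),
                    "mean_score": float(self.scores[sel].mean()),
                    "pass": self.passes[int(i)],
                }
            )
        return pd.DataFrame(rows, columns=["id", "size", "mean_score", "pass"])


def compute_outlierness(
    fit: ModelFitResult, X, priors, mask_shape=None, mask=None, flair_index=1
):
    """Outlierness score per voxel of the fit domain.

    Squared Mahalanobis distance to the nearest white-matter inlier
    component, kept only where (a) the total outlier responsibility exceeds
    the total inlier responsibility and (b) FLAIR exceeds the white-matter
    inlier FLAIR mean (lesions are hyperintense); zero elsewhere.
    """
    from .phantom import WM

    X = np.asarray(X, float)
    model = fit.model
    wm_inliers = model.class_components(WM, "inlier")
    if not wm_inliers:
        raise ValueError("model has no white-matter inlier component")
    d2 = np.column_stack(
        [_mahalanobis_sq(X, c.mean, c.cov) for c in wm_inliers]
    ).min(axis=1)

    parts = np.array([c.part == "outlier" for c in model.components])
    resp = fit.responsibilities
    outlier_resp = resp[:, parts].sum(axis=1)
    wm_w = np.array([c.weight for c in wm_inliers])
    wm_flair_mean = float(
        (wm_w / wm_w.sum()) @ np.array([c.mean[flair_index] for c in wm_inliers])
    )
    candidate = (outlier_resp > 1.0 - outlier_resp) & (
        X[:, flair_index] > wm_flair_mean
    )
    scores = np.where(candidate, d2, 0.0)
    if mask is not None:
        vol = np.zeros(mask.shape)
        vol[mask] = scores
        return vol
    return scores


def select_candidates(score_volume, T) -> CandidateSet:
    """Primary candidates: connected components of {score >= T}."""
    if not T > 0:
        raise ValueError("threshold T must be positive")
    score_volume = np.asarray(score_volume, float)
    comp = classify_components(score_volume >= T)
    passes = {i: "primary" for i in range(1, comp.n18 + 1)}
    return CandidateSet(comp.labels18.copy(), passes, score_volume, float(T))


def rescue_small_clusters(
    score_volume, candidates: CandidateSet, T, max_size=60
) -> CandidateSet:
    """Second pass at 2T/3: add components disjoint from every primary
    candidate and strictly smaller than ``max_size`` voxels."""
    score_volume = np.asarray(score_volume, float)
    low = 2.0 * T / 3.0
    low_comp = classify_components(score_volume >= low)
    labels = candidates.labels.copy()
    passes = dict(candidates.passes)
    next_id = int(labels.max()) + 1
    primary = candidates.mask
    for i in range(1, low_comp.n18 + 1):
        sel = low_comp.labels18 == i
        if (sel & primary).any():
            continue
        if sel.sum() >= max_size:
            continue
        labels[sel] = next_id
        passes[next_id] = "rescued"
        next_id += 1
    return CandidateSet(labels, passes, score_volume, float(T))


def correct_false_positives(
    candidates: CandidateSet,
    flair,
    wm_flair_mean,
    probability,
    brain_mask=None,
    csf_prior=None,
    supratentorial=None,
    voxel_mm=(1.0, 1.0, 1.0),
) -> tuple[LesionMask, pd.DataFrame]:
    """Rule-based removal of wrongly classified candidate components.

    Acting on 6-subcomponents of the candidate mask, a component is removed
    if it (a) lies more than half outside the brain mask, (b) has mean CSF
    prior above 0.5 (choroid-plexus proxy), (c) is not hyperintense (mean
    FLAIR <= white-matter mean), or (d) lies more than half outside the
    supratentorial mask. Survivors keep their outlier responsibility as the
    lesion probability.

    Returns the probabilistic lesion mask and a per-component audit table.
    """
    missing = [
        name
        for name, m in (
            ("brain_mask", brain_mask),
            ("csf_prior", csf_prior),
            ("supratentorial", supratentorial),
        )
        if m is None
    ]
    if missing:
        raise ValueError(f"missing context masks: {', '.join(missing)}")
    flair = np.asarray(flair, float)
    probability = np.asarray(probability, float)
    comp = classify_components(candidates.mask)
    keep = np.zeros(candidates.mask.shape, dtype=bool)
    rows = []
    for i in range(1, comp.n6 + 1):
        sel = comp.labels6 == i
        rule = None
        if brain_mask[sel].mean() < 0.5:
            rule = "outside_brain"
        elif csf_prior[sel].mean() > 0.5:
            rule = "csf"
        elif flair[sel].mean() <= wm_flair_mean:
            rule = "not_hyperintense"
        elif supratentorial[sel].mean() < 0.5:
            rule = "infratentorial"
        else:
            keep[sel] = True
        rows.append(
            {
                "subcomponent": i,
                "parent18": comp.parent.get(i),
                "size": int(sel.sum()),
                "removed_by": rule,
            }
        )
    values = np.where(keep, np.clip(probability, 0.0, 1.0), 0.0)
    mask = LesionMask(values, voxel_mm, space="FLAIR")
    return mask, pd.DataFrame(
        rows, columns=["subcomponent", "parent18", "size", "removed_by"]
    )


def integrate_volume(mask: LesionMask) -> float:
    """Lesion load in ml: sum of per-voxel probabilities x voxel volume."""
    return mask.volume_ml()


class WMHSegmenter(BaseEstimator):
    """Full automated WMH segmentation pipeline, scikit-learn style.

    Fits the inlier/outlier tissue mixture (with a bias-field correction
    after the initial one-component fit), scores outlierness against
    healthy white matter, applies the two-threshold candidate selection
    with small-cluster rescue, and removes false positives.

    Parameters
    ----------
    mixture : GaussianTissueMixture, optional
        Prototype mixture estimator (cloned at fit time).
    threshold : float or None
        Primary outlierness threshold T; default is the chi-square 0.95
        quantile at ``n_modalities`` degrees of freedom.
    small_cluster_max : int
        Strict upper bound (exclusive) on rescued component size.
    bias_order : int
        Polynomial order of the bias field (negative disables correction).
    binarize_at : float
        Probability cut used by :meth:`binary_mask`.

    Attributes
    ----------
    mixture_ : fitted GaussianTissueMixture
    bias_ : BiasField or None
    outlier_scores_ : ndarray, score volume
    candidates_ : CandidateSet
    lesion_mask_ : LesionMask (probabilistic)
    component_table_ : DataFrame (false-positive audit)
    lesion_volume_ml_ : float
    threshold_ : float
    """

    def __init__(
        self,
        mixture=None,
        threshold=None,
        small_cluster_max=60,
        bias_order=3,
        binarize_at=0.5,
    ):
        self.mixture = mixture
        self.threshold = threshold
        self.small_cluster_max = small_cluster_max
        self.bias_order = bias_order
        self.binarize_at = binarize_at

    def fit(
        self,
        images: MultimodalVolume,
        atlas: dict,
        mask,
        brain_mask=None,
        csf_prior=None,
        supratentorial=None,
        classes=None,
    ):
        """Segment one subject.

        Parameters
        ----------
        images : MultimodalVolume
        atlas : dict tissue class -> prior probability volume
        mask : bool volume, the fit domain (head)
        brain_mask, csf_prior, supratentorial : context for false-positive
            rules; ``brain_mask`` defaults to ``mask``, ``supratentorial``
            to the brain mask, ``csf_prior`` to the atlas CSF map.
        """
        from .phantom import CSF

        mask = np.asarray(mask, bool)
        if brain_mask is None:
            brain_mask = mask
        if supratentorial is None:
            supratentorial = brain_mask
        if classes is None:
            classes = sorted(atlas.keys())
        if csf_prior is None:
            csf_prior = atlas.get(CSF, np.zeros(images.shape))

        priors = np.column_stack([atlas[c][mask] for c in classes])
        X = images.stack(mask)

        proto = self.mixture if self.mixture is not None else GaussianTissueMixture()
        mix = clone(proto)

        # bias field from the converged initial (1 inlier per class) model
        self.bias_ = None
        raw = [images.t1, images.flair]
        if self.bias_order >= 0:
            model0 = init_model(
                X, priors, classes=classes,
                outlier_fraction=mix.outlier_fraction,
                kappa_outlier=mix.kappa_outlier,
                reg_scale=mix.reg_covar_scale,
            )
            fit0 = fit_em(model0, X, priors, tol=mix.tol,
                          max_iter=mix.max_iter, reg_scale=mix.reg_covar_scale)
            self.bias_ = estimate_bias_field(
                raw, fit0.responsibilities, fit0.model, mask,
                order=self.bias_order,
            )
            corrected = self.bias_.correct(raw)
        else:
            corrected = raw
        images_c = MultimodalVolume(corrected[0], corrected[1], images.voxel_mm)
        Xc = images_c.stack(mask)

        mix.fit(Xc, priors, classes=classes)
        self.mixture_ = mix
        self.corrected_ = images_c

        d = Xc.shape[1]
        T = self.threshold
        if T is None:
            T = float(stats.chi2.ppf(0.95, df=d))
        self.threshold_ = T

        scores = compute_outlierness(mix.fit_result_, Xc, priors)
        score_vol = np.zeros(images.shape)
        score_vol[mask] = scores
        self.outlier_scores_ = score_vol

        primary = select_candidates(score_vol, T)
        self.candidates_ = rescue_small_clusters(
            score_vol, primary, T, max_size=self.small_cluster_max
        )

        parts = np.array(
            [c.part == "outlier" for c in mix.model_.components]
        )
        prob_vol = np.zeros(images.shape)
        prob_vol[mask] = mix.responsibilities_[:, parts].sum(axis=1)

        from .phantom import WM

        wm_inliers = mix.model_.class_components(WM, "inlier")
        wm_w = np.array([c.weight for c in wm_inliers])
        wm_flair_mean = float(
            (wm_w / wm_w.sum()) @ np.array([c.mean[1] for c in wm_inliers])
        )
        self.lesion_mask_, self.component_table_ = correct_false_positives(
            self.candidates_,
            images_c.flair,
            wm_flair_mean,
            prob_vol,
            brain_mask=brain_mask,
            csf_prior=csf_prior,
            supratentorial=supratentorial,
            voxel_mm=images.voxel_mm,
        )
        self.lesion_volume_ml_ = integrate_volume(self.lesion_mask_)
        return self

    def binary_mask(self):
        """Binarized lesion mask (probability >= ``binarize_at``)."""
        return self.lesion_mask_.binarize(self.binarize_at)
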