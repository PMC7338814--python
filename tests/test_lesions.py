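"""Lesion extraction: outlierness, candidate selection, two-threshold
rescue, 18-then-6 connectivity, false-positive rules, volume integration."""

import numpy as np
import pytest
from scipy import ndimage

from wmhkit.lesions import (
    classify_components,
    compute_outlierness,
    correct_false_positives,
    integrate_volume,
    rescue_small_clusters,
    select_candidates,
)
from wmhkit.mixture import (
    GaussianComponent,
    ModelFitResult,
    TissueModel,
    fit_em,
    init_model,
)
from wmhkit.phantom import WM
from wmhkit.volumes import LesionMask


def _wm_fit(X, wm_mean=(100.0, 100.0), wm_sd=10.0, outlier_resp=None):
    """A hand-built fit whose only class is WM, for isolated scoring."""
    n = len(X)
    inlier = GaussianComponent(
        np.array(wm_mean), wm_sd**2 * np.eye(2), 0.9, WM, "inlier"
    )
    outlier = GaussianComponent(
        np.array(wm_mean), 10 * wm_sd**2 * np.eye(2), 0.1, WM, "outlier"
    )
    model = TissueModel([inlier, outlier], [WM])
    if outlier_resp is None:
        outlier_resp = np.ones(n)
    resp = np.column_stack([1.0 - outlier_resp, outlier_resp])
    return ModelFitResult(model, resp, 0.0, 0.0, 1)


def test_outlierness_zero_at_wm_mean_and_for_hypointense():
    X = np.array(
        [
            [100.0, 100.0],  # exactly at the WM mean
            [100.0, 40.0],  # outlier but hypointense on FLAIR
            [100.0, 160.0],  # hyperintense outlier
        ]
    )
    priors = np.ones((3, 1))
    fit = _wm_fit(X)
    scores = compute_outlierness(fit, X, priors)
    assert scores[0] == 0.0
    assert scores[1] == 0.0
    assert scores[2] == pytest.approx(36.0)  # (60/10)^2


def test_outlierness_respects_inlier_vs_outlier_responsibility():
    X = np.array([[100.0, 160.0], [100.0, 160.0]])
    priors = np.ones((2, 1))
    fit = _wm_fit(X, outlier_resp=np.array([0.9, 0.2]))
    scores = compute_outlierness(fit, X, priors)
    assert scores[0] > 0
    assert scores[1] == 0.0


def test_outlierness_requires_wm_inlier():
    X = np.ones((2, 2))
    comp = GaussianComponent(np.zeros(2), np.eye(2), 1.0, 999, "inlier")
    fit = ModelFitResult(TissueModel([comp], [999]), np.ones((2, 1)), 0, 0, 1)
    with pytest.raises(ValueError, match="white-matter"):
        compute_outlierness(fit, X, np.ones((2, 1)))


def test_outlierness_matches_bruteforce_quadratic_form(segmented, small_phantom):
    """Scores on a real fit equal per-voxel quadratic-form evaluation."""
    seg = segmented
    fitres = seg.mixture_.fit_result_
    wm_inliers = fitres.model.class_components(WM, "inlier")
    mask = small_phantom.head_mask
    scores = seg.outlier_scores_[mask]
    X = seg.corrected_.stack(mask)
    rng = np.random.default_rng(0)
    idx = rng.choice(len(X), 200, replace=False)
    for i in idx:
        if scores[i] == 0.0:
            continue  # masked out by the candidate conditions
        best = min(
            float((X[i] - c.mean) @ np.linalg.inv(c.cov) @ (X[i] - c.mean))
            for c in wm_inliers
        )
        assert scores[i] == pytest.approx(best, rel=1e-6)


# --- connectivity ---------------------------------------------------------


def _mask_with(voxels, shape=(4, 4, 4)):
    m = np.zeros(shape, bool)
    for v in voxels:
        m[v] = True
    return m


def test_edge_adjacent_same18_different6():
    comp = classify_components(_mask_with([(0, 0, 0), (1, 1, 0)]))
    assert comp.n18 == 1
    assert comp.n6 == 2
    assert set(comp.parent.values()) == {1}


def test_corner_adjacent_different18():
    comp = classify_components(_mask_with([(0, 0, 0), (1, 1, 1)]))
    assert comp.n18 == 2
    assert comp.n6 == 2


def test_face_adjacent_single_component_both_stages():
    comp = classify_components(_mask_with([(0, 0, 0), (1, 0, 0)]))
    assert comp.n18 == 1
    assert comp.n6 == 1


def _flood_fill_components(mask, neighbours):
    """Brute-force flood fill oracle."""
    mask = np.asarray(mask, bool)
    labels = np.zeros(mask.shape, int)
    current = 0
    for start in zip(*np.nonzero(mask)):
        if labels[start]:
            continue
        current += 1
        stack = [start]
        labels[start] = current
        while stack:
            v = stack.pop()
            for d in neighbours:
                w = tuple(np.add(v, d))
                if any(c < 0 or c >= s for c, s in zip(w, mask.shape)):
                    continue
                if mask[w] and not labels[w]:
                    labels[w] = current
                    stack.append(w)
    return labels


def _neighbour_offsets(connectivity):
    offs = []
    for d in np.ndindex(3, 3, 3):
        d = np.array(d) - 1
        order = np.abs(d).sum()
        if order == 0:
            continue
        if connectivity == 6 and order > 1:
            continue
        if connectivity == 18 and order > 2:
            continue
        offs.append(tuple(d))
    return offs


def test_components_match_flood_fill_oracle(rng):
    mask = rng.random((12, 12, 12)) < 0.25
    comp = classify_components(mask)
    for labels, conn in ((comp.labels18, 18), (comp.labels6, 6)):
        oracle = _flood_fill_components(mask, _neighbour_offsets(conn))
        # same partition up to relabelling
        assert labels.astype(bool).sum() == oracle.astype(bool).sum()
        pairs = set(zip(labels[mask], oracle[mask]))
        assert len(pairs) == len({a for a, _ in pairs})
        assert len(pairs) == len({b for _, b in pairs})


# --- selection and rescue -------------------------------------------------


def test_select_candidates_empty():
    scores = np.zeros((5, 5, 5))
    cand = select_candidates(scores, 5.0)
    assert not cand.mask.any()
    assert cand.table().empty


def test_select_candidates_connectivity():
    scores = np.zeros((8, 8, 8))
    scores[1, 1, 1] = scores[1, 2, 1] = 10.0  # face-sharing pair
    scores[5, 5, 5] = 10.0  # two voxels away from anything
    cand = select_candidates(scores, 10.0)
    assert len(cand.passes) == 2


def test_rescue_size_boundary():
    """Clusters strictly below 60 voxels are rescued; 60 are not."""
    T = 9.0
    scores = np.zeros((20, 20, 20))
    # 59-voxel cluster at a sub-threshold but rescuable score
    block59 = np.zeros_like(scores, bool)
    block59[1:5, 1:5, 1:5] = True  # 64... trim to 59
    idx = np.argwhere(block59)[:59]
    block59 = np.zeros_like(scores, bool)
    block59[tuple(idx.T)] = True
    scores[block59] = 2 * T / 3
    # 60-voxel cluster, same score, far away
    block60 = np.zeros_like(scores, bool)
    idx60 = np.argwhere(np.ones((4, 4, 4), bool))[:60] + 12
    block60[tuple(idx60.T)] = True
    scores[block60] = 2 * T / 3
    primary = select_candidates(scores, T)
    assert not primary.mask.any()
    rescued = rescue_small_clusters(scores, primary, T)
    assert rescued.mask[block59].all()
    assert not rescued.mask[block60].any()
    assert set(rescued.passes.values()) == {"rescued"}
    assert (rescued.table()["size"] < 60).all()


def test_rescue_below_lower_threshold_excluded():
    T = 9.0
    scores = np.zeros((10, 10, 10))
    scores[2:4, 2:4, 2] = 2 * T / 3 - 1e-9
    primary = select_candidates(scores, T)
    rescued = rescue_small_clusters(scores, primary, T)
    assert not rescued.mask.any()


def test_rescue_disjoint_from_primary_and_monotone(rng):
    scores = rng.random((16, 16, 16)) * 12
    T = 9.0
    primary = select_candidates(scores, T)
    out = rescue_small_clusters(scores, primary, T)
    rescued_mask = out.mask & ~primary.mask
    # rescued components never intersect primary ones
    for i, p in out.passes.items():
        sel = out.labels == i
        if p == "rescued":
            assert not (sel & primary.mask).any()
            assert sel.sum() < 60
        else:
            assert (sel == (primary.labels == i)).all()
    # lowering T never removes a primary voxel
    lower = select_candidates(scores, 0.8 * T)
    assert (primary.mask & ~lower.mask).sum() == 0
    assert rescued_mask.sum() >= 0


def test_two_pass_set_identity_vs_bruteforce(rng):
    """Primary U rescue equals the brute-force two-pass construction."""
    for _ in range(5):
        scores = (rng.random((10, 10, 10)) * 10).round(1)
        T = 6.0
        out = rescue_small_clusters(scores, select_candidates(scores, T), T)
        # brute force: high set, plus low-set components (18-conn) that are
        # disjoint from the high set and smaller than 60 voxels
        high = scores >= T
        low = scores >= 2 * T / 3
        oracle = high.copy()
        labels = _flood_fill_components(low, _neighbour_offsets(18))
        for i in range(1, labels.max() + 1):
            sel = labels == i
            if not (sel & high).any() and sel.sum() < 60:
                oracle |= sel
        assert np.array_equal(out.mask, oracle)


# --- false-positive correction and volume --------------------------------


def _toy_candidates(voxels, shape=(10, 10, 10)):
    scores = np.zeros(shape)
    for v in voxels:
        scores[v] = 10.0
    return select_candidates(scores, 5.0)


def test_fp_rule_outside_brain_removed():
    cand = _toy_candidates([(1, 1, 1), (1, 1, 2)])
    brain = np.zeros((10, 10, 10), bool)
    brain[5:, ...] = True  # candidates fully outside
    mask, table = correct_false_positives(
        cand, flair=np.full((10, 10, 10), 200.0), wm_flair_mean=100.0,
        probability=np.ones((10, 10, 10)), brain_mask=brain,
        csf_prior=np.zeros((10, 10, 10)), supratentorial=brain,
    )
    assert mask.values.sum() == 0
    assert (table["removed_by"] == "outside_brain").all()


def test_fp_rule_csf_removed():
    cand = _toy_candidates([(2, 2, 2)])
    ones = np.ones((10, 10, 10))
    brain = np.ones((10, 10, 10), bool)
    mask, table = correct_false_positives(
        cand, flair=ones * 200, wm_flair_mean=100.0, probability=ones,
        brain_mask=brain, csf_prior=ones, supratentorial=brain,
    )
    assert mask.values.sum() == 0
    assert table["removed_by"].iloc[0] == "csf"


def test_fp_rule_hypointense_removed():
    cand = _toy_candidates([(2, 2, 2)])
    brain = np.ones((10, 10, 10), bool)
    mask, table = correct_false_positives(
        cand, flair=np.full((10, 10, 10), 90.0), wm_flair_mean=100.0,
        probability=np.ones((10, 10, 10)), brain_mask=brain,
        csf_prior=np.zeros((10, 10, 10)), supratentorial=brain,
    )
    assert mask.values.sum() == 0
    assert table["removed_by"].iloc[0] == "not_hyperintense"


def test_fp_missing_context_raises():
    cand = _toy_candidates([(2, 2, 2)])
    with pytest.raises(ValueError, match="brain_mask.*supratentorial"):
        correct_false_positives(
            cand, flair=np.zeros((10, 10, 10)), wm_flair_mean=1.0,
            probability=np.zeros((10, 10, 10)),
            csf_prior=np.zeros((10, 10, 10)),
        )


def test_planted_lesions_retained_end_to_end(segmented, small_phantom):
    """Deep white-matter lesions on a clean phantom survive the rules."""
    auto = segmented.binary_mask()
    truth = small_phantom.truth_lesions
    recall = (auto & truth).sum() / truth.sum()
    assert recall > 0.9


def test_integrate_volume_arithmetic():
    vals = np.zeros((10, 10, 10))
    vals.ravel()[:100] = 1.0
    assert integrate_volume(LesionMask(vals, (1, 1, 5))) == pytest.approx(0.5)
    two = np.zeros((4, 4, 4))
    two.ravel()[:2] = 0.5
    assert integrate_volume(LesionMask(two, (1, 1, 1))) == pytest.approx(0.001)
    assert integrate_volume(LesionMask(np.zeros((3, 3, 3)), (1, 1, 1))) == 0.0
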