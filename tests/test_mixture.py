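"""Mixture model: moments initialization, EM, bias field, outlier map,
split-and-merge model selection."""

import numpy as np
import pytest

from wmhkit.mixture import (
    GaussianComponent,
    GaussianTissueMixture,
    TissueModel,
    estimate_bias_field,
    fit_em,
    init_model,
    initial_outlier_map,
    split_merge_search,
)
from wmhkit.utils import polynomial_basis


def _four_class_data(rng, n=10_000, sd=10.0):
    """Two-modality, four-class Gaussian data with 5-sigma separation."""
    means = np.array(
        [[100.0, 100.0], [200.0, 100.0], [100.0, 200.0], [200.0, 200.0]]
    )
    assert np.all(
        [np.linalg.norm(a - b) >= 5 * sd for i, a in enumerate(means)
         for b in means[i + 1:]]
    )
    X = np.vstack([m + sd * rng.standard_normal((n, 2)) for m in means])
    priors = np.zeros((4 * n, 4))
    for j in range(4):
        priors[j * n: (j + 1) * n, j] = 0.85
    priors += 0.15 / 4
    priors /= priors.sum(axis=1, keepdims=True)
    return X, priors, means, sd


def test_init_model_onehot_means_exact():
    # constant data per class with one-hot priors: weighted moments are exact
    X = np.array([[10.0, 1.0]] * 5 + [[20.0, 2.0]] * 5)
    priors = np.zeros((10, 2))
    priors[:5, 0] = 1
    priors[5:, 1] = 1
    model = init_model(X, priors, classes=["a", "b"])
    a = model.class_components("a", "inlier")[0]
    b = model.class_components("b", "inlier")[0]
    assert np.allclose(a.mean, [10.0, 1.0])
    assert np.allclose(b.mean, [20.0, 2.0])


def test_init_model_uniform_priors_give_global_mean(rng):
    X = rng.normal(50.0, 5.0, size=(500, 1))
    priors = np.full((500, 2), 0.5)
    model = init_model(X, priors, classes=[0, 1])
    for c in (0, 1):
        assert np.allclose(
            model.class_components(c, "inlier")[0].mean, X.mean(axis=0)
        )


def test_init_model_zero_mass_class_raises():
    X = np.ones((10, 1))
    priors = np.column_stack([np.ones(10), np.zeros(10)])
    with pytest.raises(ValueError, match="csf"):
        init_model(X, priors, classes=["wm", "csf"])


def test_init_model_smoothed_atlas_recovers_class_mean(small_phantom):
    from wmhkit.phantom import WM, make_pseudo_atlas

    ph = small_phantom
    atlas = make_pseudo_atlas(ph.tissue_labels, 2.0, ph.voxel_mm)
    classes = sorted(atlas)
    mask = ph.head_mask
    X = ph.images.stack(mask)
    priors = np.column_stack([atlas[c][mask] for c in classes])
    model = init_model(X, priors, classes=classes)
    wm_sample = X[ph.tissue_labels[mask] == WM]
    est = model.class_components(WM, "inlier")[0].mean
    # atlas-weighted moments blur across tissue boundaries, so the
    # initializer only needs to land in the right neighbourhood (EM
    # refinement is what recovers the means, tested separately)
    assert np.all(np.abs(est / wm_sample.mean(axis=0) - 1.0) < 0.10)


def test_fit_em_single_gaussian_closed_form(rng):
    X = rng.normal(10.0, 2.0, size=(2000, 1))
    comp = GaussianComponent(np.array([8.0]), np.array([[1.0]]), 1.0, 0, "inlier")
    model = TissueModel([comp], [0])
    res = fit_em(model, X, np.ones((2000, 1)), tol=1e-12, max_iter=200,
                 reg_scale=0.0)
    c = res.model.components[0]
    assert np.allclose(c.mean, X.mean(axis=0), atol=1e-8)
    assert np.allclose(c.cov, np.atleast_2d(X.var()), atol=1e-6)  # biased form


def test_fit_em_infinite_tol_single_iteration(rng):
    X = rng.normal(size=(100, 2))
    priors = np.ones((100, 1))
    model = init_model(X, priors, classes=[0])
    res = fit_em(model, X, priors, tol=np.inf)
    assert res.n_iterations == 1


def test_fit_em_rejects_nonfinite(rng):
    X = rng.normal(size=(50, 2))
    X[3, 1] = np.nan
    priors = np.ones((50, 1))
    model = init_model(np.nan_to_num(X), priors, classes=[0])
    with pytest.raises(ValueError, match="finite"):
        fit_em(model, X, priors)


def test_em_recovers_generating_parameters(rng):
    X, priors, means, sd = _four_class_data(rng, n=5000)
    model = init_model(X, priors, classes=list(range(4)))
    res = fit_em(model, X, priors, tol=1e-7, max_iter=200)
    for j in range(4):
        est = res.model.class_components(j, "inlier")[0].mean
        assert np.all(np.abs(est - means[j]) / means[j] < 0.02)
    # log-likelihood trace monotone non-decreasing
    trace = np.array(res.ll_trace)
    assert np.all(np.diff(trace) >= -1e-8 * np.abs(trace[:-1]))


def test_responsibilities_normalized(rng):
    X, priors, *_ = _four_class_data(rng, n=500)
    model = init_model(X, priors, classes=list(range(4)))
    res = fit_em(model, X, priors, tol=1e-6)
    assert np.allclose(res.responsibilities.sum(axis=1), 1.0, atol=1e-6)


def test_component_permutation_invariance(rng):
    X, priors, *_ = _four_class_data(rng, n=400)
    model = init_model(X, priors, classes=list(range(4)))
    res = fit_em(model, X, priors, tol=1e-6, max_iter=5)
    shuffled = res.model.copy()
    shuffled.components = shuffled.components[::-1]
    from wmhkit.mixture import _e_step

    _, ll_a = _e_step(res.model, X, priors)
    _, ll_b = _e_step(shuffled, X, priors)
    assert np.isclose(ll_a, ll_b, rtol=1e-12)
    score_a = initial_outlier_map(res, X, priors)
    res_b = res
    res_b.model = shuffled
    score_b = initial_outlier_map(res_b, X, priors)
    assert np.allclose(score_a, score_b)


# --- bias field -----------------------------------------------------------


def _fitted_result(X, priors, classes):
    model = init_model(X, priors, classes=classes)
    return fit_em(model, X, priors, tol=1e-7, max_iter=100)


def test_bias_field_zero_on_unbiased_input():
    im = np.full((12, 12, 12), 100.0)
    mask = np.ones(im.shape, bool)
    X = im[mask][:, None]
    priors = np.ones((X.shape[0], 1))
    res = _fitted_result(X, priors, [0])
    bias = estimate_bias_field([im], res.responsibilities, res.model, mask, order=2)
    assert np.all(np.abs(bias.evaluate()[0]) < 1e-6)


def test_bias_field_recovers_planted_order2(rng):
    shape = (24, 24, 24)
    mask = np.ones(shape, bool)
    basis, powers = polynomial_basis(shape, mask, 2)
    coef = np.zeros(len(powers))
    coef[powers.index((2, 0, 0))] = 0.15
    coef[powers.index((0, 1, 1))] = -0.1
    log_field = (basis @ coef).reshape(shape)
    im = 150.0 * np.exp(log_field) * np.exp(rng.normal(0, 0.01, shape))
    X = im[mask][:, None]
    # single known component isolates the regression from mixture fitting
    comp = GaussianComponent(X.mean(0), np.atleast_2d(X.var()), 1.0, 0, "inlier")
    model = TissueModel([comp], [0])
    resp = np.ones((X.shape[0], 1))
    bias = estimate_bias_field([im], resp, model, mask, order=2)
    fitted = bias.evaluate()[0][mask]
    r = np.corrcoef(fitted, log_field[mask])[0, 1]
    assert r > 0.95
    # correction flattens the image down to the noise floor
    corrected = bias.correct([im])[0]
    assert corrected[mask].std() < im[mask].std() * 0.3


def test_bias_field_order_zero_is_mean_residual(rng):
    im = np.exp(rng.normal(5.0, 0.1, size=(8, 8, 8)))
    mask = np.ones(im.shape, bool)
    X = im[mask][:, None]
    priors = np.ones((X.shape[0], 1))
    res = _fitted_result(X, priors, [0])
    bias = estimate_bias_field([im], res.responsibilities, res.model, mask, order=0)
    mu = res.model.components[0].mean  # inlier and outlier share the class
    log_means = np.log(np.array([np.clip(c.mean, 1e-12, None)
                                 for c in res.model.components]))[:, 0]
    expected = np.mean(np.log(im[mask]) - res.responsibilities @ log_means)
    assert np.allclose(bias.evaluate()[0][mask], expected, atol=1e-10)


def test_bias_field_too_few_voxels_raises():
    im = np.full((2, 2, 1), 10.0)
    mask = np.ones(im.shape, bool)
    resp = np.ones((4, 1))
    comp = GaussianComponent(np.array([10.0]), np.array([[1.0]]), 1.0, 0)
    model = TissueModel([comp], [0])
    with pytest.raises(ValueError, match="basis"):
        estimate_bias_field([im], resp, model, mask, order=3)


# --- initial outlier map --------------------------------------------------


def test_outlier_map_closed_form():
    comp = GaussianComponent(np.array([100.0]), np.array([[25.0]]), 1.0, 0)
    model = TissueModel([comp], [0])
    X = np.array([[100.0], [110.0]])
    priors = np.ones((2, 1))
    res = fit_em(model, X, priors, tol=np.inf)  # single E-step, no fitting
    # rebuild with the original parameters to test the map in isolation
    res.model = TissueModel(
        [GaussianComponent(np.array([100.0]), np.array([[25.0]]), 1.0, 0)], [0]
    )
    scores = initial_outlier_map(res, X, priors)
    assert scores[0] == pytest.approx(0.0)
    assert scores[1] == pytest.approx(4.0)  # (10^2)/25


def test_outlier_map_matches_bruteforce(rng):
    X, priors, *_ = _four_class_data(rng, n=300)
    model = init_model(X, priors, classes=list(range(4)))
    res = fit_em(model, X, priors, tol=1e-6)
    scores = initial_outlier_map(res, X, priors)
    top = priors.argmax(axis=1)
    for i in rng.choice(len(X), 50, replace=False):
        c = res.model.classes[top[i]]
        best = min(
            (X[i] - k.mean) @ np.linalg.inv(k.cov) @ (X[i] - k.mean)
            for k in res.model.class_components(c, "inlier")
        )
        assert scores[i] == pytest.approx(best, rel=1e-8)


# --- split and merge ------------------------------------------------------


@pytest.mark.parametrize("seed", range(10))
def test_split_merge_keeps_single_gaussian_single(seed):
    rng = np.random.default_rng(seed)
    X = rng.normal(100.0, 10.0, size=(3000, 2))
    priors = np.ones((3000, 1))
    comp = GaussianComponent(X.mean(0), np.cov(X.T), 1.0, 0, "inlier")
    model = TissueModel([comp], [0])
    res = fit_em(model, X, priors, tol=1e-6)
    out = split_merge_search(res, X, priors, max_components_per_class=3)
    assert len(out.model.class_components(0, "inlier")) == 1


def test_split_merge_finds_two_component_class(rng):
    # well-separated equal-weight pair: 5 sigma apart
    X = np.vstack([
        rng.normal(100.0, 10.0, size=(3000, 2)),
        rng.normal(160.0, 10.0, size=(3000, 2)),
    ])
    priors = np.ones((6000, 1))
    comp = GaussianComponent(X.mean(0), np.cov(X.T), 1.0, 0, "inlier")
    model = TissueModel([comp], [0])
    res = fit_em(model, X, priors, tol=1e-6)
    out = split_merge_search(res, X, priors, max_components_per_class=3)
    assert len(out.model.class_components(0, "inlier")) == 2
    assert out.criterion < res.criterion


def test_split_merge_cap_one_is_identity(rng):
    X = rng.normal(size=(200, 2)) * 5 + 50
    priors = np.ones((200, 1))
    model = init_model(X, priors, classes=[0])
    res = fit_em(model, X, priors, tol=1e-6)
    out = split_merge_search(res, X, priors, max_components_per_class=1)
    assert out is res


# --- estimator surface ----------------------------------------------------


def test_estimator_fit_recovery_and_sklearn_protocol(rng):
    from sklearn.base import clone

    X, priors, means, _ = _four_class_data(rng, n=2000)
    est = GaussianTissueMixture(max_components_per_class=1)
    assert clone(est).get_params() == est.get_params()
    est.fit(X, priors)
    assert hasattr(est, "model_") and hasattr(est, "log_likelihood_")
    for j in range(4):
        got = est.model_.class_components(j, "inlier")[0].mean
        assert np.all(np.abs(got - means[j]) / means[j] < 0.02)
    pred = est.predict(X, priors)
    acc = (pred == np.repeat(np.arange(4), 2000)).mean()
    assert acc > 0.95
    assert np.allclose(est.predict_proba(X, priors).sum(axis=1), 1.0, atol=1e-6)
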