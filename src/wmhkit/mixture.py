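"""Inlier/outlier Gaussian mixture over tissue classes with atlas priors.

Each anatomical class (grey matter, white matter, CSF, non-brain) is a
mixture of multivariate Gaussians over the modalities (T1, FLAIR): one or
more *inlier* components describing expected intensities, plus one broad
*outlier* component per class capturing unexpected observations such as
lesions. Spatial tissue priors (an atlas) weight the class memberships per
voxel, the number of inlier components per class is chosen by a
split-and-merge search scored with BIC, and a low-order polynomial bias
field is estimated on log-intensities (a multiplicative scanner field is
additive in the log domain).

The voxel-level machinery is exposed both as functions (``init_model``,
``fit_em``, ``estimate_bias_field``, ``initial_outlier_map``,
``split_merge_search``) and as the scikit-learn style estimator
:class:`GaussianTissueMixture` operating on an ``(n_voxels, n_modalities)``
design matrix plus an ``(n_voxels, n_classes)`` prior matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats
from scipy.special import logsumexp
from sklearn.base import BaseEstimator

from .utils import polynomial_basis

__all__ = [
    "GaussianComponent",
    "TissueModel",
    "BiasField",
    "ModelFitResult",
    "GaussianTissueMixture",
    "init_model",
    "fit_em",
    "estimate_bias_field",
    "initial_outlier_map",
    "split_merge_search",
]

_TINY = 1e-300


@dataclass(eq=False)
class GaussianComponent:
    """One Gaussian of a tissue class: inlier or outlier part."""

    mean: np.ndarray
    cov: np.ndarray
    weight: float  # within-class weight
    tissue_class: int
    part: str = "inlier"  # "inlier" | "outlier"

    def __post_init__(self):
        self.mean = np.atleast_1d(np.asarray(self.mean, dtype=float))
        self.cov = np.atleast_2d(np.asarray(self.cov, dtype=float))
        if self.part not in ("inlier", "outlier"):
            raise ValueError(f"part must be inlier/outlier, got {self.part!r}")
        if not self.weight > 0:
            raise ValueError("component weight must be positive")


@dataclass
class TissueModel:
    """Full mixture: components grouped by tissue class."""

    components: list
    classes: list
    outlier_fraction: float = 0.01

    def class_components(self, tissue_class, part=None):
        return [
            c
            for c in self.components
            if c.tissue_class == tissue_class and (part is None or c.part == part)
        ]

    def check(self):
        for c in self.classes:
            comps = self.class_components(c)
            if not self.class_components(c, "inlier"):
                raise ValueError(f"class {c} has no inlier component")
            total = sum(k.weight for k in comps)
            if abs(total - 1.0) > 1e-8:
                raise ValueError(f"class {c} weights sum to {total}, not 1")
        return self

    def copy(self):
        return TissueModel(
            components=[
                replace(c, mean=c.mean.copy(), cov=c.cov.copy())
                for c in self.components
            ],
            classes=list(self.classes),
            outlier_fraction=self.outlier_fraction,
        )


@dataclass
class BiasField:
    """Per-modality polynomial field on log-intensities over a mask."""

    order: int
    coefficients: np.ndarray  # (n_modalities, n_terms)
    powers: list
    shape: tuple
    mask: np.ndarray

    def evaluate(self):
        """Fields as 3-D arrays (zero outside the mask)."""
        basis, _ = polynomial_basis(self.shape, self.mask, self.order)
        out = []
        for coef in self.coefficients:
            vol = np.zeros(self.shape)
            vol[self.mask] = basis @ coef
            out.append(vol)
        return out

    def correct(self, images):
        """Divide images by exp(field): removes the multiplicative bias."""
        fields = self.evaluate()
        return [np.asarray(im, float) / np.exp(f) for im, f in zip(images, fields)]


@dataclass
class ModelFitResult:
    model: TissueModel
    responsibilities: np.ndarray  # (n_voxels, n_components)
    log_likelihood: float
    criterion: float
    n_iterations: int
    ll_trace: list = field(default_factory=list)
    bias: BiasField | None = None


def _regularize(cov, scale=1e-6):
    d = cov.shape[0]
    eps = scale * max(np.trace(cov), 1e-30) / d
    cov = cov + eps * np.eye(d)
    w = np.linalg.eigvalsh(cov)
    if w.min() <= 1e-10:
        warnings.warn("singular covariance regularized", RuntimeWarning)
        cov = cov + (1e-10 - w.min() + eps) * np.eye(d)
    return cov


def _log_gaussian(X, mean, cov):
    d = X.shape[1]
    L = np.linalg.cholesky(cov)
    diff = X - mean
    sol = np.linalg.solve(L, diff.T)
    maha = np.einsum("ij,ij->j", sol, sol)
    logdet = 2.0 * np.log(np.diag(L)).sum()
    return -0.5 * (maha + logdet + d * np.log(2.0 * np.pi))


def _class_index(model):
    return {c: j for j, c in enumerate(model.classes)}


def _log_prior_matrix(model, priors):
    """(n, K) log of atlas-class prior x within-class weight."""
    cidx = _class_index(model)
    logp = np.log(np.clip(priors, _TINY, None))
    cols = [
        logp[:, cidx[c.tissue_class]] + np.log(c.weight) for c in model.components
    ]
    return np.column_stack(cols)


def _e_step(model, X, priors):
    logw = _log_prior_matrix(model, priors)
    logd = np.column_stack(
        [_log_gaussian(X, c.mean, c.cov) for c in model.components]
    )
    lognum = logw + logd
    norm = logsumexp(lognum, axis=1)
    resp = np.exp(lognum - norm[:, None])
    return resp, float(norm.sum())


def _m_step(model, X, priors, resp, reg_scale=1e-6, update_parts=("inlier", "outlier")):
    nk = resp.sum(axis=0)
    class_tot = {}
    for c, n in zip(model.components, nk):
        class_tot[c.tissue_class] = class_tot.get(c.tissue_class, 0.0) + n
    for j, comp in enumerate(model.components):
        if comp.part not in update_parts:
            continue
        n = nk[j]
        if n < 1e-8:
            comp.weight = max(1e-8, n / max(class_tot[comp.tissue_class], 1e-30))
            continue
        r = resp[:, j]
        mean = r @ X / n
        diff = X - mean
        cov = (r[:, None] * diff).T @ diff / n
        comp.mean = mean
        comp.cov = _regularize(cov, reg_scale)
    # within-class weights renormalize over *all* parts so they stay a simplex
    for j, comp in enumerate(model.components):
        tot = class_tot[comp.tissue_class]
        comp.weight = max(nk[j] / max(tot, 1e-30), 1e-10)
    for c in model.classes:
        comps = model.class_components(c)
        s = sum(k.weight for k in comps)
        for k in comps:
            k.weight /= s


def _n_parameters(model):
    d = model.components[0].mean.size
    p = 0
    for c in model.classes:
        comps = model.class_components(c)
        p += len(comps) - 1  # within-class weights
        p += len(comps) * (d + d * (d + 1) // 2)
    return p


def _bic(ll, model, n):
    return -2.0 * ll + _n_parameters(model) * np.log(max(n, 2))


def init_model(
    X,
    priors,
    classes=None,
    outlier_fraction=0.01,
    kappa_outlier=10.0,
    reg_scale=1e-6,
) -> TissueModel:
    """One inlier Gaussian per class from atlas-weighted sample moments,
    plus one broad outlier Gaussian per class (covariance scaled by
    ``kappa_outlier``) at small initial weight.
    """
    X = np.asarray(X, dtype=float)
    priors = np.asarray(priors, dtype=float)
    if classes is None:
        classes = list(range(priors.shape[1]))
    comps = []
    for j, c in enumerate(classes):
        w = priors[:, j]
        mass = w.sum()
        if mass <= 0:
            raise ValueError(f"tissue class {c!r} has zero total atlas mass")
        mean = w @ X / mass
        diff = X - mean
        cov = (w[:, None] * diff).T @ diff / mass
        cov = _regularize(cov, reg_scale)
        comps.append(
            GaussianComponent(mean, cov, 1.0 - outlier_fraction, c, "inlier")
        )
        comps.append(
            GaussianComponent(
                mean.copy(), kappa_outlier * cov, outlier_fraction, c, "outlier"
            )
        )
    return TissueModel(comps, list(classes), outlier_fraction).check()


def fit_em(
    model,
    X,
    priors,
    tol=1e-5,
    max_iter=100,
    reg_scale=1e-6,
) -> ModelFitResult:
    """Expectation-maximisation at fixed component structure.

    Stops when the relative log-likelihood change drops below ``tol`` or
    after ``max_iter`` sweeps; the log-likelihood trace is monotone
    non-decreasing up to numerical tolerance.
    """
    if not tol > 0:
        raise ValueError("tol must be positive")
    X = np.asarray(X, dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite intensities in input")
    model = model.copy()
    trace = []
    ll_prev = None
    n_iter = 0
    resp = None
    for it in range(1, max_iter + 1):
        resp, ll = _e_step(model, X, priors)
        if ll_prev is not None and abs(ll - ll_prev) <= tol * abs(ll_prev):
            ll_prev = ll
            trace.append(ll)
            break
        trace.append(ll)
        _m_step(model, X, priors, resp, reg_scale)
        ll_prev = ll
        n_iter = it
    else:
        # budget exhausted: refresh responsibilities for the final params
        resp, ll_prev = _e_step(model, X, priors)
        trace.append(ll_prev)
    crit = _bic(ll_prev, model, X.shape[0])
    return ModelFitResult(model, resp, ll_prev, crit, n_iter, trace)


def estimate_bias_field(
    images, responsibilities, model, mask, order=3
) -> BiasField:
    """Weighted least-squares polynomial fit to per-voxel log-residuals.

    The residual at a voxel is its log-intensity minus the
    responsibility-weighted log class mean; a multiplicative scanner field
    appears there additively. One coefficient vector is fit per modality.
    """
    if order < 0:
        raise ValueError("order must be >= 0")
    images = [np.asarray(im, float) for im in images]
    shape = images[0].shape
    mask = np.asarray(mask, bool)
    n = int(mask.sum())
    basis, powers = polynomial_basis(shape, mask, order)
    if n < basis.shape[1]:
        raise ValueError(
            f"{n} voxels cannot support {basis.shape[1]} basis functions"
        )
    resp = np.asarray(responsibilities, float)
    log_means = np.log(
        np.clip(np.array([c.mean for c in model.components]), 1e-12, None)
    )  # (K, d)
    expected = resp @ log_means  # (n, d)
    coefs = []
    for m, im in enumerate(images):
        y = np.log(np.clip(im[mask], 1e-12, None))
        residual = y - expected[:, m]
        coef, *_ = np.linalg.lstsq(basis, residual, rcond=None)
        coefs.append(coef)
    return BiasField(order, np.array(coefs), powers, shape, mask)


def initial_outlier_map(fit: ModelFitResult, X, priors) -> np.ndarray:
    """Outlier score after the initial one-component-per-class fit.

    score(voxel) = smallest squared Mahalanobis distance to the inlier
    components of the voxel's maximum-prior class. Re-used to seed the
    per-class outlier weights before the refined fit.
    """
    X = np.asarray(X, float)
    model = fit.model
    cidx = _class_index(model)
    top = np.argmax(priors, axis=1)
    scores = np.zeros(X.shape[0])
    for c in model.classes:
        sel = top == cidx[c]
        if not sel.any():
            continue
        d2 = np.column_stack(
            [_mahalanobis_sq(X[sel], k.mean, k.cov)
             for k in model.class_components(c, "inlier")]
        )
        scores[sel] = d2.min(axis=1)
    return scores


def _mahalanobis_sq(X, mean, cov):
    L = np.linalg.cholesky(cov)
    sol = np.linalg.solve(L, (X - mean).T)
    return np.einsum("ij,ij->j", sol, sol)


def reweight_outliers_from_map(model, scores, priors, quantile=0.95):
    """Set per-class outlier weights to the atlas-weighted fraction of
    voxels whose outlier score exceeds the chi-square ``quantile``."""
    model = model.copy()
    d = model.components[0].mean.size
    cut = stats.chi2.ppf(quantile, df=d)
    flagged = scores > cut
    cidx = _class_index(model)
    for c in model.classes:
        w = priors[:, cidx[c]]
        mass = max(w.sum(), 1e-30)
        frac = float(np.clip((w * flagged).sum() / mass, 1e-3, 0.5))
        inliers = model.class_components(c, "inlier")
        outliers = model.class_components(c, "outlier")
        if not outliers:
            continue
        tot_in = sum(k.weight for k in inliers)
        for k in outliers:
            k.weight = frac / len(outliers)
        for k in inliers:
            k.weight *= (1.0 - frac) / tot_in
    return model.check()


def _component_nongaussianity(X, resp_col):
    """Weighted |skewness| + |excess kurtosis| along the principal axis."""
    n = resp_col.sum()
    if n < 10:
        return 0.0
    mean = resp_col @ X / n
    diff = X - mean
    cov = (resp_col[:, None] * diff).T @ diff / n
    w, v = np.linalg.eigh(cov)
    proj = diff @ v[:, -1]
    sd = max(np.sqrt(w[-1]), 1e-12)
    z = proj / sd
    skew = (resp_col @ z**3) / n
    kurt = (resp_col @ z**4) / n - 3.0
    return abs(skew) + abs(kurt)


def _symmetric_kl(a: GaussianComponent, b: GaussianComponent):
    d = a.mean.size

    def kl(p, q):
        iq = np.linalg.inv(q.cov)
        diff = q.mean - p.mean
        return 0.5 * (
            np.trace(iq @ p.cov)
            + diff @ iq @ diff
            - d
            + np.log(np.linalg.det(q.cov) / np.linalg.det(p.cov))
        )

    return kl(a, b) + kl(b, a)


def _split_component(model, comp_index):
    model = model.copy()
    comp = model.components[comp_index]
    w, v = np.linalg.eigh(comp.cov)
    axis = v[:, -1] * np.sqrt(w[-1])
    left = replace(
        comp, mean=comp.mean - 0.5 * axis, cov=comp.cov.copy(),
        weight=comp.weight / 2
    )
    right = replace(
        comp, mean=comp.mean + 0.5 * axis, cov=comp.cov.copy(),
        weight=comp.weight / 2
    )
    model.components[comp_index] = left
    model.components.insert(comp_index + 1, right)
    return model


def _merge_components(model, i, j):
    model = model.copy()
    a, b = model.components[i], model.components[j]
    w = a.weight + b.weight
    mean = (a.weight * a.mean + b.weight * b.mean) / w
    cov = (
        a.weight * (a.cov + np.outer(a.mean - mean, a.mean - mean))
        + b.weight * (b.cov + np.outer(b.mean - mean, b.mean - mean))
    ) / w
    merged = replace(a, mean=mean, cov=cov, weight=w)
    model.components[i] = merged
    del model.components[j]
    return model


def split_merge_search(
    fit: ModelFitResult,
    X,
    priors,
    max_components_per_class=2,
    tol=1e-5,
    max_iter=40,
    reg_scale=1e-6,
) -> ModelFitResult:
    """Greedy split-and-merge over inlier components, scored by BIC.

    Each round proposes (a) splitting the inlier component with the worst
    within-component Gaussianity among classes below the cap and (b) merging
    the most similar inlier pair (symmetric KL) within a class; each
    proposal is refit by a short EM and kept only if BIC improves. Stops
    when neither proposal helps.
    """
    if max_components_per_class < 1:
        raise ValueError("max_components_per_class must be >= 1")
    X = np.asarray(X, float)
    best = fit
    if max_components_per_class == 1:
        return best
    for _round in range(8):
        model = best.model
        resp, _ = _e_step(model, X, priors)
        proposals = []

        # split proposal: worst-Gaussianity inlier component with headroom
        cand = [
            (j, c)
            for j, c in enumerate(model.components)
            if c.part == "inlier"
            and len(model.class_components(c.tissue_class, "inlier"))
            < max_components_per_class
        ]
        if cand:
            scores = [
                _component_nongaussianity(X, resp[:, j]) for j, _ in cand
            ]
            j_split = cand[int(np.argmax(scores))][0]
            proposals.append(_split_component(model, j_split))

        # merge proposal: most similar same-class inlier pair
        pairs = []
        for c in model.classes:
            idx = [
                j for j, k in enumerate(model.components)
                if k.tissue_class == c and k.part == "inlier"
            ]
            for a in range(len(idx)):
                for b in range(a + 1, len(idx)):
                    pairs.append((idx[a], idx[b]))
        if pairs:
            kls = [
                _symmetric_kl(model.components[i], model.components[j])
                for i, j in pairs
            ]
            i, j = pairs[int(np.argmin(kls))]
            if len(model.components) > len(model.classes):
                proposals.append(_merge_components(model, i, j))

        improved = False
        for prop in proposals:
            refit = fit_em(prop, X, priors, tol=tol, max_iter=max_iter,
                           reg_scale=reg_scale)
            if refit.criterion < best.criterion - 1e-9:
                best = refit
                improved = True
                break
        if not improved:
            break
    return best


class GaussianTissueMixture(BaseEstimator):
    """Atlas-guided inlier/outlier Gaussian mixture, scikit-learn style.

    Parameters
    ----------
    tol : float
        Relative log-likelihood convergence tolerance.
    max_iter : int
        EM iteration cap per structure.
    kappa_outlier : float
        Outlier covariance inflation over the class inlier covariance.
    outlier_fraction : float
        Initial within-class outlier weight.
    max_components_per_class : int
        Cap for the split-and-merge search (1 disables the search).
    outlier_quantile : float
        Chi-square quantile turning the initial outlier map into per-class
        outlier weights.
    reg_covar_scale : float
        Covariance ridge, as a fraction of trace/dim.

    Attributes
    ----------
    model_ : TissueModel
    responsibilities_ : ndarray (n_voxels, n_components)
    log_likelihood_ : float
    criterion_ : float (BIC; lower is better)
    n_iter_ : int
    initial_outlier_scores_ : ndarray
    """

    def __init__(
        self,
        tol=1e-5,
        max_iter=100,
        kappa_outlier=10.0,
        outlier_fraction=0.01,
        max_components_per_class=2,
        outlier_quantile=0.95,
        reg_covar_scale=1e-6,
    ):
        self.tol = tol
        self.max_iter = max_iter
        self.kappa_outlier = kappa_outlier
        self.outlier_fraction = outlier_fraction
        self.max_components_per_class = max_components_per_class
        self.outlier_quantile = outlier_quantile
        self.reg_covar_scale = reg_covar_scale

    def fit(self, X, priors, classes=None):
        """Fit on intensities ``X`` (n_voxels, n_modalities) with per-voxel
        class ``priors`` (n_voxels, n_classes)."""
        X = np.asarray(X, float)
        priors = np.asarray(priors, float)
        if X.ndim != 2 or priors.ndim != 2 or X.shape[0] != priors.shape[0]:
            raise ValueError("X and priors must be 2-D with matching rows")
        model = init_model(
            X, priors, classes=classes,
            outlier_fraction=self.outlier_fraction,
            kappa_outlier=self.kappa_outlier,
            reg_scale=self.reg_covar_scale,
        )
        initial = fit_em(model, X, priors, tol=self.tol,
                         max_iter=self.max_iter, reg_scale=self.reg_covar_scale)
        scores = initial_outlier_map(initial, X, priors)
        seeded = reweight_outliers_from_map(
            initial.model, scores, priors, quantile=self.outlier_quantile
        )
        refit = fit_em(seeded, X, priors, tol=self.tol,
                       max_iter=self.max_iter, reg_scale=self.reg_covar_scale)
        final = split_merge_search(
            refit, X, priors,
            max_components_per_class=self.max_components_per_class,
            tol=self.tol, reg_scale=self.reg_covar_scale,
        )
        self.classes_ = list(final.model.classes)
        self.model_ = final.model
        self.responsibilities_ = final.responsibilities
        self.log_likelihood_ = final.log_likelihood
        self.criterion_ = final.criterion
        self.n_iter_ = initial.n_iterations + final.n_iterations
        self.initial_outlier_scores_ = scores
        self.fit_result_ = final
        return self

    def predict_proba(self, X, priors):
        """Per-component responsibilities for new voxels."""
        resp, _ = _e_step(self.model_, np.asarray(X, float),
                          np.asarray(priors, float))
        return resp

    def predict(self, X, priors):
        """Maximum-posterior tissue class per voxel."""
        resp = self.predict_proba(X, priors)
        cidx = _class_index(self.model_)
        class_post = np.zeros((X.shape[0], len(self.model_.classes)))
        for j, c in enumerate(self.model_.components):
            class_post[:, cidx[c.tissue_class]] += resp[:, j]
        return np.asarray(self.model_.classes)[class_post.argmax(axis=1)]

    def score(self, X, priors):
        """Mean per-voxel log-likelihood."""
        _, ll = _e_step(self.model_, np.asarray(X, float),
                        np.asarray(priors, float))
        return ll / X.shape[0]
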