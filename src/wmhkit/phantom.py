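"""Seeded multimodal brain phantoms with ground-truth white-matter lesions.

The phantom is deliberately geometric rather than anatomical: nested
ellipsoids give a non-brain shell, a cortical grey-matter ribbon, a
white-matter interior, two ellipsoidal lateral ventricles and two deep
grey-matter nuclei. Analytic surfaces keep every downstream oracle exact
(ventricular surface, cortical sheet, lobar sectors) while still exercising
the whole segmentation pipeline: lesions are hyperintense on FLAIR and
hypointense on T1 relative to white matter, a smooth low-order multiplicative
bias field and additive Gaussian noise corrupt the images, and voxels may be
anisotropic.

Three lesion morphologies are planted, mirroring the clinical spectrum:
small punctate spheres deep in the white matter, confluent blobs from a
thresholded smooth random field, and periventricular caps hugging the
ventricular surface.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .utils import polynomial_basis
from .volumes import MultimodalVolume, voxel_volume_ml

__all__ = [
    "NONBRAIN",
    "CSF",
    "GM",
    "WM",
    "DEEP_GM",
    "LOBE_NAMES",
    "PhantomSpec",
    "PhantomOutput",
    "generate_phantom",
    "plant_lesions",
    "apply_bias_and_noise",
    "make_pseudo_atlas",
]

# tissue label codes
NONBRAIN, CSF, GM, WM, DEEP_GM = 0, 1, 2, 3, 4

#: 9 lobar regions: 4 lobes x 2 hemispheres + 1 subcortical
#: (basal ganglia + thalamus proxy). Infratentorial structures are not
#: modelled; the phantom is supratentorial by construction.
LOBE_NAMES = {
    1: "frontal-L",
    2: "frontal-R",
    3: "parietal-L",
    4: "parietal-R",
    5: "temporal-L",
    6: "temporal-R",
    7: "occipital-L",
    8: "occipital-R",
    9: "subcortical",
}

_DEFAULT_TISSUE_MEANS = {
    # (T1, FLAIR) intensities in arbitrary scanner units
    NONBRAIN: (120.0, 110.0),
    CSF: (150.0, 60.0),  # FLAIR suppresses CSF
    GM: (450.0, 380.0),
    WM: (620.0, 320.0),
    DEEP_GM: (460.0, 390.0),
}


@dataclass
class PhantomSpec:
    """Parameters of one synthetic acquisition.

    ``lesion_contrast`` is (T1 multiplier, FLAIR multiplier) applied to the
    white-matter means: FLAIR multiplier > 1 (hyperintense), T1 < 1
    (hypointense).
    """

    grid_shape: tuple = (64, 64, 64)
    voxel_mm: tuple = (1.0, 1.0, 1.0)
    target_lesion_ml: float = 4.0
    lesion_mix: dict = field(
        default_factory=lambda: {
            "punctate": 0.25,
            "confluent": 0.45,
            "periventricular": 0.30,
        }
    )
    tissue_means: dict = field(default_factory=lambda: dict(_DEFAULT_TISSUE_MEANS))
    lesion_contrast: tuple = (0.80, 1.60)
    bias_amplitude: float = 0.10
    noise_sd: float = 12.0
    seed: int = 0

    def validate(self):
        if len(self.grid_shape) != 3 or any(int(s) <= 0 for s in self.grid_shape):
            raise ValueError(f"grid_shape must be a positive triple: {self.grid_shape}")
        if len(self.voxel_mm) != 3 or any(v <= 0 for v in self.voxel_mm):
            raise ValueError(f"voxel_mm must be positive: {self.voxel_mm}")
        if self.target_lesion_ml < 0:
            raise ValueError("target_lesion_ml must be nonnegative")
        mix = {k: float(v) for k, v in self.lesion_mix.items()}
        unknown = set(mix) - {"punctate", "confluent", "periventricular"}
        if unknown:
            raise ValueError(f"unknown lesion morphologies: {sorted(unknown)}")
        if any(v < 0 for v in mix.values()):
            raise ValueError("lesion_mix proportions must be nonnegative")
        if self.target_lesion_ml > 0 and abs(sum(mix.values()) - 1.0) > 1e-8:
            raise ValueError("lesion_mix proportions must sum to 1")
        t1_mult, flair_mult = self.lesion_contrast
        if not flair_mult > 1.0:
            raise ValueError("FLAIR lesion contrast multiplier must exceed 1")
        if not t1_mult < 1.0:
            raise ValueError("T1 lesion contrast multiplier must be below 1")
        if self.bias_amplitude < 0 or self.noise_sd < 0:
            raise ValueError("bias_amplitude and noise_sd must be nonnegative")


@dataclass
class PhantomOutput:
    """A generated phantom: images, truth and geometry side-products."""

    t1: np.ndarray
    flair: np.ndarray
    truth_lesions: np.ndarray
    brain_mask: np.ndarray
    head_mask: np.ndarray
    tissue_labels: np.ndarray
    ventricle_surface: np.ndarray
    cortical_sheet: np.ndarray
    lobe_labels: np.ndarray
    voxel_mm: tuple
    noiseless_t1: np.ndarray
    noiseless_flair: np.ndarray
    spec: PhantomSpec

    @property
    def images(self) -> MultimodalVolume:
        return MultimodalVolume(self.t1, self.flair, self.voxel_mm)

    def truth_volume_ml(self) -> float:
        return float(self.truth_lesions.sum()) * voxel_volume_ml(self.voxel_mm)


def _ellipsoid(shape, voxel_mm, center_mm, radii_mm):
    """Boolean mask of an axis-aligned ellipsoid given in mm coordinates."""
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    acc = np.zeros(shape, dtype=float)
    for g, v, c, r in zip(grids, voxel_mm, center_mm, radii_mm):
        acc = acc + ((g * v - c) / r) ** 2
    return acc <= 1.0


def _build_geometry(spec: PhantomSpec):
    """Nested-ellipsoid anatomy. Returns the tissue label volume."""
    shape = tuple(int(s) for s in spec.grid_shape)
    vx = np.asarray(spec.voxel_mm, dtype=float)
    extent = np.asarray(shape) * vx
    center = extent / 2.0

    head_r = 0.46 * extent
    brain_r = 0.38 * extent
    gm_thickness = max(2.0 * float(vx.min()), 2.5)  # mm
    inner_r = brain_r - gm_thickness

    if np.any(inner_r < 8.0):
        raise ValueError(
            "grid too small to host ventricles and cortex: white-matter "
            f"interior radii {tuple(np.round(inner_r, 1))} mm must all be >= 8 mm; "
            "increase grid_shape or voxel_mm"
        )

    head = _ellipsoid(shape, vx, center, head_r)
    brain = _ellipsoid(shape, vx, center, brain_r)
    interior = _ellipsoid(shape, vx, center, inner_r)

    labels = np.full(shape, NONBRAIN, dtype=np.int16)
    labels[head] = NONBRAIN
    labels[brain & ~interior] = GM
    labels[interior] = WM

    # two lateral ventricles, offset left/right of the midline
    vent_r = np.maximum(0.055 * extent, 2.0 * vx)
    vent_r[1] = max(0.16 * extent[1], 3.0 * vx[1])  # elongated along y
    for side in (-1.0, 1.0):
        c = center + np.array([side * 0.10 * extent[0], 0.0, 0.02 * extent[2]])
        labels[_ellipsoid(shape, vx, c, vent_r)] = CSF

    # deep grey nuclei lateral to each ventricle
    nuc_r = np.maximum(0.05 * extent, 1.5 * vx)
    for side in (-1.0, 1.0):
        c = center + np.array([side * 0.21 * extent[0], 0.02 * extent[1], 0.0])
        nucleus = _ellipsoid(shape, vx, c, nuc_r)
        labels[nucleus & (labels == WM)] = DEEP_GM

    labels[~head] = NONBRAIN
    return labels, head, center, extent


def _lobe_labels(tissue_labels, voxel_mm, center_mm, extent_mm):
    """Rasterize 9 lobar regions: 8 angular sectors + subcortical core.

    Sectors split each hemisphere (left/right of the midline) into four
    quadrants of the sagittal (y, z) angle: frontal = anterior-superior,
    parietal = posterior-superior, occipital = posterior-inferior,
    temporal = anterior-inferior.
    """
    shape = tissue_labels.shape
    vx = np.asarray(voxel_mm, dtype=float)
    ii, jj, kk = np.meshgrid(
        np.arange(shape[0]) * vx[0] - center_mm[0],
        np.arange(shape[1]) * vx[1] - center_mm[1],
        np.arange(shape[2]) * vx[2] - center_mm[2],
        indexing="ij",
    )
    right = ii >= 0
    anterior = jj >= 0
    superior = kk >= 0

    lobes = np.zeros(shape, dtype=np.int16)
    lobes[anterior & superior] = 1  # frontal-L (left filled below)
    lobes[~anterior & superior] = 3  # parietal
    lobes[anterior & ~superior] = 5  # temporal
    lobes[~anterior & ~superior] = 7  # occipital
    lobes[right] += 1  # -R variants

    # subcortical: deep grey nuclei plus a central core around the ventricles
    core_r = 0.14 * extent_mm
    core = (ii / core_r[0]) ** 2 + (jj / core_r[1]) ** 2 + (kk / core_r[2]) ** 2 <= 1.0
    lobes[core | (tissue_labels == DEEP_GM)] = 9

    lobes[tissue_labels == NONBRAIN] = 0
    return lobes


def _six_connected_structure():
    return ndimage.generate_binary_structure(3, 1)


def plant_lesions(tissue_labels, spec: PhantomSpec, rng) -> np.ndarray:
    """Plant ground-truth lesions of the three morphologies into white matter.

    The total planted voxel count equals the voxel equivalent of
    ``spec.target_lesion_ml`` (rounded), apportioned by ``spec.lesion_mix``;
    any punctate shortfall (when eroded white matter cannot host another
    sphere) is absorbed by the confluent field, so the realized load tracks
    the target far inside the 15% tolerance.
    """
    vox_ml = voxel_volume_ml(spec.voxel_mm)
    n_target = int(round(spec.target_lesion_ml / vox_ml))
    wm = tissue_labels == WM
    if n_target == 0:
        return np.zeros_like(wm, dtype=bool)
    if n_target > 0.5 * wm.sum():
        raise ValueError(
            f"requested lesion load ({spec.target_lesion_ml} ml ~ {n_target} voxels) "
            f"exceeds half the available white matter ({int(wm.sum())} voxels)"
        )

    mix = {k: float(spec.lesion_mix.get(k, 0.0)) for k in
           ("periventricular", "punctate", "confluent")}
    quotas = {k: int(round(v * n_target)) for k, v in mix.items()}
    # rounding drift goes to the largest slice
    drift = n_target - sum(quotas.values())
    quotas[max(quotas, key=quotas.get)] += drift

    lesions = np.zeros_like(wm, dtype=bool)
    ventricles = tissue_labels == CSF
    struct6 = _six_connected_structure()

    # distance (voxels) from the ventricular system, used both for caps and
    # to keep punctate/confluent lesions away from the surface
    dist_vent = ndimage.distance_transform_edt(~ventricles, sampling=spec.voxel_mm)

    # --- periventricular caps: nearest-to-ventricle WM voxels -------------
    n_pv = quotas["periventricular"]
    if n_pv > 0:
        order = np.argsort(dist_vent[wm], kind="stable")
        idx = np.flatnonzero(wm.ravel())[order[:n_pv]]
        pv = np.zeros(wm.size, dtype=bool)
        pv[idx] = True
        lesions |= pv.reshape(wm.shape)

    # --- punctate spheres: radius 1-3 voxels in deep WM -------------------
    n_punct = quotas["punctate"]
    planted_punct = 0
    if n_punct > 0:
        struct26 = ndimage.generate_binary_structure(3, 3)
        grids = np.indices(wm.shape)
        # two passes: strict deep-WM placement first, then relaxed margins
        for min_dist, max_r in ((8.0, 3), (3.0, 2)):
            if planted_punct >= n_punct:
                break
            deep_wm = wm & (dist_vent > min_dist)
            centers_ok = ndimage.binary_erosion(deep_wm, struct6, iterations=max_r)
            candidates = np.argwhere(
                centers_ok & ~ndimage.binary_dilation(lesions, struct26, iterations=2)
            )
            rng.shuffle(candidates)
            for c in candidates:
                if planted_punct >= n_punct:
                    break
                r = int(rng.integers(1, max_r + 1))
                d2 = sum((g - ci) ** 2 for g, ci in zip(grids, c))
                sphere = (d2 <= r * r) & wm
                # 1-voxel margin keeps components separate at 26-connectivity
                if (ndimage.binary_dilation(sphere, struct26) & lesions).any():
                    continue
                room = n_punct - planted_punct
                if sphere.sum() > room:
                    # trim the sphere from the outside in
                    order = np.argsort(d2[sphere], kind="stable")
                    keep = np.argwhere(sphere)[order[:room]]
                    sphere = np.zeros_like(sphere)
                    sphere[tuple(keep.T)] = True
                lesions |= sphere
                planted_punct += int(sphere.sum())

    # punctate shortfall flows into the confluent field only when the mix
    # asks for confluent lesions at all (pure-punctate phantoms must keep
    # the per-component sphere-volume bound)
    shortfall = n_punct - planted_punct
    n_conf = quotas["confluent"] + (shortfall if mix["confluent"] > 0 else 0)
    if n_conf > 0:
        noise = rng.standard_normal(wm.shape)
        fld = ndimage.gaussian_filter(noise, sigma=3.0)
        allowed = wm & (dist_vent > 3.0) & ~ndimage.binary_dilation(lesions, struct6)
        if allowed.sum() < n_conf:
            allowed = wm & ~lesions
        vals = np.where(allowed, fld, -np.inf).ravel()
        idx = np.argpartition(vals, -n_conf)[-n_conf:]
        conf = np.zeros(wm.size, dtype=bool)
        conf[idx] = True
        lesions |= conf.reshape(wm.shape)

    return lesions


def apply_bias_and_noise(images, bias_amplitude, noise_sd, rng, mask=None):
    """Corrupt noiseless images with a smooth multiplicative bias field and
    additive zero-mean Gaussian noise.

    The bias field is a random polynomial of order <= 3, centred to mean 1
    over ``mask`` (the brain) and scaled so the field reaches at least
    1 +/- ``bias_amplitude`` on both sides. One independent field is drawn
    per modality, as scanners bias each acquisition separately.

    Parameters
    ----------
    images : sequence of ndarray
    bias_amplitude, noise_sd : float, >= 0
    rng : numpy Generator
    mask : ndarray of bool, optional
        Field normalization domain; defaults to the whole grid.

    Returns
    -------
    corrupted : list of ndarray
    fields : list of ndarray (the multiplicative bias fields)
    """
    if bias_amplitude < 0 or noise_sd < 0:
        raise ValueError("amplitudes must be nonnegative")
    images = [np.asarray(im, dtype=float) for im in images]
    shape = images[0].shape
    if mask is None:
        mask = np.ones(shape, dtype=bool)

    corrupted, fields = [], []
    full = np.ones(shape, dtype=bool)
    for im in images:
        fld = np.ones(shape)
        if bias_amplitude > 0:
            basis, powers = polynomial_basis(shape, full, order=3)
            coeff = rng.standard_normal(len(powers))
            coeff[powers.index((0, 0, 0))] = 0.0
            raw = (basis @ coeff).reshape(shape)
            raw = raw - raw[mask].mean()
            lo, hi = -raw[mask].min(), raw[mask].max()
            scale = min(lo, hi)
            if scale <= 1e-12:
                scale = max(lo, hi, 1e-12)
            fld = 1.0 + bias_amplitude * raw / scale
        out = im * fld
        if noise_sd > 0:
            out = out + rng.normal(0.0, noise_sd, size=shape)
        corrupted.append(out)
        fields.append(fld)
    return corrupted, fields


def make_pseudo_atlas(tissue_labels, smoothing_mm, voxel_mm=(1.0, 1.0, 1.0),
                      classes=None):
    """Smoothed one-hot label maps standing in for population tissue priors.

    Returns a dict class -> probability volume; per-voxel probabilities sum
    to 1. ``smoothing_mm = 0`` reproduces exact one-hot maps.
    """
    tissue_labels = np.asarray(tissue_labels)
    if classes is None:
        classes = sorted(int(c) for c in np.unique(tissue_labels))
    vx = np.asarray(voxel_mm, dtype=float)
    probs = {}
    for c in classes:
        onehot = (tissue_labels == c).astype(float)
        if smoothing_mm > 0:
            onehot = ndimage.gaussian_filter(onehot, sigma=smoothing_mm / vx)
        probs[c] = onehot
    total = sum(probs.values())
    total = np.where(total <= 0, 1.0, total)
    for c in classes:
        probs[c] = probs[c] / total
    return probs


def generate_phantom(spec: PhantomSpec) -> PhantomOutput:
    """Generate one phantom. Deterministic given ``spec`` (incl. seed)."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    tissue_labels, head, center, extent = _build_geometry(spec)
    lesions = plant_lesions(tissue_labels, spec, rng)

    t1 = np.zeros(spec.grid_shape, dtype=float)
    flair = np.zeros(spec.grid_shape, dtype=float)
    for c, (m_t1, m_flair) in spec.tissue_means.items():
        sel = tissue_labels == c
        t1[sel] = m_t1
        flair[sel] = m_flair
    wm_t1, wm_flair = spec.tissue_means[WM]
    t1_mult, flair_mult = spec.lesion_contrast
    t1[lesions] = wm_t1 * t1_mult
    flair[lesions] = wm_flair * flair_mult

    brain_mask = np.isin(tissue_labels, (CSF, GM, WM, DEEP_GM))
    struct6 = _six_connected_structure()
    domain = np.isin(tissue_labels, (WM, DEEP_GM))
    ventricles = tissue_labels == CSF
    ventricle_surface = ventricles & ndimage.binary_dilation(domain, struct6)
    cortical_sheet = (tissue_labels == GM) & ndimage.binary_dilation(domain, struct6)
    lobe_labels = _lobe_labels(tissue_labels, spec.voxel_mm, center, extent)

    (t1_obs, flair_obs), _fields = apply_bias_and_noise(
        (t1, flair), spec.bias_amplitude, spec.noise_sd, rng, mask=brain_mask
    )

    return PhantomOutput(
        t1=t1_obs,
        flair=flair_obs,
        truth_lesions=lesions,
        brain_mask=brain_mask,
        head_mask=head,
        tissue_labels=tissue_labels,
        ventricle_surface=ventricle_surface,
        cortical_sheet=cortical_sheet,
        lobe_labels=lobe_labels,
        voxel_mm=tuple(spec.voxel_mm),
        noiseless_t1=t1,
        noiseless_flair=flair,
        spec=replace(spec),
    )
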