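# Methods

## Segmentation model

The segmenter models the joint (T1, FLAIR) intensity of every voxel in the
head as an atlas-weighted mixture of multivariate Gaussians grouped into
four anatomical classes (grey matter, white matter, CSF, non-brain). Each
class holds one or more *inlier* components for expected intensities plus
one *outlier* component — the same mean but a covariance inflated by
κ = 10 and a small weight — that absorbs unexpected observations such as
lesions. The fit proceeds in stages:

1. **Initialization.** One inlier Gaussian per class from atlas-weighted
   sample moments; outlier weight 0.01.
2. **Initial EM** at this one-component structure, to convergence.
3. **Bias field.** Intensities are log-transformed so a multiplicative
   scanner field becomes additive; the per-voxel residual (log-intensity
   minus responsibility-weighted log class mean) is fit by least squares
   with a 3-D polynomial basis of order 3, one field per modality, and the
   images are divided by the exponentiated field. Order 0 degenerates to a
   global rescaling; fitting requires more voxels than basis functions.
4. **Outlier seeding.** An outlier score — the squared Mahalanobis distance
   to the inlier component(s) of each voxel's maximum-prior class — is
   computed from the converged initial model; per-class outlier weights are
   re-initialized to the atlas-weighted fraction of voxels whose score
   exceeds the χ² 0.95 quantile (clipped to [0.001, 0.5]). This makes the
   outlier part sensitive enough to claim lesion voxels early.
5. **Split-and-merge.** Greedy structure search over inlier components:
   each round proposes splitting the component with the worst
   within-component Gaussianity (weighted |skewness| + |excess kurtosis|
   along its principal axis, split ±0.5σ along that axis) and merging the
   most similar same-class pair (symmetric KL, moment-matched merge); a
   proposal is kept only if BIC improves after a short EM refit. BIC is
   computed on the fit-domain voxels; free parameters are the per-class
   weight simplices plus means and covariances. The default cap is 2
   components per class — ample for the phantom's unimodal classes while
   keeping the search cheap; raise it for real data with heavier
   intensity structure.

EM uses log-sum-exp responsibilities; covariances carry a ridge of
1e-6 × trace/dim (plus an escalation with a warning if still nearly
singular). Convergence: relative log-likelihood change < 1e-5, cap 100
iterations. The log-likelihood trace is monotone to 1e-8 by construction
of the M-step.

## Lesion extraction

Candidate voxels must (a) be better explained by the outlier part than the
inlier part (responsibility comparison) and (b) be hyperintense on FLAIR
relative to the white-matter inlier mean; their score is the squared
Mahalanobis distance to the nearest white-matter inlier component. The
primary threshold is T = χ²₀.₉₅ with dof = number of modalities
(5.99 for two) — an outlierness score is a squared distance, so a χ²
quantile is its natural scale. Both threshold comparisons are inclusive
(≥). A rescue pass adds connected components of the {score ≥ 2T/3} field
that are disjoint from every primary component and strictly smaller than
60 voxels, compensating partial-volume dilution of small lesions.
Components are labelled at 18-connectivity and re-partitioned at
6-connectivity; false-positive rules act on the 6-subcomponents (and can
consult the 18-parent): a subcomponent is dropped when more than half of
it lies outside the brain mask, its mean CSF prior exceeds 0.5 (choroid
plexus proxy), its mean FLAIR is not hyperintense, or it lies outside the
supratentorial mask. Survivors keep their outlier responsibility as a
probability; volumes integrate that map (voxel volume in mm³ / 1000).
For binary comparisons the probabilistic map is cut at 0.5.

## Semi-automated protocol and consensus

Thresholds are percentages of the median whole-brain FLAIR intensity:
130 % (high) / 120 % (low) for Siemens and Philips, raised to 145 % / 130 %
for GE (whose scans run hot posteriorly); maximum viewing intensities are
238 % and 340 % respectively. The protocol wording for inclusion is
"exceeds"; the default comparison is inclusive (≥) with a `strict_gt`
switch. Seed growing returns the connected component containing the seed
(default 3-D 6-connectivity; the original protocol's in-plane behaviour is
reachable by passing a 2-D slice). Manual edits are set union/difference
with removals taking precedence. Consensus over exactly four raters is
nested majority voting: each leave-one-out triplet votes 2-of-3 per voxel
and the overall consensus takes ≥ 3 of the 4 triplet votes. The ≥ 3 rule
resolves the 2–2 tie conservatively (negative); with it the nested scheme
is exactly equivalent to direct ≥ 3-of-4 voting (verified exhaustively),
and the permissive ≥ 2 variant is config-switchable.

## Agreement metrics

Dice uses the both-empty = 1 convention (avoids 0/0 and rewards trivial
agreement). The detection/outline decomposition calls two lesions "the
same" when their components share at least one voxel; component
connectivity defaults to 18 (matching the segmenter's first stage) and is
configurable to 6 or 26. ICC is the two-way random-effects,
absolute-agreement, single-measure form — the "agreement" flavour that
penalizes systematic offsets — with the standard F-based confidence
interval. Bland–Altman limits are mean ± 1.96 × sample SD (n−1) of paired
differences. Volume tests are paired t-tests on log₂ volumes (WMH loads
are right-skewed; a unit difference in log₂ is a doubling); degenerate
zero-variance cases return t = 0, p = 1 (identical inputs) or t = ±∞,
p = 0 (constant non-unit ratio).

## Bullseye parcellation

The domain is white matter + deep grey matter; the Laplace equation is
solved with Dirichlet values 0 on the ventricular surface and 1 on the
cortical sheet using the 7-point stencil with voxel-size-aware weights.
Faces not touching another node are insulating (zero-flux), and a
6-connectivity reachability check rejects domain voxels with no path to
either boundary. The linear system is solved exactly — direct sparse
factorization below 20k unknowns, Jacobi-preconditioned conjugate
gradients (rtol 1e-10) above — and the residual is checked against the
1e-5 tolerance; relaxation sweeps would solve the same system more slowly.
Layers bin φ into [0, ¼), [¼, ½), [½, ¾), [¾, 1]; crossing with 9 lobar
labels (frontal/parietal/temporal/occipital × L/R + subcortical) gives the
36 regions. Lobar labels are propagated onto white matter by nearest
labelled voxel (Euclidean distance transform), which is deterministic and
visit-order independent. Infratentorial structures are outside the domain
(the segmenter is supratentorial; the phantom models none). Region tables
normalize by total error or by true-positive volume; zero denominators are
flagged rather than divided.

**Accuracy of the solver.** Against closed forms, the slab solution is
exact to < 1e-4. For concentric spheres the voxelized walls are
stair-cased, which biases the effective boundary radius by a fraction of a
voxel and perturbs the 1/r profile most near the inner sphere; the
validation therefore runs at 0.25 mm resolution and compares from 2 mm
(inner) / 1 mm (outer) off the walls, where the discrete solution matches
(1/a − 1/r)/(1/a − 1/b) to better than 0.02. This near-boundary stand-off
is the standard treatment for irregular Dirichlet boundaries; layer
binning is insensitive to it because layers are quantiles of φ, not of r.

## Synthetic phantoms

The phantom is geometric, not anatomical: nested ellipsoids form a
non-brain shell, a cortical grey ribbon (≈ 2.5 mm), a white-matter
interior, two elongated lateral ventricles and two deep-grey nuclei, on an
arbitrary grid with arbitrary (possibly anisotropic) voxel sizes. Default
intensities (T1, FLAIR): CSF (150, 60), GM (450, 380), WM (620, 320),
deep GM (460, 390), non-brain (120, 110) — arbitrary scanner units chosen
so FLAIR suppresses CSF and T1 orders CSF < GM < WM. Lesions multiply the
WM means by 0.80 (T1) and 1.60 (FLAIR); the defaults give a strong
(≈ 16 σ at the default noise) contrast, and both multipliers are
config-exposed since quantitative lesion contrast is scanner- and
sequence-dependent. Three morphologies are planted to a target load:
periventricular caps (nearest-to-ventricle WM voxels by distance
transform), punctate spheres (radius 1–3 voxels in deep WM, kept disjoint
at 26-connectivity), and confluent blobs (top quantile of a σ = 3 voxel
Gaussian random field in WM); the default mix is 30/25/45 % and the
realized load matches the target voxel count by construction (well inside
the 15 % tolerance). Corruption is a random order-3 polynomial
multiplicative bias field, mean 1 over the brain and reaching at least
1 ± amplitude (default 0.10), drawn independently per modality, plus
additive Gaussian noise (default SD 12 — Gaussian rather than Rician
because the downstream model assumes Gaussian classes). Lobar labels are
rasterized as 8 angular sectors (sagittal-plane quadrants × hemisphere)
plus a subcortical core.

What the phantom does **not** emulate: real cortical folding, partial
volume at tissue interfaces, Rician noise, ghosting/motion artefacts,
infratentorial anatomy, or realistic lesion texture. Passing the phantom
suite therefore demonstrates correctness of the machinery (model fitting,
thresholding rules, metrics, parcellation) and strong-contrast recovery;
it does not certify performance on clinical data, where contrast is
weaker and boundaries are mixed. Problem sizes in the shipped checks —
64³ phantoms, 20 seeds, lesion loads 2–10 ml — were chosen as the smallest
configuration that exercises every morphology and keeps ≥ 30 ml of white
matter available for planting.

## Numerical and design choices

- All randomness flows from a single integer seed through
  `numpy.random.default_rng`; identical (config, seed) runs are
  byte-identical, and the pipeline manifest records a parameter hash.
- Voxel coordinates are 0-based indices; world geometry comes from the
  NIfTI affine; millilitre integrals always use the header voxel volume.
- Ties and boundaries: threshold comparisons inclusive (≥); "less than 60
  voxels" strict; layer bins half-open with the top bin closed; removals
  beat additions in manual edits.
- The mixture estimator (`GaussianTissueMixture`) and segmenter
  (`WMHSegmenter`) follow scikit-learn conventions (constructor
  parameters, `fit`, trailing-underscore fitted attributes,
  `get_params`/`set_params`), so they compose with sklearn tooling;
  domain inputs (atlas, masks) are passed to `fit` alongside the data.

## Known limitations

- The outlierness reference is the white-matter inlier component; if the
  split-and-merge search were allowed many components per class on data
  where lesions dominate a class, an inlier component could migrate onto
  lesions and depress sensitivity. The default cap (2) and the outlier
  seeding mitigate this on the phantom; real-data use should inspect the
  fitted component table.
- False-positive rules are deliberately simple proxies (CSF prior for
  choroid plexus, mask majorities for location); they do not encode the
  full clinical exclusion list.
- The semi-automated protocol's location judgements (corticospinal tract,
  septal regions) are human decisions and only representable through the
  manual-edit operation.
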