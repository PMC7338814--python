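# wmhkit

Segmentation and evaluation of **white-matter hyperintensities (WMH)** —
the bright lesions seen in white matter on FLAIR MRI (dark on T1) that are
a core imaging marker of cerebral small-vessel disease. The package is
aimed at neuroimaging researchers who need (a) an automated WMH segmenter,
(b) the semi-automated intensity-threshold protocol used to build
gold-standard reference segmentations, (c) rigorous agreement metrics
between segmentations and raters, and (d) a regional "bullseye" summary of
where lesions and errors sit. A seeded synthetic phantom generator makes
every stage testable end-to-end without patient data.

## The model

The automated segmenter is an **atlas-guided inlier/outlier Gaussian
mixture**. Each tissue class *c* ∈ {GM, WM, CSF, non-brain} is a mixture of
multivariate Gaussians over the modalities y = (T1, FLAIR):

p(yᵢ) = Σ_c aᵢc Σ_{k∈c} w_ck 𝒩(yᵢ; μ_ck, Σ_ck)

where aᵢc are spatial atlas priors and each class carries one broad
*outlier* component (covariance κ·Σ inflated, κ = 10) alongside its inlier
components, whose number is selected by a split-and-merge search scored
with BIC. A polynomial bias field (order ≤ 3) is estimated on
log-intensities after the initial one-component fit, where a multiplicative
scanner field is additive. Candidate lesion voxels are scored by their
**outlierness** — the squared Mahalanobis distance d²(yᵢ) to healthy
(inlier) white matter — thresholded at T = χ²₀.₉₅(2 dof), with a second
pass at 2T/3 rescuing small clusters (< 60 voxels) disjoint from the
primary detections. Connected components are classified at
18-neighbourhood then re-partitioned at 6-neighbourhood before rule-based
false-positive removal; WMH volume is the integral of the surviving
probabilistic map.

Evaluation follows the detection/outline error decomposition: components
shared between segmentation S and reference R (non-empty intersection)
contribute **outline errors** (OEFP = S∖R, OEFN = R∖S within the shared
lesion), unshared components are **detection errors** (DEFP, DEFN), so that
Dice = 2·TP / (2·TP + OEFP + OEFN + DEFP + DEFN) exactly. Volume agreement
uses ICC(2,1) (two-way random, absolute agreement), Bland–Altman limits of
agreement, and a paired t-test on log₂ volumes. The bullseye parcellation
solves the Laplace equation between the ventricular surface (φ = 0) and
cortical sheet (φ = 1), bins φ into 4 equidistant layers, and crosses them
with 9 lobar regions into 36 regions.

## Worked example

```python
from wmhkit import PipelineConfig, run_pipeline

cfg = PipelineConfig(seed=1, target_lesion_ml=4.0)
bundle = run_pipeline(cfg)
m = bundle["metrics"]
print(f"Dice vs planted truth : {m['dice']:.3f}")
print(f"Estimated WMH load    : {m['lesion_volume_ml']:.2f} ml")
print(f"Planted WMH load      : {m['truth_volume_ml']:.2f} ml")
```

prints

```
Dice vs planted truth : 0.994
Estimated WMH load    : 4.03 ml
Planted WMH load      : 4.00 ml
```

i.e. on a 64³ phantom with 4 ml of planted lesions (punctate, confluent
and periventricular morphologies, bias field and noise applied), the
automated mask overlaps the ground truth at Dice 0.994 and recovers the
lesion load to within 1%. The bundle also carries the error decomposition
(here TP = 4.000 ml, DEFP = 0.045 ml, OEFP = 0.003 ml, no false negatives)
and the 36-region bullseye table of error proportions.

The same stages are available from the shell:

```bash
wmhkit phantom --seed 1 --out ph/
wmhkit segment --t1 ph/t1.nii.gz --flair ph/flair.nii.gz \
               --labels ph/tissue_labels.nii.gz --out lesions.nii.gz
wmhkit evaluate --seg lesions.nii.gz --ref ph/truth.nii.gz --out metrics.json
wmhkit semiauto threshold --scanner GE --flair ph/flair.nii.gz \
               --brain-mask ph/brain_mask.nii.gz --out thr.nii.gz
wmhkit run --seed 1 --out run1/
```

## Layout

- `wmhkit.phantom` — seeded multimodal phantoms with ground-truth lesions
- `wmhkit.mixture` — `GaussianTissueMixture` (EM, bias field, split/merge)
- `wmhkit.lesions` — `WMHSegmenter`, outlierness, rescue, FP correction
- `wmhkit.semiauto` — median-intensity protocol, seed growing, consensus
- `wmhkit.evaluation` — Dice, DE/OE decomposition, ICC, Bland–Altman
- `wmhkit.bullseye` — Laplace layers × lobes, 36-region tables
- `wmhkit.pipeline` / `wmhkit.cli` — orchestration and the `wmhkit` CLI

See `docs/methods.md` for the modelling assumptions, parameter defaults
and known limitations.
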