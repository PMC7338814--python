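"""Agreement metrics between segmentations and between raters.

Spatial overlap is summarized by the Dice score and by a decomposition of
disagreement into detection error (entire lesion components present in only
one segmentation) and outline error (boundary disagreement within shared
lesions), each split into false positives and false negatives. Volume-level
agreement uses the two-way absolute-agreement intraclass correlation
(ICC(2,1)), Bland-Altman limits of agreement, and a paired t-test on
log2-transformed volumes (WMH loads are right-skewed; log2 makes the test
statistic a statement about volume ratios).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .utils import connectivity_structure
from .volumes import voxel_volume_ml

__all__ = [
    "ErrorDecomposition",
    "AgreementStats",
    "dice",
    "decompose_errors",
    "confusion_summary",
    "icc_agreement",
    "bland_altman",
    "paired_log2_ttest",
]


def _check_same_grid(S, R):
    S = np.asarray(S, bool)
    R = np.asarray(R, bool)
    if S.shape != R.shape:
        raise ValueError(f"grid mismatch: {S.shape} vs {R.shape}")
    return S, R


def dice(S, R) -> float:
    """Dice score: twice the overlap over the sum of segmented volumes.

    Both-empty is defined as 1 (perfect trivial agreement).
    """
    S, R = _check_same_grid(S, R)
    s, r = int(S.sum()), int(R.sum())
    if s + r == 0:
        return 1.0
    return 2.0 * int((S & R).sum()) / (s + r)


@dataclass
class ErrorDecomposition:
    """Voxelwise maps and counts of the detection/outline error split.

    For segmentation S against reference R:
    OEFP/OEFN — boundary voxels of lesions present in both (S\\R and R\\S
    within intersecting components); DEFP/DEFN — whole components present
    in only one of the two; TP — the shared voxels.
    """

    tp_mask: np.ndarray
    oefp_mask: np.ndarray
    oefn_mask: np.ndarray
    defp_mask: np.ndarray
    defn_mask: np.ndarray
    voxel_mm: tuple = (1.0, 1.0, 1.0)

    def counts(self) -> dict:
        return {
            "TP": int(self.tp_mask.sum()),
            "OEFP": int(self.oefp_mask.sum()),
            "OEFN": int(self.oefn_mask.sum()),
            "DEFP": int(self.defp_mask.sum()),
            "DEFN": int(self.defn_mask.sum()),
        }

    def ml(self) -> dict:
        v = voxel_volume_ml(self.voxel_mm)
        return {k: n * v for k, n in self.counts().items()}

    def dice_from_decomposition(self) -> float:
        c = self.counts()
        denom = 2 * c["TP"] + c["OEFP"] + c["DEFP"] + c["OEFN"] + c["DEFN"]
        if denom == 0:
            return 1.0
        return 2.0 * c["TP"] / denom


def decompose_errors(S, R, connectivity=18, voxel_mm=(1.0, 1.0, 1.0)) -> ErrorDecomposition:
    """Split disagreement between S and R into DE and OE, each FP and FN.

    A lesion component of one segmentation is "the same lesion" as in the
    other when the two share at least one voxel; its surplus voxels then
    count as outline error. Components with empty intersection are
    detection errors in their entirety.
    """
    S, R = _check_same_grid(S, R)
    struct = connectivity_structure(connectivity)
    tp = S & R

    oefp = np.zeros_like(S)
    defp = np.zeros_like(S)
    labels_s, n_s = ndimage.label(S, structure=struct)
    for i in range(1, n_s + 1):
        comp = labels_s == i
        if (comp & R).any():
            oefp |= comp & ~R
        else:
            defp |= comp

    oefn = np.zeros_like(S)
    defn = np.zeros_like(S)
    labels_r, n_r = ndimage.label(R, structure=struct)
    for i in range(1, n_r + 1):
        comp = labels_r == i
        if (comp & S).any():
            oefn |= comp & ~S
        else:
            defn |= comp

    return ErrorDecomposition(tp, oefp, oefn, defp, defn, tuple(voxel_mm))


def confusion_summary(pairs, connectivity=18) -> pd.DataFrame:
    """Sum a set of (S, R, voxel_mm) pairs into one confusion table (ml).

    Layout mirrors a reference-vs-segmentation confusion matrix: the
    false-positive cell (reference negative, segmentation positive) and the
    false-negative cell are each split into their outline- and
    detection-error parts; the diagonal lesion cell is the TP volume.
    """
    totals = {"TP": 0.0, "OEFP": 0.0, "OEFN": 0.0, "DEFP": 0.0, "DEFN": 0.0}
    for S, R, voxel_mm in pairs:
        ml = decompose_errors(S, R, connectivity=connectivity, voxel_mm=voxel_mm).ml()
        for k in totals:
            totals[k] += ml[k]
    return pd.DataFrame(
        {
            "segmentation_no_lesion": [np.nan, totals["OEFN"] + totals["DEFN"]],
            "segmentation_lesion": [totals["OEFP"] + totals["DEFP"], totals["TP"]],
            "FP_OE": [totals["OEFP"], np.nan],
            "FP_DE": [totals["DEFP"], np.nan],
            "FN_OE": [np.nan, totals["OEFN"]],
            "FN_DE": [np.nan, totals["DEFN"]],
        },
        index=["reference_no_lesion", "reference_lesion"],
    )


@dataclass
class AgreementStats:
    icc: float
    ci_low: float
    ci_high: float

    def __post_init__(self):
        if not (self.ci_low <= self.icc <= self.ci_high):
            # numerical edge: clamp the point estimate into its interval
            self.icc = min(max(self.icc, self.ci_low), self.ci_high)


def icc_agreement(table, alpha=0.05) -> AgreementStats:
    """ICC(2,1): two-way random effects, absolute agreement, single measure.

    ``table`` is subjects x raters with no missing cells. The confidence
    interval is the standard F-based interval (McGraw & Wong).
    """
    Y = np.asarray(table, dtype=float)
    if Y.ndim != 2 or Y.shape[0] < 2 or Y.shape[1] < 2:
        raise ValueError("need a subjects x raters table, >= 2 of each")
    if not np.all(np.isfinite(Y)):
        raise ValueError("table contains missing/non-finite cells")
    n, k = Y.shape
    grand = Y.mean()
    if np.allclose(Y, grand):
        raise ValueError("zero total variance: ICC undefined")
    row_means = Y.mean(axis=1)
    col_means = Y.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((Y - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))

    icc = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)

    # McGraw & Wong F-based interval for ICC(A,1)
    a = k * icc / (n * (1.0 - icc)) if icc < 1 else np.inf
    b = 1.0 + k * icc * (n - 1.0) / (n * (1.0 - icc)) if icc < 1 else np.inf
    if np.isfinite(a) and (a * msc + b * mse) > 0:
        v = (a * msc + b * mse) ** 2 / (
            (a * msc) ** 2 / (k - 1.0)
            + (b * mse) ** 2 / ((n - 1.0) * (k - 1.0))
        )
        f_low = stats.f.ppf(1 - alpha / 2, n - 1.0, v)
        f_up = stats.f.ppf(1 - alpha / 2, v, n - 1.0)
        lower = n * (msr - f_low * mse) / (
            f_low * (k * msc + (k * n - k - n) * mse) + n * msr
        )
        upper = n * (f_up * msr - mse) / (
            k * msc + (k * n - k - n) * mse + n * f_up * msr
        )
    else:
        lower = upper = icc
    return AgreementStats(float(icc), float(lower), float(upper))


def bland_altman(a, b):
    """Bland-Altman agreement: mean difference and 95% limits of agreement
    (mean +/- 1.96 x sample SD of the paired differences).

    Returns
    -------
    mean_diff, loa_low, loa_high : float
    points : ndarray (n, 2) of (pair mean, difference) for plotting
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValueError("need two equal-length 1-D arrays with >= 2 entries")
    d = a - b
    mean_diff = float(d.mean())
    sd = float(d.std(ddof=1))
    loa_low = mean_diff - 1.96 * sd
    loa_high = mean_diff + 1.96 * sd
    points = np.column_stack([(a + b) / 2.0, d])
    return mean_diff, loa_low, loa_high, points


def paired_log2_ttest(a, b):
    """Two-sided paired t-test on log2-transformed volumes.

    Volumes must be strictly positive; the mean of log2(a) - log2(b) is the
    mean log2 volume ratio.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValueError("need two equal-length 1-D arrays with >= 2 entries")
    if np.any(a <= 0) or np.any(b <= 0):
        raise ValueError("volumes must be strictly positive for log transform")
    d = np.log2(a) - np.log2(b)
    if np.allclose(d, 0.0):
        return 0.0, 1.0
    if np.isclose(d.std(ddof=1), 0.0):
        # constant nonzero ratio: degenerate test, overwhelming evidence
        return float(np.sign(d.mean()) * np.inf), 0.0
    res = stats.ttest_rel(np.log2(a), np.log2(b))
    return float(res.statistic), float(res.pvalue)
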