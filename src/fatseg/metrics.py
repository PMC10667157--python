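"""Agreement, error and reliability metrics for fat segmentation and volumetry.

Two families of measures are implemented. Pixelwise agreement between a
predicted and a reference label map is summarised by overall accuracy and
per-class Dice coefficients. Volumetric agreement between predicted and
reference fat volumes over a cohort is summarised by the Pearson
correlation R, the mean percentage error MPE (bias), the population
standard deviation SD of the relative errors (variation), the
root-mean-square percentage error RMSPE, the second Wasserstein distance
PW2 of the mean-normalised volume distributions, and the excess kurtosis
k_ex of the relative errors. Reliability between paired measurements is
summarised by the intraclass correlation ICC and the coefficient of
variation CV, and method comparison by a Bland-Altman summary.

All relative-error statistics use population (1/n) normalisation so that
the decomposition RMSPE^2 = MPE^2 + SD^2 is exact.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import LABELS, SAT, VAT

__all__ = [
    "SegmentationScores",
    "VolumeAgreementReport",
    "ReliabilityReport",
    "BlandAltmanSummary",
    "segmentation_scores",
    "dice_coefficient",
    "relative_errors",
    "mpe",
    "sd_rel",
    "rmspe",
    "pearson_r",
    "pw2_rel",
    "excess_kurtosis",
    "icc",
    "cv",
    "bland_altman",
    "volume_agreement",
]


@dataclass(frozen=True)
class SegmentationScores:
    """Pixelwise agreement: overall accuracy and per-class Dice."""

    accuracy: float
    dice_sat: float
    dice_vat: float


@dataclass(frozen=True)
class VolumeAgreementReport:
    """Cohort-level volumetric agreement between predicted and true volumes."""

    r: float
    mpe: float
    sd: float
    rmspe: float
    pw2: float
    k_ex: float


@dataclass(frozen=True)
class ReliabilityReport:
    icc: float
    cv: float


@dataclass(frozen=True)
class BlandAltmanSummary:
    """Mean relative difference and 95% limits of agreement (mu +/- 1.96 SD)."""

    mu: float
    lower: float
    upper: float


def _as1d(x) -> np.ndarray:
    return np.asarray(x, dtype=float).ravel()


def dice_coefficient(pred: np.ndarray, truth: np.ndarray, label: int) -> float:
    """Dice overlap 2|P∩T|/(|P|+|T|) for one label; empty-vs-empty is 1."""
    p = pred == label
    t = truth == label
    denom = p.sum() + t.sum()
    if denom == 0:
        return 1.0
    return 2.0 * np.logical_and(p, t).sum() / denom


def segmentation_scores(pred: np.ndarray, truth: np.ndarray) -> SegmentationScores:
    """Accuracy over all three classes plus SAT and VAT Dice.

    Raises on shape mismatch or labels outside {0, 1, 2}.
    """
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs truth {truth.shape}")
    for name, arr in (("pred", pred), ("truth", truth)):
        if not np.isin(arr, LABELS).all():
            raise ValueError(f"{name} contains labels outside {LABELS}")
    return SegmentationScores(
        accuracy=float(np.mean(pred == truth)),
        dice_sat=float(dice_coefficient(pred, truth, SAT)),
        dice_vat=float(dice_coefficient(pred, truth, VAT)),
    )


def relative_errors(v_pred, v_true) -> np.ndarray:
    """Per-subject relative errors e_i = (pred_i - true_i) / true_i."""
    v_pred, v_true = _as1d(v_pred), _as1d(v_true)
    if v_pred.shape != v_true.shape:
        raise ValueError("v_pred and v_true must have equal length")
    if np.any(v_true <= 0):
        raise ValueError("true volumes must be strictly positive")
    return (v_pred - v_true) / v_true


def mpe(e) -> float:
    """Mean percentage error (bias) of the relative errors."""
    return float(np.mean(_as1d(e)))


def sd_rel(e) -> float:
    """Population standard deviation (variation) of the relative errors."""
    e = _as1d(e)
    if e.size < 2:
        raise ValueError("sd_rel needs at least 2 samples")
    return float(np.std(e))


def rmspe(e) -> float:
    """Root-mean-square percentage error; satisfies rmspe^2 = mpe^2 + sd^2."""
    return float(np.sqrt(np.mean(np.square(_as1d(e)))))


def pearson_r(v_pred, v_true) -> float:
    """Pearson linear correlation between predicted and true volumes."""
    v_pred, v_true = _as1d(v_pred), _as1d(v_true)
    if v_pred.size < 2:
        raise ValueError("pearson_r needs at least 2 samples")
    return float(np.corrcoef(v_pred, v_true)[0, 1])


def pw2_rel(v_pred, v_true) -> float:
    """Second Wasserstein distance between the mean-normalised empirical
    distributions of predicted and true volumes.

    Both samples are divided by ``mean(v_true)``; with equal sample sizes
    the quantile-matched form is
    ``W2 = sqrt(mean((sort(x) - sort(y))^2))``.
    """
    v_pred, v_true = _as1d(v_pred), _as1d(v_true)
    if v_pred.size == 0 or v_pred.shape != v_true.shape:
        raise ValueError("pw2_rel needs two equal-length non-empty samples")
    scale = np.mean(v_true)
    if scale <= 0:
        raise ValueError("mean true volume must be positive")
    x = np.sort(v_pred / scale)
    y = np.sort(v_true / scale)
    return float(np.sqrt(np.mean(np.square(x - y))))


def excess_kurtosis(e) -> float:
    """Fourth standardised moment minus 3, with population moments."""
    e = _as1d(e)
    if e.size < 4:
        raise ValueError("excess_kurtosis needs at least 4 samples")
    c = e - e.mean()
    var = np.mean(c**2)
    if var == 0:
        raise ValueError("excess_kurtosis undefined for zero variance")
    return float(np.mean(c**4) / var**2 - 3.0)


def icc(a, b, form: str = "absolute") -> float:
    """Intraclass correlation for paired measurements.

    The default is the two-way, single-measure, absolute-agreement form
    ICC(2,1); ``form="consistency"`` gives the consistency form ICC(3,1).
    Computed from the two-way ANOVA decomposition with n subjects and
    k = 2 raters.
    """
    a, b = _as1d(a), _as1d(b)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("icc needs two equal-length samples, n >= 2")
    x = np.stack([a, b], axis=1)  # n subjects x k raters
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((x - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)          # between-subjects
    msc = ss_cols / (k - 1)          # between-raters
    mse = ss_err / ((n - 1) * (k - 1))
    if form == "absolute":
        denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    elif form == "consistency":
        denom = msr + (k - 1) * mse
    else:
        raise ValueError(f"unknown ICC form: {form!r}")
    if denom == 0:
        return 1.0
    return float((msr - mse) / denom)


def cv(a, b) -> float:
    """Root-mean-square coefficient of variation over paired measurements:
    sqrt(mean_i((within-pair SD_i / within-pair mean_i)^2)).
    """
    a, b = _as1d(a), _as1d(b)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("cv needs two equal-length samples, n >= 2")
    means = (a + b) / 2.0
    if np.any(means == 0):
        raise ValueError("cv undefined when a within-pair mean is zero")
    sds = np.abs(a - b) / np.sqrt(2.0)  # sample SD of two values
    return float(np.sqrt(np.mean((sds / means) ** 2)))


def bland_altman(v_pred, v_true) -> BlandAltmanSummary:
    """Mean relative difference and 95% limits of agreement."""
    e = relative_errors(v_pred, v_true)
    mu = float(np.mean(e))
    sd = float(np.std(e))
    return BlandAltmanSummary(mu=mu, lower=mu - 1.96 * sd, upper=mu + 1.96 * sd)


def volume_agreement(v_pred, v_true) -> VolumeAgreementReport:
    """Full cohort-level agreement report between predicted and true volumes.

    Statistics that are undefined on degenerate inputs (constant errors,
    constant predictions) are reported as NaN rather than raising, so an
    agreement report can always be produced for an untrained or
    pathological predictor.
    """
    e = relative_errors(v_pred, v_true)
    degenerate = np.std(np.asarray(v_pred, dtype=float)) == 0 or np.std(e) == 0
    return VolumeAgreementReport(
        r=float("nan") if degenerate else pearson_r(v_pred, v_true),
        mpe=mpe(e),
        sd=sd_rel(e),
        rmspe=rmspe(e),
        pw2=pw2_rel(v_pred, v_true),
        k_ex=excess_kurtosis(e) if len(e) >= 4 and np.std(e) > 0 else float("nan"),
    )
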