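"""Repeatability metrics: precision errors and intra-class correlation.

Each phenotyping method's repeatability is summarized from repeated
measurements of the same samples: per-sample absolute precision error
PE(SD) and relative precision error PE(%CV), averaged across samples by
root-mean-square, and the two-way mixed-model single-measure
absolute-agreement intra-class correlation coefficient with an F-based
95% confidence interval.  ICC > 0.8 is reported as excellent
reproducibility.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["PrecisionResult", "ICCResult", "precision_metrics", "icc_absolute_agreement"]


@dataclass
class PrecisionResult:
    pe_sd: np.ndarray  # per-sample SD across replicates
    pe_cv: np.ndarray  # per-sample 100 * SD / mean (NaN where mean is 0)
    rms_sd: float
    rms_cv: float


@dataclass
class ICCResult:
    icc: float
    ci_low: float
    ci_high: float
    excellent: bool  # icc > 0.8


def precision_metrics(replicates) -> PrecisionResult:
    """Precision errors from a samples x replicates matrix.

    PE(SD) is the per-sample standard deviation (n-1); PE(%CV) the same as
    a percentage of the sample mean.  Parameter-level averages are
    root-mean-square over samples.  A zero sample mean with nonzero SD
    leaves that sample's %CV undefined (NaN, with a warning).
    """
    X = np.asarray(replicates, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("need a 2D samples x replicates matrix with >= 2 replicates")
    sd = X.std(axis=1, ddof=1)
    mean = X.mean(axis=1)
    cv = np.full(sd.shape, np.nan)
    nonzero = mean != 0
    cv[nonzero] = 100.0 * sd[nonzero] / np.abs(mean[nonzero])
    if np.any(~nonzero & (sd > 0)):
        warnings.warn("zero sample mean with nonzero SD: %CV undefined for that sample",
                      stacklevel=2)
    rms_sd = float(np.sqrt(np.mean(sd**2)))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        rms_cv = float(np.sqrt(np.nanmean(cv**2)))
    return PrecisionResult(pe_sd=sd, pe_cv=cv, rms_sd=rms_sd, rms_cv=rms_cv)


def icc_absolute_agreement(matrix, confidence: float = 0.95) -> ICCResult:
    """ICC(A,1): two-way model, single measure, absolute agreement.

    From the two-way ANOVA mean squares of an n samples x k raters matrix
    (no missing cells):

        ICC = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)

    with the F-distribution confidence interval on Satterthwaite degrees
    of freedom.  Zero total variance leaves the coefficient undefined.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("need >= 2 samples and >= 2 repeats")
    if not np.all(np.isfinite(X)):
        raise ValueError("missing cells are not supported")
    n, k = X.shape
    if np.ptp(X) == 0:
        warnings.warn("zero total variance: ICC undefined", stacklevel=2)
        return ICCResult(icc=float("nan"), ci_low=float("nan"),
                         ci_high=float("nan"), excellent=False)
    grand = X.mean()
    row_means = X.mean(axis=1)
    col_means = X.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((X - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))

    icc = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)

    alpha = 1.0 - confidence
    a = k * icc / (n * (1.0 - icc)) if icc < 1.0 else np.inf
    b = 1.0 + k * icc * (n - 1) / (n * (1.0 - icc)) if icc < 1.0 else np.inf
    if np.isfinite(a) and (a * msc + b * mse) > 0:
        v = (a * msc + b * mse) ** 2 / (
            (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
        )
        f1 = stats.f.ppf(1.0 - alpha / 2, n - 1, v)
        f2 = stats.f.ppf(1.0 - alpha / 2, v, n - 1)
        lower = n * (msr - f1 * mse) / (
            f1 * (k * msc + (k * n - k - n) * mse) + n * msr
        )
        upper = n * (f2 * msr - mse) / (
            k * msc + (k * n - k - n) * mse + n * f2 * msr
        )
    else:
        lower, upper = float("nan"), float("nan")
    return ICCResult(
        icc=float(icc),
        ci_low=float(lower),
        ci_high=float(upper),
        excellent=bool(icc > 0.8),
    )
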