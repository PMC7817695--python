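"""Multivariate outlier screen calling mutant lines with abnormal joint phenotypes.

A mutant line is screened against a large wild-type reference cohort on 18
joint parameters (9 per plateau side) by three complementary criteria:

1. **Reference range** — the line mean of a parameter falls outside the
   wild-type envelope: mean +/- 2 SD for normally distributed parameters
   (Shapiro-Wilk), or the 2.5th-97.5th percentile range otherwise.
2. **Wilcoxon rank-sum screen** — two-tailed rank-sum tests per parameter
   against the reference, declared significant below alpha divided by the
   *effective* number of tests N_eff, computed from the eigenvalues of the
   reference parameter correlation matrix as
   N_eff = N - sum_{lambda > 1} (lambda - 1);
   a second, more stringent threshold (P < 1e-4) additionally corrects for
   the number of lines screened.
3. **Robust Mahalanobis distances** — the minimum volume ellipsoid (MVE)
   estimate of location and scatter of the reference cohort yields robust
   distances MD_i; an animal with MD_i^2 above the chi-square 0.975
   quantile (p degrees of freedom) is a multivariate outlier, and a line
   is called when at least 50% of its animals are flagged.

Each line also receives severity points: one per criterion met (max 3)
plus one per abnormal phenotype category — cartilage morphology, cartilage
integrity, subchondral bone structure (max 3).
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DEFAULT_PARAMETERS",
    "ReferenceRange",
    "MahalanobisResult",
    "LineScreenReport",
    "ScreenConfig",
    "ScreenResult",
    "fit_reference_range",
    "classify_range_outlier",
    "wilcoxon_screen",
    "effective_tests",
    "bonferroni_threshold",
    "mve_fit",
    "robust_mahalanobis",
    "line_mahalanobis_call",
    "default_category_map",
    "screen_lines",
]

_SIDES = ("MTP", "LTP")
_PER_SIDE = (
    "Cg.V",
    "Median Cg.Th",
    "Max Cg.Th",
    "Cg. Damage Area",
    "SC BV/TV",
    "SC Tb.Th",
    "SC Tb.N",
    "SC TMD",
    "SC BMC",
)
#: The 18 joint parameters: 9 per tibial plateau side.
DEFAULT_PARAMETERS = tuple(f"{side} {p}" for side in _SIDES for p in _PER_SIDE)


def default_category_map(parameters: Sequence[str]) -> dict[str, str]:
    """Map parameter names to severity categories by morphometric family."""
    out = {}
    for name in parameters:
        if "Damage" in name:
            out[name] = "cartilage_integrity"
        elif "Cg." in name:
            out[name] = "cartilage_morphology"
        else:
            out[name] = "subchondral_structure"
    return out


@dataclass
class ReferenceRange:
    parameter: str
    is_normal: bool
    center: float
    low: float
    high: float
    n_reference: int


@dataclass
class MahalanobisResult:
    robust_center: np.ndarray
    robust_cov: np.ndarray
    distances: np.ndarray
    flags: np.ndarray
    h: int


@dataclass
class LineScreenReport:
    line: str
    n_animals: int
    range_outlier_params: list[str]
    wilcoxon_p: dict[str, float]
    wilcoxon_outlier_params: list[str]
    wilcoxon_outlier_params_stringent: list[str]
    mahalanobis_fraction: float
    mahalanobis_call: bool
    categories: dict[str, bool]
    severity_points: int

    @property
    def criteria(self) -> tuple[bool, bool, bool]:
        return (
            bool(self.range_outlier_params),
            bool(self.wilcoxon_outlier_params),
            self.mahalanobis_call,
        )


@dataclass
class ScreenConfig:
    reference_line: str = "WT"
    alpha: float = 0.05
    alpha_normality: float = 0.05
    stringent_p: float = 1e-4
    exact_limit: int = 10  # Wilcoxon exact branch when min(n) <= this and no ties
    category_map: Optional[dict[str, str]] = None
    mve_subsets: int = 10000
    seed: int = 0


@dataclass
class ScreenResult:
    reports: list[LineScreenReport]
    n_eff: float
    threshold: float
    reference_ranges: dict[str, ReferenceRange]
    mahalanobis: Optional[MahalanobisResult]
    qq: Optional[tuple[np.ndarray, np.ndarray]]  # (chi2 quantiles, ordered MD^2)
    config: ScreenConfig = field(default_factory=ScreenConfig)


def fit_reference_range(
    values: Sequence[float],
    parameter: str = "",
    alpha_normality: float = 0.05,
) -> ReferenceRange:
    """Wild-type envelope of one parameter.

    Shapiro-Wilk at ``alpha_normality`` decides the branch: normal data get
    mean +/- 2 SD (sample SD, n-1), non-normal data the 2.5th-97.5th
    percentiles (linear interpolation between closest ranks) around the
    median.
    """
    x = np.asarray(values, dtype=float)
    n_missing = np.count_nonzero(~np.isfinite(x))
    if n_missing:
        warnings.warn(
            f"{parameter or 'parameter'}: {n_missing} missing values excluded "
            "from the reference range",
            stacklevel=2,
        )
        x = x[np.isfinite(x)]
    if x.size < 3:
        raise ValueError("reference range requires at least 3 finite values")
    if np.ptp(x) == 0:
        warnings.warn(
            f"{parameter or 'parameter'}: constant reference sample, degenerate range",
            stacklevel=2,
        )
        v = float(x[0])
        return ReferenceRange(parameter, True, v, v, v, x.size)
    _, p_sw = stats.shapiro(x)
    if p_sw >= alpha_normality:
        mean = float(x.mean())
        sd = float(x.std(ddof=1))
        return ReferenceRange(parameter, True, mean, mean - 2.0 * sd, mean + 2.0 * sd, x.size)
    low, high = np.percentile(x, [2.5, 97.5])
    return ReferenceRange(parameter, False, float(np.median(x)), float(low), float(high), x.size)


def classify_range_outlier(line_values: Sequence[float], rng: ReferenceRange) -> bool:
    """True when the line mean lies outside the reference envelope."""
    x = np.asarray(line_values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size == 0:
        raise ValueError("need at least one finite value")
    m = x.mean()
    return bool(m < rng.low or m > rng.high)


def wilcoxon_screen(
    line_values: Sequence[float],
    reference_values: Sequence[float],
    exact_limit: int = 10,
) -> float:
    """Two-tailed Wilcoxon rank-sum P of line vs reference.

    Exact null distribution when the smaller sample has at most
    ``exact_limit`` observations and the pooled sample is tie-free;
    otherwise the normal approximation with tie and continuity
    corrections (the rank-sum convention of common statistical
    environments).
    """
    x = np.asarray(line_values, dtype=float)
    y = np.asarray(reference_values, dtype=float)
    x = x[np.isfinite(x)]
    y = y[np.isfinite(y)]
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        return 1.0
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (min(x.size, y.size) <= exact_limit and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    p = float(res.pvalue)
    return 1.0 if math.isnan(p) else min(p, 1.0)


def effective_tests(reference_matrix) -> float:
    """Effective number of independent tests among correlated parameters.

    N_eff = N - sum over eigenvalues lambda of the parameter correlation
    matrix of I(lambda > 1) * (lambda - 1).  Equals N for independent
    parameters and collapses to 1 in the rank-one limit.
    """
    if isinstance(reference_matrix, pd.DataFrame):
        names = list(reference_matrix.columns)
        X = reference_matrix.to_numpy(dtype=float)
    else:
        X = np.asarray(reference_matrix, dtype=float)
        names = [f"column {i}" for i in range(X.shape[1])]
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("need a 2D matrix with at least 2 parameters")
    sds = np.nanstd(X, axis=0)
    for j, sd in enumerate(sds):
        if sd == 0:
            raise ValueError(f"constant column {names[j]!r} has no correlation structure")
    corr = np.corrcoef(X, rowvar=False)
    lam = np.linalg.eigvalsh(corr)
    excess = lam[lam > 1.0] - 1.0
    return float(X.shape[1] - excess.sum())


def bonferroni_threshold(alpha: float = 0.05, n_eff: float = 1.0) -> float:
    """Significance threshold alpha / N_eff."""
    if n_eff < 1:
        raise ValueError("n_eff must be >= 1")
    return alpha / n_eff


def _subset_objective(X: np.ndarray, idx: np.ndarray, h: int):
    """log-volume objective of the ellipsoid grown from one (p+1)-subset."""
    sub = X[idx]
    mean = sub.mean(axis=0)
    cov = np.cov(sub, rowvar=False)
    sign, logdet = np.linalg.slogdet(cov)
    if sign <= 0:
        return None
    try:
        d2 = _sq_mahalanobis(X, mean, cov)
    except np.linalg.LinAlgError:
        return None
    m2 = np.partition(d2, h - 1)[h - 1]
    if m2 <= 0:
        return None
    p = X.shape[1]
    return logdet + p * np.log(m2), d2


def _sq_mahalanobis(X: np.ndarray, center: np.ndarray, cov: np.ndarray) -> np.ndarray:
    diff = X - center
    return np.einsum("ij,ij->i", diff, np.linalg.solve(cov, diff.T).T)


def mve_fit(
    X,
    seed: int = 0,
    n_subsets: int = 10000,
    exhaustive_limit: int = 20,
    reweight: bool = True,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Minimum volume ellipsoid estimate of location and scatter.

    Searches elemental (p+1)-subsets, expands each to the h = floor((n+p+1)/2)
    points nearest in its metric, and keeps the subset of minimum ellipsoid
    volume.  The mean and covariance of that h-subset (covariance rescaled
    so the median squared distance of the full sample matches the
    chi-square median) form the raw estimate; by default one reweighting
    step follows — the classical mean and covariance of the points within
    the chi-square 0.975 cutoff of the raw estimate, with the truncation
    consistency factor — which keeps the breakdown of the raw fit but is
    far more efficient on clean data.  All n <= ``exhaustive_limit``
    subsets are enumerated when feasible; otherwise ``n_subsets`` seeded
    random subsets are drawn.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2D (samples x parameters)")
    n, p = X.shape
    if n <= p:
        raise ValueError(f"need more samples ({n}) than parameters ({p})")
    h = (n + p + 1) // 2
    rng = np.random.default_rng(seed)

    if n <= exhaustive_limit and math.comb(n, p + 1) <= max(n_subsets, 100000):
        subset_iter = (np.array(c) for c in itertools.combinations(range(n), p + 1))
    else:
        subset_iter = (rng.choice(n, size=p + 1, replace=False) for _ in range(n_subsets))

    best = None
    best_d2 = None
    tried = 0
    for idx in subset_iter:
        tried += 1
        out = _subset_objective(X, idx, h)
        if out is None:
            continue
        obj, d2 = out
        if best is None or obj < best:
            best = obj
            best_d2 = d2
    if best is None:
        raise np.linalg.LinAlgError(
            f"no non-singular (p+1)-subset found in {tried} draws; "
            "X may be rank deficient"
        )
    keep = np.argsort(best_d2)[:h]
    T = X[keep].mean(axis=0)
    C_h = np.cov(X[keep], rowvar=False)
    sign, _ = np.linalg.slogdet(C_h)
    if sign <= 0:
        raise np.linalg.LinAlgError("covariance of the optimal h-subset is singular")
    d2_all = _sq_mahalanobis(X, T, C_h)
    factor = np.median(d2_all) / stats.chi2.ppf(0.5, p)
    C = C_h * factor
    if reweight:
        cutoff = stats.chi2.ppf(0.975, p)
        keep_rw = _sq_mahalanobis(X, T, C) <= cutoff
        m = int(keep_rw.sum())
        if m > p + 2:
            T = X[keep_rw].mean(axis=0)
            C = np.cov(X[keep_rw], rowvar=False)
            # truncation consistency: the classical covariance of the
            # inner 97.5% of a normal sample underestimates the scatter
            C /= stats.chi2.cdf(cutoff, p + 2) / 0.975
            # finite-sample consistency: squared distances of points not in
            # the fit follow a scaled F, with mean p (m-1)(m+1)/(m (m-p-2))
            # under an m-point classical covariance; rescale so the
            # chi-square cutoff applies to fresh observations
            C *= (m - 1) * (m + 1) / (m * (m - p - 2))
    return T, C, h


def robust_mahalanobis(
    X, center: np.ndarray, cov: np.ndarray
) -> MahalanobisResult:
    """Robust distances MD_i and outlier flags MD_i^2 > chi2_{p; 0.975}."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    center = np.asarray(center, dtype=float)
    cov = np.asarray(cov, dtype=float)
    p = center.size
    if X.shape[1] != p or cov.shape != (p, p):
        raise ValueError("dimension mismatch between X, center and covariance")
    d2 = _sq_mahalanobis(X, center, cov)
    cutoff = stats.chi2.ppf(0.975, p)
    return MahalanobisResult(
        robust_center=center,
        robust_cov=cov,
        distances=np.sqrt(np.maximum(d2, 0.0)),
        flags=d2 > cutoff,
        h=0,
    )


def line_mahalanobis_call(flags: Sequence[bool]) -> bool:
    """A line is abnormal when >= 50% of its animals are flagged."""
    flags = np.asarray(flags, dtype=bool)
    if flags.size == 0:
        return False
    return bool(flags.mean() >= 0.5)


def screen_lines(table: pd.DataFrame, config: Optional[ScreenConfig] = None) -> ScreenResult:
    """Run the full three-criterion screen on a phenotype table.

    ``table`` needs a ``line`` column plus one column per parameter
    (non-numeric columns other than ``line`` are ignored).  The reference
    line supplies the ranges, N_eff, and the MVE fit; every other line is
    screened against it.
    """
    cfg = config or ScreenConfig()
    if "line" not in table.columns:
        raise ValueError("table must contain a 'line' column")
    params = [
        c
        for c in table.columns
        if c not in ("line", "animal_id") and pd.api.types.is_numeric_dtype(table[c])
    ]
    if not params:
        raise ValueError("no numeric parameter columns found")
    ref = table[table["line"] == cfg.reference_line]
    if ref.empty:
        raise ValueError(f"reference line {cfg.reference_line!r} not present")

    ref_X = ref[params].to_numpy(dtype=float)
    n_eff = effective_tests(ref[params].dropna()) if len(params) > 1 else 1.0
    threshold = bonferroni_threshold(cfg.alpha, n_eff)
    ranges = {
        p: fit_reference_range(ref[p].to_numpy(), p, cfg.alpha_normality) for p in params
    }
    cat_map = cfg.category_map or default_category_map(params)
    categories_all = sorted(set(cat_map.values()))

    complete_ref = ref_X[np.all(np.isfinite(ref_X), axis=1)]
    if complete_ref.shape[0] < ref_X.shape[0]:
        warnings.warn(
            "reference animals with incomplete rows dropped from the Mahalanobis fit",
            stacklevel=2,
        )
    mve = None
    qq = None
    if complete_ref.shape[0] > len(params):
        T, C, h = mve_fit(complete_ref, seed=cfg.seed, n_subsets=cfg.mve_subsets)
        mve = robust_mahalanobis(complete_ref, T, C)
        mve.h = h
        md2 = np.sort(mve.distances**2)
        probs = (np.arange(1, md2.size + 1) - 0.5) / md2.size
        qq = (stats.chi2.ppf(probs, len(params)), md2)
    else:
        warnings.warn(
            "too few complete reference rows for the Mahalanobis criterion; skipped",
            stacklevel=2,
        )

    reports = []
    for line, grp in table[table["line"] != cfg.reference_line].groupby("line", sort=True):
        range_out = []
        wilcox_p = {}
        wilcox_out = []
        wilcox_strict = []
        for p in params:
            vals = grp[p].to_numpy(dtype=float)
            vals = vals[np.isfinite(vals)]
            if vals.size == 0:
                wilcox_p[p] = float("nan")
                continue
            if classify_range_outlier(vals, ranges[p]):
                range_out.append(p)
            pv = wilcoxon_screen(
                vals, ref[p].dropna().to_numpy(), exact_limit=cfg.exact_limit
            )
            wilcox_p[p] = pv
            if pv < threshold:
                wilcox_out.append(p)
            if pv < cfg.stringent_p:
                wilcox_strict.append(p)

        maha_fraction = 0.0
        maha_call = False
        if mve is not None:
            line_X = grp[params].to_numpy(dtype=float)
            complete = line_X[np.all(np.isfinite(line_X), axis=1)]
            if complete.shape[0] < line_X.shape[0]:
                warnings.warn(
                    f"line {line}: incomplete rows dropped from Mahalanobis analysis",
                    stacklevel=2,
                )
            if complete.shape[0]:
                res = robust_mahalanobis(complete, mve.robust_center, mve.robust_cov)
                maha_fraction = float(res.flags.mean())
                maha_call = line_mahalanobis_call(res.flags)

        flagged = set(range_out) | set(wilcox_out)
        cats = {
            cat: any(cat_map.get(p) == cat for p in flagged) for cat in categories_all
        }
        n_criteria = sum((bool(range_out), bool(wilcox_out), maha_call))
        severity = min(3, n_criteria) + min(3, sum(cats.values()))
        reports.append(
            LineScreenReport(
                line=str(line),
                n_animals=int(len(grp)),
                range_outlier_params=range_out,
                wilcoxon_p=wilcox_p,
                wilcoxon_outlier_params=wilcox_out,
                wilcoxon_outlier_params_stringent=wilcox_strict,
                mahalanobis_fraction=maha_fraction,
                mahalanobis_call=maha_call,
                categories=cats,
                severity_points=severity,
            )
        )
    return ScreenResult(
        reports=reports,
        n_eff=n_eff,
        threshold=threshold,
        reference_ranges=ranges,
        mahalanobis=mve,
        qq=qq,
        config=cfg,
    )


def plot_qq(result: ScreenResult, path: str) -> None:
    """Save the chi-square QQ diagnostic of the reference robust distances."""
    if result.qq is None:
        raise ValueError("screen result carries no Mahalanobis QQ data")
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    q, md2 = result.qq
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.plot(q, md2, "o", ms=3)
    lim = max(q.max(), md2.max())
    ax.plot([0, lim], [0, lim], "k--", lw=1)
    ax.set_xlabel("chi-square quantiles")
    ax.set_ylabel("ordered robust MD$^2$")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
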