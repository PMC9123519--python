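"""Inter-grader and inter-device agreement statistics.

Implements the statistical layer used to compare paired cone-mosaic metric
estimates: one-way random-effects intraclass correlation (ICC) with its
F-based (Searle) confidence interval, Bland–Altman bias and 95% limits of
agreement with approximate confidence intervals, percent bias relative to
the grand mean, ordinary least-squares regression of paired differences on a
covariate, and the minimum detectable difference of a power analysis.

Sign convention: differences are ``A − B`` with A the first-listed rater or
device, so a positive density bias means A reads higher than B.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import ParameterError, UndefinedMetricError


@dataclass(frozen=True)
class PairedMetricTable:
    """Paired measurements of one metric by two raters or devices."""

    roi_ids: tuple
    a: np.ndarray
    b: np.ndarray
    label_a: str = "A"
    label_b: str = "B"
    units: str = ""

    @classmethod
    def from_pairs(cls, pairs: Sequence[tuple[float, float]],
                   label_a: str = "A", label_b: str = "B",
                   units: str = "") -> "PairedMetricTable":
        arr = np.asarray(pairs, dtype=float)
        return cls(roi_ids=tuple(range(len(arr))), a=arr[:, 0], b=arr[:, 1],
                   label_a=label_a, label_b=label_b, units=units)

    def values(self) -> np.ndarray:
        vals = np.column_stack([np.asarray(self.a, dtype=float),
                                np.asarray(self.b, dtype=float)])
        if not np.all(np.isfinite(vals)):
            raise ParameterError("paired table contains non-finite values")
        return vals


@dataclass(frozen=True)
class IccResult:
    icc: float
    ci: tuple[float, float]
    n: int
    k: int


@dataclass(frozen=True)
class AgreementResult:
    """Bland–Altman summary: bias, 95% limits of agreement and their CIs."""

    bias: float
    loa_lo: float
    loa_hi: float
    ci_bias: tuple[float, float]
    ci_loa_lo: tuple[float, float]
    ci_loa_hi: tuple[float, float]
    sd_diff: float
    percent_bias: float | None
    n: int


def _as_matrix(table: PairedMetricTable | np.ndarray) -> np.ndarray:
    if isinstance(table, PairedMetricTable):
        return table.values()
    m = np.asarray(table, dtype=float)
    if m.ndim != 2 or m.shape[1] < 2:
        raise ParameterError("need an (n_subjects, k_raters) table with k >= 2")
    return m


def icc_oneway(table: PairedMetricTable | np.ndarray,
               alpha: float = 0.05) -> IccResult:
    """One-way random-effects ANOVA intraclass correlation, ICC(1).

    ``ICC = (MS_between − MS_within) / (MS_between + (k−1)·MS_within)``,
    with the two-sided (1−alpha) confidence interval from the F distribution
    (Searle interval), matching the classical one-way ICC estimator.
    Zero total variance makes the ICC undefined; 1 is returned with a
    degenerate CI and a warning.
    """
    m = _as_matrix(table)
    n, k = m.shape
    if n < 3:
        raise ParameterError("need at least 3 subjects for an ICC CI")
    row_means = m.mean(axis=1)
    grand = m.mean()
    ms_between = k * ((row_means - grand) ** 2).sum() / (n - 1)
    ms_within = ((m - row_means[:, None]) ** 2).sum() / (n * (k - 1))
    if ms_between == 0 and ms_within == 0:
        warnings.warn("zero variance: ICC undefined, returning 1", stacklevel=2)
        return IccResult(icc=1.0, ci=(1.0, 1.0), n=n, k=k)
    if ms_within == 0:
        return IccResult(icc=1.0, ci=(1.0, 1.0), n=n, k=k)
    icc = (ms_between - ms_within) / (ms_between + (k - 1) * ms_within)
    f_obs = ms_between / ms_within
    df1, df2 = n - 1, n * (k - 1)
    f_lo = f_obs / stats.f.ppf(1 - alpha / 2, df1, df2)
    f_hi = f_obs * stats.f.ppf(1 - alpha / 2, df2, df1)
    lo = (f_lo - 1) / (f_lo + k - 1)
    hi = (f_hi - 1) / (f_hi + k - 1)
    return IccResult(icc=float(icc), ci=(float(lo), float(hi)), n=n, k=k)


def percent_bias(bias: float, mean_a: float, mean_b: float) -> float:
    """Bias as a percentage of the grand mean ``(mean_a + mean_b)/2``."""
    grand = (mean_a + mean_b) / 2.0
    if grand == 0:
        raise UndefinedMetricError("percent bias undefined at zero grand mean")
    return 100.0 * bias / grand


def bland_altman(table: PairedMetricTable | np.ndarray,
                 alpha: float = 0.05) -> AgreementResult:
    """Bland–Altman agreement of paired measurements (differences A − B).

    The limits of agreement use the classical 1.96 multiplier.  The bias CI
    is t-based; each limit's CI uses the large-sample variance approximation
    ``3·SD²/n``.
    """
    m = _as_matrix(table)
    if m.shape[0] < 3:
        raise ParameterError("need at least 3 pairs")
    a, b = m[:, 0], m[:, 1]
    d = a - b
    n = len(d)
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    if sd == 0:
        warnings.warn("constant differences: limits of agreement collapse "
                      "to the bias", stacklevel=2)
    loa_lo = bias - 1.96 * sd
    loa_hi = bias + 1.96 * sd
    t = stats.t.ppf(1 - alpha / 2, n - 1)
    se_bias = sd / np.sqrt(n)
    se_loa = np.sqrt(3.0 * sd ** 2 / n)
    pct = None
    try:
        pct = percent_bias(bias, float(a.mean()), float(b.mean()))
    except UndefinedMetricError:
        pass
    return AgreementResult(
        bias=bias, loa_lo=float(loa_lo), loa_hi=float(loa_hi),
        ci_bias=(bias - t * se_bias, bias + t * se_bias),
        ci_loa_lo=(loa_lo - t * se_loa, loa_lo + t * se_loa),
        ci_loa_hi=(loa_hi - t * se_loa, loa_hi + t * se_loa),
        sd_diff=sd, percent_bias=pct, n=n)


def diff_vs_covariate(table: PairedMetricTable | np.ndarray,
                      covariate: Sequence[float]) -> dict:
    """OLS regression of paired differences (A − B) on a covariate.

    Returns slope, intercept, r² and the two-sided slope p-value.
    """
    m = _as_matrix(table)
    x = np.asarray(covariate, dtype=float)
    if m.shape[0] < 3 or len(x) != m.shape[0]:
        raise ParameterError("need >= 3 rows and one covariate value per row")
    if np.ptp(x) == 0:
        raise ParameterError("constant covariate: slope undefined")
    d = m[:, 0] - m[:, 1]
    if np.ptp(d) == 0:  # constant differences: flat fit explains nothing
        return {"slope": 0.0, "intercept": float(d[0]), "r2": 0.0, "p": 1.0}
    res = stats.linregress(x, d)
    return {"slope": float(res.slope), "intercept": float(res.intercept),
            "r2": float(res.rvalue ** 2), "p": float(res.pvalue)}


def detectable_difference(mean: float, sd: float, n: int,
                          power: float = 0.80, alpha: float = 0.05,
                          design: str = "two_sample") -> float:
    """Minimum detectable difference as a percentage of ``mean``.

    two_sample: ``δ = (t_{1−α/2,2n−2} + t_{power,2n−2}) · sd · sqrt(2/n)``;
    paired:     ``δ = (t_{1−α/2,n−1} + t_{power,n−1}) · sd / sqrt(n)``.
    """
    if n < 2:
        raise ParameterError("n must be >= 2")
    if not (0 < power < 1 and 0 < alpha < 1):
        raise ParameterError("power and alpha must be in (0, 1)")
    if not mean > 0 or sd < 0:
        raise ParameterError("mean must be > 0 and sd >= 0")
    if design == "two_sample":
        df = 2 * n - 2
        delta = (stats.t.ppf(1 - alpha / 2, df)
                 + stats.t.ppf(power, df)) * sd * np.sqrt(2.0 / n)
    elif design == "paired":
        df = n - 1
        delta = (stats.t.ppf(1 - alpha / 2, df)
                 + stats.t.ppf(power, df)) * sd / np.sqrt(n)
    else:
        raise ParameterError(f"unknown design {design!r}")
    return float(100.0 * delta / mean)
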