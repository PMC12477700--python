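"""Single-case inference against a control cohort, plus supporting tests.

The central tool is the Crawford-Howell single-case t-test, which compares
one observation x* to a small control sample (mean x_bar, sd s, size n):

    t = (x* - x_bar) / (s * sqrt((n + 1) / n)),   df = n - 1,

with a two-tailed p from the t distribution. Control distributions are
summarized by empirical 95% percentile intervals (the violin envelopes of
the study's figures). One-sample t-tests (against zero or chance) and the
Wilcoxon signed-rank test round out the statistics used by the pipeline.
P values are reported uncorrected by default; Holm correction is available.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

logger = logging.getLogger("somastab.casestats")


@dataclass
class CaseVsControls:
    """A case's statistic against the control cohort."""

    case_value: float
    control_values: np.ndarray
    t: float
    df: int
    p_two_tailed: float
    interval_95: tuple[float, float]

    def __post_init__(self) -> None:
        self.control_values = np.asarray(self.control_values, dtype=float)

    @property
    def significant(self) -> bool:
        return self.p_two_tailed < 0.05


def crawford_howell_test(
    case_value: float, control_values: np.ndarray
) -> CaseVsControls:
    """Point estimate of the abnormality of a case relative to controls.

    Uses the n-inflated standard error so the test is exact for a single new
    observation from the control distribution; df = n - 1. Also attaches the
    empirical 95% percentile interval of the control values.
    """
    ctrl = np.asarray(control_values, dtype=float)
    n = len(ctrl)
    if n < 2:
        raise ValueError("need at least 2 control values")
    sd = ctrl.std(ddof=1)
    if sd == 0:
        raise ValueError("control values have zero variance")
    t = (case_value - ctrl.mean()) / (sd * np.sqrt((n + 1) / n))
    df = n - 1
    p = 2.0 * stats.t.sf(abs(t), df)
    return CaseVsControls(
        case_value=float(case_value),
        control_values=ctrl,
        t=float(t),
        df=df,
        p_two_tailed=float(min(p, 1.0)),
        interval_95=percentile_interval(ctrl, 0.95),
    )


def one_sample_t(values: np.ndarray, null_value: float = 0.0) -> tuple[float, int, float]:
    """Two-tailed one-sample t-test against ``null_value`` (closed form)."""
    x = np.asarray(values, dtype=float)
    n = len(x)
    if n < 2:
        raise ValueError("need at least 2 values")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("values have zero variance")
    t = (x.mean() - null_value) / (sd / np.sqrt(n))
    df = n - 1
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), df, float(min(p, 1.0))


def wilcoxon_signed_rank(
    paired_diffs: np.ndarray, alternative: str = "two-sided"
) -> tuple[float, float]:
    """Wilcoxon signed-rank test on paired differences.

    Zero differences are dropped; ties are mid-ranked; the null distribution
    is exact for n <= 25 without ties and a normal approximation otherwise.
    The reported statistic W is the smaller of the two signed rank sums
    (so W = 0 when all differences share a sign).
    """
    d = np.asarray(paired_diffs, dtype=float)
    d = d[d != 0]
    if len(d) == 0:
        raise ValueError("all paired differences are zero")
    method = "exact" if (len(d) <= 25 and len(np.unique(np.abs(d))) == len(d)) else "approx"
    res = stats.wilcoxon(d, alternative=alternative, method=method)
    return float(res.statistic), float(res.pvalue)


def percentile_interval(
    values: np.ndarray, coverage: float = 0.95
) -> tuple[float, float]:
    """Empirical central percentile interval with linear interpolation.

    coverage 0.95 returns the 2.5th and 97.5th percentiles (linear
    interpolation between order statistics); coverage 1.0 returns the range.
    """
    x = np.asarray(values, dtype=float)
    if len(x) < 2:
        raise ValueError("need at least 2 values for a percentile interval")
    if not 0.0 < coverage <= 1.0:
        raise ValueError("coverage must lie in (0, 1]")
    alpha = (1.0 - coverage) / 2.0
    lo, hi = np.quantile(x, [alpha, 1.0 - alpha], method="linear")
    return float(lo), float(hi)


def holm_correction(p_values: np.ndarray) -> np.ndarray:
    """Holm step-down adjusted p values (optional multiplicity control)."""
    p = np.asarray(p_values, dtype=float)
    order = np.argsort(p)
    m = len(p)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj


def shapiro_normality_advisory(values: np.ndarray, label: str = "") -> float:
    """Shapiro-Wilk normality screen: logs a warning, never switches tests."""
    x = np.asarray(values, dtype=float)
    if len(x) < 3:
        return float("nan")
    p = float(stats.shapiro(x).pvalue)
    if p < 0.05:
        warnings.warn(
            f"Shapiro-Wilk suggests non-normal control values"
            f"{f' for {label}' if label else ''} (p={p:.3f})",
            stacklevel=2,
        )
    return p
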