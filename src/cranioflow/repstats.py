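"""Test-retest repeatability, reliability and method-conformity statistics.

Implements the statistical surface of a two-session (or two-method, or
two-rating) flow study: intraclass correlation with Koo–Li grading,
Bland–Altman agreement, paired t-tests, Pearson correlation, the
lumen-area-versus-repeatability correlation, and group comparison summaries.

The ICC is the two-way, absolute-agreement, single-measurement form
ICC(A,1), computed from the two-way ANOVA mean squares:

    ICC(A,1) = (MS_R − MS_E) / (MS_R + (k−1)·MS_E + (k/n)·(MS_C − MS_E))

with MS_R the between-subject, MS_C the between-session and MS_E the
residual mean square.  Absolute agreement penalises a constant session
offset, which is the relevant notion of test-retest bias; the consistency
form ICC(C,1) is available behind a flag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PairedMeasurements",
    "RepeatabilityResult",
    "ConformityResult",
    "icc_absolute_agreement",
    "icc_consistency",
    "grade_icc",
    "bland_altman",
    "paired_t",
    "pearson",
    "size_vs_error",
    "group_compare",
    "repeatability_result",
    "significance_stars",
]


@dataclass
class PairedMeasurements:
    """Aligned paired values (session 1/2, method 2D/4D, or rating 1/2).

    Pairs with a missing value in either arm are dropped listwise on
    construction.
    """

    a: np.ndarray
    b: np.ndarray
    subject_ids: np.ndarray | None = None
    quantity: str = ""
    units: str = ""

    def __post_init__(self) -> None:
        a = np.asarray(self.a, dtype=float)
        b = np.asarray(self.b, dtype=float)
        if a.shape != b.shape or a.ndim != 1:
            raise ValueError("a and b must be equal-length 1D arrays")
        ids = (np.asarray(self.subject_ids) if self.subject_ids is not None
               else np.arange(a.size))
        keep = np.isfinite(a) & np.isfinite(b)
        self.a, self.b, self.subject_ids = a[keep], b[keep], ids[keep]

    @property
    def n(self) -> int:
        return self.a.size


@dataclass
class RepeatabilityResult:
    """ICC, Bland–Altman and paired-t summary for one vessel/quantity."""

    icc: float
    icc_grade: str
    mean_diff: float
    sd_diff: float
    loa_low: float
    loa_high: float
    t_stat: float
    p_value: float
    mean_diff_pct: float
    sd_diff_pct: float
    n: int
    degenerate_t: bool = False


@dataclass
class ConformityResult:
    """Inter-method (4D − 2D) agreement summary."""

    mean_diff: float
    sd_diff: float
    loa_low: float
    loa_high: float
    pearson_r: float
    r_p_value: float
    t_stat: float
    t_p_value: float
    n: int


def _anova_mean_squares(pm: PairedMeasurements) -> tuple[float, float, float, int, int]:
    """Two-way (subject × session) ANOVA mean squares for k paired columns."""
    x = np.stack([pm.a, pm.b], axis=1)  # (n, k)
    n, k = x.shape
    if n < 3:
        raise ValueError("ICC needs at least 3 subjects")
    grand = x.mean()
    rowm = x.mean(axis=1)
    colm = x.mean(axis=0)
    ss_r = k * np.sum((rowm - grand) ** 2)
    ss_c = n * np.sum((colm - grand) ** 2)
    resid = x - rowm[:, None] - colm[None, :] + grand
    ss_e = np.sum(resid**2)
    ms_r = ss_r / (n - 1)
    ms_c = ss_c / (k - 1)
    ms_e = ss_e / ((n - 1) * (k - 1))
    return ms_r, ms_c, ms_e, n, k


def icc_absolute_agreement(pm: PairedMeasurements) -> float:
    """Two-way, absolute-agreement, single-measurement ICC(A,1).

    Returns NaN (reported missing) when the data carry no variance at all.
    """
    ms_r, ms_c, ms_e, n, k = _anova_mean_squares(pm)
    denom = ms_r + (k - 1) * ms_e + (k / n) * (ms_c - ms_e)
    if denom == 0.0:
        return float("nan")
    return float((ms_r - ms_e) / denom)


def icc_consistency(pm: PairedMeasurements) -> float:
    """Two-way consistency ICC(C,1): insensitive to a constant session shift."""
    ms_r, _, ms_e, _, k = _anova_mean_squares(pm)
    denom = ms_r + (k - 1) * ms_e
    if denom == 0.0:
        return float("nan")
    return float((ms_r - ms_e) / denom)


def grade_icc(icc: float) -> str:
    """Koo–Li interpretation bins: <0.5 poor, 0.5–0.75 moderate, 0.75–0.9
    good, >0.9 excellent.  Boundary convention: [0.5, 0.75) moderate,
    [0.75, 0.9] good, >0.9 excellent."""
    if not np.isfinite(icc):
        return "undefined"
    if icc < 0.5:
        return "poor"
    if icc < 0.75:
        return "moderate"
    if icc <= 0.9:
        return "good"
    return "excellent"


def bland_altman(pm: PairedMeasurements) -> dict:
    """Bland–Altman agreement of b against a.

    Differences are b − a; limits of agreement are mean ± 1.96·SD with the
    sample (n−1) SD.  Per-subject percentage differences are normalised by
    the first arm (session 1 / 2D), missing where a = 0.
    """
    if pm.n < 2:
        raise ValueError("Bland-Altman needs at least 2 pairs")
    diffs = pm.b - pm.a
    mean_diff = float(diffs.mean())
    sd_diff = float(diffs.std(ddof=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = np.where(pm.a != 0, 100.0 * diffs / pm.a, np.nan)
    pct_ok = pct[np.isfinite(pct)]
    return {
        "mean_diff": mean_diff,
        "sd_diff": sd_diff,
        "loa_low": mean_diff - 1.96 * sd_diff,
        "loa_high": mean_diff + 1.96 * sd_diff,
        "diffs": diffs,
        "means": (pm.a + pm.b) / 2.0,
        "pct_diffs": pct,
        "mean_diff_pct": float(pct_ok.mean()) if pct_ok.size else float("nan"),
        "sd_diff_pct": float(pct_ok.std(ddof=1)) if pct_ok.size > 1 else float("nan"),
    }


def paired_t(pm: PairedMeasurements) -> tuple[float, float, bool]:
    """Two-sided paired t-test on b − a.

    Returns ``(t, p, degenerate)``; a zero-variance difference vector is
    degenerate (t undefined) and flagged rather than reported as ±inf.
    """
    if pm.n < 2:
        raise ValueError("paired t needs at least 2 pairs")
    diffs = pm.b - pm.a
    if np.allclose(diffs.std(ddof=1), 0.0):
        return float("nan"), float("nan"), True
    res = stats.ttest_rel(pm.b, pm.a)
    return float(res.statistic), float(res.pvalue), False


def pearson(pm: PairedMeasurements) -> tuple[float, float]:
    """Pearson product-moment correlation with its two-sided t-based p-value.

    Returns (NaN, NaN) for constant input, where r is undefined.
    """
    if pm.n < 3:
        raise ValueError("Pearson correlation needs at least 3 pairs")
    if pm.a.std() == 0.0 or pm.b.std() == 0.0:
        return float("nan"), float("nan")
    res = stats.pearsonr(pm.a, pm.b)
    return float(res.statistic), float(res.pvalue)


def size_vs_error(areas, metric) -> tuple[float, float]:
    """Correlation between per-vessel lumen area and a repeatability metric
    (per-vessel ICC, or mean absolute between-session difference)."""
    areas = np.asarray(areas, dtype=float)
    metric = np.asarray(metric, dtype=float)
    keep = np.isfinite(areas) & np.isfinite(metric)
    if keep.sum() < 3:
        raise ValueError("need at least 3 vessels")
    return pearson(PairedMeasurements(a=areas[keep], b=metric[keep]))


def group_compare(group1, group2, label1: str = "group1", label2: str = "group2") -> pd.DataFrame:
    """Summary comparison of two groups of per-subject values.

    Reports means and SDs, a paired t-test on size-matched order-paired
    samples (skipped with a warning when sizes differ — pairing across
    distinct cohorts is statistically irregular and is reported alongside),
    and an independent-samples Welch t-test, both clearly labelled.
    """
    g1 = np.asarray(group1, dtype=float)
    g2 = np.asarray(group2, dtype=float)
    rows = []
    for label, g in ((label1, g1), (label2, g2)):
        rows.append({"group": label, "n": g.size, "mean": float(g.mean()),
                     "sd": float(g.std(ddof=1)) if g.size > 1 else float("nan")})
    summary = pd.DataFrame(rows)

    tests = []
    if g1.size == g2.size:
        t, p, degen = paired_t(PairedMeasurements(a=g1, b=g2))
        tests.append({"test": "paired_t", "stat": t, "p": p,
                      "note": "order-paired across groups" + (" (degenerate)" if degen else "")})
    else:
        warnings.warn("group sizes differ; paired t-test skipped")
    w = stats.ttest_ind(g2, g1, equal_var=False)
    tests.append({"test": "welch_t", "stat": float(w.statistic), "p": float(w.pvalue),
                  "note": "independent samples, unequal variances"})
    summary.attrs["tests"] = pd.DataFrame(tests)
    return summary


def significance_stars(p: float) -> str:
    """Conventional significance markers: * p<0.05, ** p<0.01, *** p<0.001."""
    if not np.isfinite(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def repeatability_result(pm: PairedMeasurements, *, consistency: bool = False) -> RepeatabilityResult:
    """Full test-retest summary for one vessel and quantity."""
    icc = icc_consistency(pm) if consistency else icc_absolute_agreement(pm)
    ba = bland_altman(pm)
    t, p, degen = paired_t(pm)
    return RepeatabilityResult(
        icc=icc, icc_grade=grade_icc(icc),
        mean_diff=ba["mean_diff"], sd_diff=ba["sd_diff"],
        loa_low=ba["loa_low"], loa_high=ba["loa_high"],
        t_stat=t, p_value=p,
        mean_diff_pct=ba["mean_diff_pct"], sd_diff_pct=ba["sd_diff_pct"],
        n=pm.n, degenerate_t=degen,
    )


def conformity_result(pm: PairedMeasurements) -> ConformityResult:
    """Inter-method (b − a, i.e. 4D − 2D) conformity summary."""
    ba = bland_altman(pm)
    r, rp = pearson(pm)
    t, tp, _ = paired_t(pm)
    return ConformityResult(
        mean_diff=ba["mean_diff"], sd_diff=ba["sd_diff"],
        loa_low=ba["loa_low"], loa_high=ba["loa_high"],
        pearson_r=r, r_p_value=rp, t_stat=t, t_p_value=tp, n=pm.n,
    )
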