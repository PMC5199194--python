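"""Cohort-level summaries and the statistical test battery.

Values are reported as mean +/- SEM.  Distributions are compared with the
two-sided Kolmogorov-Smirnov test (two-sample between age groups, or
one-sample against the Uniform(0, 90) null expected if the two eyes'
preferences were unrelated), within-cohort paired comparisons with the
paired t-test, and per-cell associations with Pearson correlation.
Asymptotic p-values are used for the K-S tests; no multiple-testing
correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence

import numpy as np
from scipy import stats as sps

from .protocol import CONTRA, CORTICAL, IPSI, THALAMIC, TOTAL
from .decompose import CellResult


@dataclass(frozen=True)
class SummaryStat:
    n: int
    mean: float
    sem: float  # NaN when n == 1


@dataclass(frozen=True)
class TestResult:
    name: str        # ks_two_sample | ks_vs_uniform | paired_t | pearson
    groups: str      # human-readable description of what was compared
    statistic: float
    p_value: float
    n: int


@dataclass
class CohortSummary:
    label: str
    metrics: Dict[str, SummaryStat] = field(default_factory=dict)
    n_cells: int = 0
    excluded: Dict[str, int] = field(default_factory=dict)


def summarize(values: Sequence[float]) -> SummaryStat:
    """n, mean and SEM (sample SD / sqrt(n)) of a metric sample."""
    arr = np.asarray([v for v in values], dtype=float)
    if arr.size == 0:
        raise ValueError("cannot summarize an empty sample")
    if arr.size == 1:
        return SummaryStat(n=1, mean=float(arr[0]), sem=float("nan"))
    sem = float(np.std(arr, ddof=1) / np.sqrt(arr.size))
    return SummaryStat(n=int(arr.size), mean=float(np.mean(arr)), sem=sem)


def ks_two_sample(a: Sequence[float], b: Sequence[float],
                  groups: str = "") -> TestResult:
    """Two-sided two-sample K-S test with asymptotic p-value."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    res = sps.ks_2samp(a, b, alternative="two-sided", method="asymp")
    return TestResult(name="ks_two_sample", groups=groups,
                      statistic=float(res.statistic),
                      p_value=float(min(res.pvalue, 1.0)),
                      n=int(a.size + b.size))


def ks_vs_uniform(deltas: Sequence[float], groups: str = "") -> TestResult:
    """One-sample K-S test of a delta-O sample against Uniform(0, 90)."""
    d = np.asarray(deltas, dtype=float)
    if d.size == 0:
        raise ValueError("empty sample")
    if np.any((d < 0) | (d > 90)):
        raise ValueError("delta-O values must lie in [0, 90]")
    res = sps.kstest(d, sps.uniform(loc=0, scale=90).cdf, method="asymp")
    return TestResult(name="ks_vs_uniform", groups=groups,
                      statistic=float(res.statistic),
                      p_value=float(min(res.pvalue, 1.0)), n=int(d.size))


def paired_t(a: Sequence[float], b: Sequence[float],
             groups: str = "") -> TestResult:
    """Two-sided paired t-test.

    When every pairwise difference is exactly zero the statistic is 0 and
    the p-value undefined (NaN).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size != b.size:
        raise ValueError("paired samples must have equal length")
    if a.size < 2:
        raise ValueError("paired t-test needs n >= 2")
    diff = a - b
    sd = np.std(diff, ddof=1)
    if sd == 0:
        return TestResult(name="paired_t", groups=groups, statistic=0.0,
                          p_value=float("nan"), n=int(a.size))
    t, p = sps.ttest_rel(a, b)
    return TestResult(name="paired_t", groups=groups, statistic=float(t),
                      p_value=float(p), n=int(a.size))


def pearson(a: Sequence[float], b: Sequence[float],
            groups: str = "") -> TestResult:
    """Pearson correlation with two-sided p from the t transform."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size != b.size:
        raise ValueError("samples must have equal length")
    if a.size < 3:
        raise ValueError("Pearson correlation needs n >= 3")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("zero variance in one of the samples")
    res = sps.pearsonr(a, b)
    return TestResult(name="pearson", groups=groups,
                      statistic=float(res.statistic),
                      p_value=float(res.pvalue), n=int(a.size))


def _paired_metric(results: Sequence[CellResult], getter_a, getter_b):
    """Listwise extraction of two per-cell metrics, dropping cells where
    either is undefined."""
    a, b, dropped = [], [], 0
    for r in results:
        va, vb = getter_a(r), getter_b(r)
        if va is None or vb is None:
            dropped += 1
            continue
        a.append(va)
        b.append(vb)
    return np.asarray(a), np.asarray(b), dropped


def _metric(results: Sequence[CellResult], getter):
    vals = [getter(r) for r in results]
    kept = [v for v in vals if v is not None]
    return np.asarray(kept, dtype=float), len(vals) - len(kept)


#: per-cell metric extractors used for cohort summaries
METRIC_GETTERS = {
    "delta_o_total": lambda r: r.delta_o.get(TOTAL),
    "delta_o_thalamic": lambda r: r.delta_o.get(THALAMIC),
    "delta_o_cortical": lambda r: r.delta_o.get(CORTICAL),
    "thal_total_diff_contra": lambda r: r.thal_total_diff.get(CONTRA),
    "thal_total_diff_ipsi": lambda r: r.thal_total_diff.get(IPSI),
    "thal_cort_diff_contra": lambda r: r.thal_cort_diff.get(CONTRA),
    "thal_cort_diff_ipsi": lambda r: r.thal_cort_diff.get(IPSI),
    "scale_factor_contra": lambda r: r.scale_factor.get(CONTRA),
    "scale_factor_ipsi": lambda r: r.scale_factor.get(IPSI),
    "ci_ratio_total": lambda r: r.ci_ratio_total,
    "ci_ratio_thalamic": lambda r: r.ci_ratio_thalamic,
}


def summarize_cohort(label: str,
                     results: Sequence[CellResult]) -> CohortSummary:
    """Mean +/- SEM of every defined per-cell metric in a cohort."""
    summary = CohortSummary(label=label, n_cells=len(results))
    for name, getter in METRIC_GETTERS.items():
        vals, dropped = _metric(results, getter)
        vals = vals[np.isfinite(vals)]
        if vals.size:
            summary.metrics[name] = summarize(vals)
        if dropped:
            summary.excluded[name] = dropped
    return summary


def compare_cohorts(young: Sequence[CellResult],
                    adult: Sequence[CellResult]
                    ) -> tuple[CohortSummary, CohortSummary,
                               List[TestResult]]:
    """The full test battery between and within the two age cohorts.

    Between groups: two-sample K-S on the inter-ocular differences of
    total and thalamic EPSCs.  Against the random-matching null: one-sample
    K-S of each delta-O sample vs Uniform(0, 90).  Within each cohort:
    paired t between total and thalamic delta-O, paired t between contra
    and ipsi thalamic-cortical differences, and Pearson correlation of
    thalamic vs total delta-O.  Cells with undefined preferences are
    excluded listwise per statistic; an empty battery (all cells excluded)
    is returned rather than raised.
    """
    if not young or not adult:
        raise ValueError("both cohorts must be nonempty")
    sy = summarize_cohort("young", young)
    sa = summarize_cohort("adult", adult)
    tests: List[TestResult] = []
    cohorts = {"young": young, "adult": adult}

    for metric in ("delta_o_total", "delta_o_thalamic"):
        g = METRIC_GETTERS[metric]
        vy, _ = _metric(young, g)
        va, _ = _metric(adult, g)
        if vy.size and va.size:
            tests.append(ks_two_sample(
                vy, va, groups=f"young vs adult {metric}"))
        for name, v in (("young", vy), ("adult", va)):
            if v.size:
                tests.append(ks_vs_uniform(
                    v, groups=f"{name} {metric} vs uniform(0,90)"))

    for name, res in cohorts.items():
        a, b, _ = _paired_metric(res, METRIC_GETTERS["delta_o_total"],
                                 METRIC_GETTERS["delta_o_thalamic"])
        if a.size >= 2:
            tests.append(paired_t(
                a, b, groups=f"{name} delta_o total vs thalamic"))
        if a.size >= 3 and np.std(a) > 0 and np.std(b) > 0:
            tests.append(pearson(
                b, a, groups=f"{name} delta_o thalamic vs total"))
        c, i, _ = _paired_metric(res,
                                 METRIC_GETTERS["thal_cort_diff_contra"],
                                 METRIC_GETTERS["thal_cort_diff_ipsi"])
        if c.size >= 2:
            tests.append(paired_t(
                c, i, groups=f"{name} thal-cort diff contra vs ipsi"))
    return sy, sa, tests
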