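"""Repeated-run statistics: run series, paired t-tests, effect sizes, OLS.

The evaluation protocol trains each model ten times with reshuffled
training data (fixed holdout test set), reports the mean (SD) of each
metric over runs, and compares models with dependent t-tests on the
per-run differences — two-tailed between trained models, one-tailed
(model > rule) against the rule-based comparator — Bonferroni-corrected
at the 0.05 family level.  Cohen's d for paired series is
mean(diff)/SD(diff) (``d_z``); a pooled-SD variant is available.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .metrics import METRIC_NAMES, MetricReport

__all__ = ["RunSeries", "ComparisonResult", "paired_t", "cohens_d",
           "token_limit_regression"]


@dataclass
class RunSeries:
    """Per-metric results of repeated runs of one model family."""

    family: str
    target: str
    runs: list[MetricReport]

    def values(self, metric: str) -> np.ndarray:
        if metric not in METRIC_NAMES:
            raise ValueError(f"unknown metric {metric!r}")
        return np.array([getattr(r, metric) for r in self.runs], dtype=float)

    def mean(self, metric: str) -> float:
        return float(self.values(metric).mean())

    def sd(self, metric: str) -> float:
        v = self.values(metric)
        return float(v.std(ddof=1)) if v.size > 1 else 0.0

    def summary_row(self) -> dict[str, str]:
        row = {"model": self.family}
        for m in METRIC_NAMES:
            row[m] = f"{self.mean(m):.3f} ({self.sd(m):.3f})"
        return row


@dataclass(frozen=True)
class ComparisonResult:
    """One paired t-test between two run series on one metric."""

    pair: tuple[str, str]
    metric: str
    t: float
    p: float
    tails: int
    bonferroni_m: int
    cohens_d: float

    @property
    def adjusted_alpha(self) -> float:
        return 0.05 / self.bonferroni_m

    @property
    def significant(self) -> bool:
        return self.p < self.adjusted_alpha


def cohens_d(diff: np.ndarray, pooled: tuple[np.ndarray, np.ndarray] | None = None
             ) -> float:
    """Paired effect size: mean(diff)/SD(diff); set ``pooled`` to the two
    series for the pooled-SD variant instead."""
    diff = np.asarray(diff, dtype=float)
    if pooled is not None:
        a, b = (np.asarray(x, dtype=float) for x in pooled)
        sd = math.sqrt(0.5 * (a.var(ddof=1) + b.var(ddof=1)))
    else:
        sd = diff.std(ddof=1)
    m = diff.mean()
    if sd == 0.0:
        return 0.0 if m == 0.0 else math.copysign(math.inf, m)
    return float(m / sd)


def paired_t(series_a: RunSeries, series_b: RunSeries, metric: str,
             tails: int = 2, m: int = 1,
             d_variant: str = "paired") -> ComparisonResult:
    """Dependent t-test of ``series_a`` vs ``series_b`` on one metric.

    ``tails=1`` tests the one-sided alternative mean(a) > mean(b), the
    direction used against the rule-based comparator.  ``m`` is the
    Bonferroni family size.  Zero-variance differences with nonzero mean
    report p below the representable minimum and d as signed infinity.
    """
    a, b = series_a.values(metric), series_b.values(metric)
    if a.size != b.size:
        raise ValueError("run series must have equal length for a paired test")
    if tails not in (1, 2):
        raise ValueError("tails must be 1 or 2")
    if m < 1:
        raise ValueError("bonferroni m must be >= 1")
    diff = a - b
    if diff.std(ddof=1) == 0.0:
        if diff.mean() == 0.0:
            t, p = 0.0, 1.0
        else:
            t = math.copysign(math.inf, diff.mean())
            p = 0.0 if (tails == 2 or diff.mean() > 0) else 1.0
            p = max(p, 0.0)
            if p == 0.0:
                p = np.nextafter(0.0, 1.0)  # below machine precision
    else:
        alternative = "two-sided" if tails == 2 else "greater"
        res = sps.ttest_rel(a, b, alternative=alternative)
        t, p = float(res.statistic), float(res.pvalue)
    d = cohens_d(diff, pooled=(a, b) if d_variant == "pooled" else None)
    return ComparisonResult(pair=(series_a.family, series_b.family),
                            metric=metric, t=t, p=p, tails=tails,
                            bonferroni_m=m, cohens_d=d)


def token_limit_regression(points) -> tuple[float, float, float]:
    """OLS of a performance metric on the max-token limit.

    ``points`` is a sequence of (max_tokens, metric) pairs; returns
    (slope, two-sided p for the slope, R^2).
    """
    pts = np.asarray(list(points), dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise ValueError("need at least 3 (max_tokens, value) points")
    x, y = pts[:, 0], pts[:, 1]
    if np.ptp(x) == 0:
        raise ValueError("token limit is constant; slope undefined")
    res = sps.linregress(x, y)
    r2 = float(res.rvalue ** 2) if np.ptp(y) > 0 else 0.0
    return float(res.slope), float(res.pvalue), r2
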