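"""Group comparison and cohort aggregation.

The two-sample comparison used throughout is the Mann-Whitney rank-sum
test, two-tailed.  For small samples (n_a + n_b <= 12, no ties) the p value
is exact, from the full permutation distribution of the U statistic; larger
or tied samples use the normal approximation with tie correction.  The
method actually used is reported on the result.

Cohort summaries follow the convention of pooled live-imaging studies:
fractions and means are computed per independent experiment first, then
averaged across experiments (mean ± SD over N experiments), while per-cell
values are retained for the rank tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import InsufficientDataError

__all__ = ["RankSumResult", "rank_sum_test", "CohortSummary", "summarize_cohort"]

EXACT_MAX_N = 12


@dataclass(frozen=True)
class RankSumResult:
    """U statistic (for the first group) and two-tailed p value."""

    u: float
    p: float
    method: str  # "exact" or "asymptotic"
    n_a: int
    n_b: int


def _u_distribution(n_a: int, n_b: int) -> np.ndarray:
    """Null counts of rank arrangements per U value (no ties), by the
    classical recurrence N(u; i, j) = N(u − j; i − 1, j) + N(u; i, j − 1)
    with N(u; 0, j) = N(u; i, 0) = [u == 0]."""
    m = n_a * n_b
    counts = np.zeros((n_a + 1, n_b + 1, m + 1), dtype=np.int64)
    counts[0, :, 0] = 1
    counts[:, 0, 0] = 1
    for i in range(1, n_a + 1):
        for j in range(1, n_b + 1):
            for u in range(i * j + 1):
                acc = counts[i, j - 1, u]
                if u >= j:
                    acc += counts[i - 1, j, u - j]
                counts[i, j, u] = acc
    return counts[n_a, n_b]


def _exact_two_tailed_p(u: float, n_a: int, n_b: int) -> float:
    """Exact two-tailed p: the null probability of a U at least as far from
    its mean n_a·n_b/2 as the observed one (sum of both tails)."""
    dist = _u_distribution(n_a, n_b)
    total = dist.sum()
    mean = n_a * n_b / 2.0
    dev = abs(u - mean)
    tail = dist[np.abs(np.arange(len(dist)) - mean) >= dev - 1e-12].sum()
    return float(min(1.0, tail / total))


def rank_sum_test(group_a: Sequence[float], group_b: Sequence[float]) -> RankSumResult:
    """Two-tailed Mann-Whitney rank-sum test.

    U counts pairs (a, b) with a > b plus half the tied pairs.  Exact
    enumeration is used when n_a + n_b <= 12 and there are no ties; the
    normal approximation with tie correction (and continuity correction)
    otherwise.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise InsufficientDataError("rank_sum_test needs non-empty groups")
    greater = (a[:, None] > b[None, :]).sum()
    ties = (a[:, None] == b[None, :]).sum()
    u = float(greater) + 0.5 * float(ties)
    has_ties = len(np.unique(np.concatenate([a, b]))) < a.size + b.size
    if a.size + b.size <= EXACT_MAX_N and not has_ties:
        p = _exact_two_tailed_p(u, a.size, b.size)
        method = "exact"
    else:
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        p = float(res.pvalue)
        method = "asymptotic"
    return RankSumResult(u=u, p=p, method=method, n_a=int(a.size), n_b=int(b.size))


@dataclass
class CohortSummary:
    """Per-condition summary across independent experiments.

    ``n_cells`` counts usable cells (metric present); ``n_experiments`` is
    N.  Fractions/means are first computed within each experiment, then
    summarised as mean ± SD across experiments; SD is ``None`` when N = 1.
    """

    condition: str
    n_cells: int
    n_experiments: int
    metric_means: dict = field(default_factory=dict)  # metric -> (mean, sd)
    fraction_asymmetric: tuple[float, float | None] | None = None
    fraction_misoriented: tuple[float, float | None] | None = None
    n_excluded: int = 0
    empty: bool = False

    def to_dict(self) -> dict:
        def pair(p):
            return None if p is None else {"mean": p[0], "sd": p[1]}

        return {
            "condition": self.condition,
            "n_cells": self.n_cells,
            "n_experiments": self.n_experiments,
            "n_excluded": self.n_excluded,
            "empty": self.empty,
            "fraction_asymmetric": pair(self.fraction_asymmetric),
            "fraction_misoriented": pair(self.fraction_misoriented),
            "metrics": {
                k: {"mean": v[0], "sd": v[1]} for k, v in self.metric_means.items()
            },
        }


def _across_experiments(per_exp: pd.Series) -> tuple[float, float | None]:
    mean = float(per_exp.mean())
    sd = float(per_exp.std(ddof=1)) if len(per_exp) > 1 else None
    return mean, sd


def summarize_cohort(
    table: pd.DataFrame,
    condition_col: str = "condition",
    experiment_col: str = "experiment",
    metric_cols: Sequence[str] = (),
    asymmetric_col: str | None = "asymmetric",
    misoriented_col: str | None = "misoriented",
) -> list[CohortSummary]:
    """Summarize a per-cell metrics table into per-condition summaries.

    Rows with a missing value for a metric are excluded from that metric
    and counted in ``n_excluded``.  Conditions with zero usable cells are
    returned flagged ``empty`` rather than dropped.
    """
    out: list[CohortSummary] = []
    for cond, sub in table.groupby(condition_col, sort=True):
        usable = sub.dropna(how="all", subset=list(metric_cols) or None)
        summary = CohortSummary(
            condition=str(cond),
            n_cells=int(len(usable)),
            n_experiments=int(sub[experiment_col].nunique()),
            n_excluded=int(len(sub) - len(usable)),
            empty=len(usable) == 0,
        )
        if summary.empty:
            out.append(summary)
            continue
        grouped = usable.groupby(experiment_col)
        for m in metric_cols:
            per_exp = grouped[m].mean().dropna()
            if len(per_exp):
                summary.metric_means[m] = _across_experiments(per_exp)
        for col, attr in (
            (asymmetric_col, "fraction_asymmetric"),
            (misoriented_col, "fraction_misoriented"),
        ):
            if col and col in usable.columns:
                flags = usable[col].dropna()
                if len(flags):
                    per_exp = (
                        usable.loc[flags.index]
                        .groupby(experiment_col)[col]
                        .mean()
                    )
                    setattr(summary, attr, _across_experiments(per_exp))
        out.append(summary)
    return out
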