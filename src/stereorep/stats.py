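"""Frequency tables over clone representatives and cohort statistics.

Implements the study's statistical toolkit: exact and Monte Carlo Fisher
tests on contingency tables, Kruskal-Wallis with Dunn/Bonferroni post-hoc
comparisons, and the Cochran-Mantel-Haenszel test on stratified 2x2
tables. Monte Carlo results are reproducible for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import gammaln
from statsmodels.stats.contingency_tables import StratifiedTable


@dataclass(frozen=True)
class TestResult:
    test_name: str
    p_value: float
    statistic: float | None = None
    mc_iterations: int | None = None
    seed: int | None = None
    comparison: tuple[str, str] | None = None

    def __post_init__(self):
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p_value out of [0, 1]: {self.p_value}")

    def to_dict(self) -> dict:
        return {
            "test_name": self.test_name,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "mc_iterations": self.mc_iterations,
            "seed": self.seed,
            "comparison": list(self.comparison) if self.comparison else None,
        }


def round_half_away(value: float | Decimal, decimals: int) -> float:
    """Round half away from zero at the given number of decimals."""
    q = Decimal(1).scaleb(-decimals)
    d = value if isinstance(value, Decimal) else Decimal(str(value))
    return float(d.quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class FrequencyReport:
    """Per-group counts and percentages of a common total."""

    grouping: str
    counts: Mapping[str, int]
    total: int
    decimals: int
    percentages: Mapping[str, float] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "group": list(self.counts),
                "count": list(self.counts.values()),
                "total": self.total,
                "percent": [self.percentages[k] for k in self.counts],
            }
        )


def frequency_table(
    counts: Mapping[str, int] | int,
    total: int,
    decimals: int = 2,
    grouping: str = "by_subset",
) -> FrequencyReport:
    """Counts as percentages of ``total``, rounded half away from zero.

    ``counts`` may be a single integer (reported under group ``"all"``) or
    a mapping of group label to count. Percentages are computed exactly on
    the integer ratio before rounding.
    """
    if total <= 0:
        raise ValueError("total must be a positive integer")
    if decimals < 0:
        raise ValueError("decimals must be >= 0")
    if isinstance(counts, int):
        counts = {"all": counts}
    for label, c in counts.items():
        if c < 0 or c > total:
            raise ValueError(f"count {c} for {label!r} out of [0, {total}]")
    percentages = {
        label: round_half_away(Decimal(c) * 100 / Decimal(total), decimals)
        for label, c in counts.items()
    }
    return FrequencyReport(
        grouping=grouping,
        counts=dict(counts),
        total=total,
        decimals=decimals,
        percentages=percentages,
    )


def _as_table(table) -> np.ndarray:
    arr = np.asarray(table, dtype=np.int64)
    if arr.ndim != 2:
        raise ValueError("contingency table must be 2-dimensional")
    if (arr < 0).any():
        raise ValueError("contingency table entries must be non-negative")
    return arr


def _check_margins(arr: np.ndarray) -> None:
    if (arr.sum(axis=1) == 0).any() or (arr.sum(axis=0) == 0).any():
        raise ValueError("degenerate table: a row or column margin is zero")


def fisher_exact_2x2(table) -> TestResult:
    """Two-sided Fisher exact test on a 2x2 table.

    The p-value sums, over all tables with the observed margins, the
    hypergeometric probabilities no larger than that of the observed table.
    """
    arr = _as_table(table)
    if arr.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got {arr.shape}")
    _check_margins(arr)
    statistic, p = sps.fisher_exact(arr, alternative="two-sided")
    return TestResult("fisher_exact", p_value=float(p), statistic=float(statistic))


def _log_table_prob(tables: np.ndarray) -> np.ndarray:
    """Log hypergeometric probability of r x c tables with fixed margins,
    up to the margin-dependent constant (identical across tables)."""
    return -gammaln(tables + 1.0).sum(axis=(-2, -1))


def fisher_exact_mc(
    table, iterations: int = 10_000, seed: int = 0
) -> TestResult:
    """Monte Carlo Fisher test on an r x c table.

    Tables with the observed margins are sampled (Patefield algorithm via
    :func:`scipy.stats.random_table`); the p estimate uses the add-one
    correction ``(1 + hits) / (1 + iterations)`` so it is never zero.
    """
    arr = _as_table(table)
    _check_margins(arr)
    if iterations < 1000:
        raise ValueError("iterations must be >= 1000")
    rng = np.random.default_rng(seed)
    dist = sps.random_table(arr.sum(axis=1), arr.sum(axis=0))
    sims = dist.rvs(iterations, random_state=rng)
    lp_obs = _log_table_prob(arr)
    lp_sim = _log_table_prob(sims)
    hits = int((lp_sim <= lp_obs + 1e-9).sum())
    p = (1 + hits) / (1 + iterations)
    return TestResult(
        "fisher_mc", p_value=p, statistic=None,
        mc_iterations=iterations, seed=seed,
    )


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> TestResult:
    """Kruskal-Wallis H test with tie correction; chi-square p with
    k - 1 degrees of freedom. Identical observations across all groups
    give H = 0, p = 1."""
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(g) == 0 for g in groups):
        raise ValueError("all groups must be non-empty")
    pooled = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    if np.all(pooled == pooled[0]):
        return TestResult("kruskal_wallis", p_value=1.0, statistic=0.0)
    h, p = sps.kruskal(*groups)
    return TestResult("kruskal_wallis", p_value=float(p), statistic=float(h))


def dunn_bonferroni(
    groups: Sequence[Sequence[float]],
    labels: Sequence[str] | None = None,
) -> list[TestResult]:
    """Dunn's pairwise post-hoc comparisons on mean ranks with tie
    correction; two-sided normal p-values multiplied by the number of
    comparisons (Bonferroni), capped at 1."""
    k = len(groups)
    if k < 3:
        raise ValueError("need at least 3 groups")
    if any(len(g) == 0 for g in groups):
        raise ValueError("all groups must be non-empty")
    labels = list(labels) if labels is not None else [str(i) for i in range(k)]
    sizes = np.array([len(g) for g in groups])
    pooled = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    n = len(pooled)
    ranks = sps.rankdata(pooled)
    bounds = np.concatenate([[0], np.cumsum(sizes)])
    mean_ranks = np.array(
        [ranks[bounds[i] : bounds[i + 1]].mean() for i in range(k)]
    )
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (12.0 * (n - 1))
    var_base = n * (n + 1) / 12.0 - tie_term
    m = k * (k - 1) // 2
    results: list[TestResult] = []
    for i in range(k):
        for j in range(i + 1, k):
            se = np.sqrt(var_base * (1.0 / sizes[i] + 1.0 / sizes[j]))
            z = 0.0 if se == 0 else (mean_ranks[i] - mean_ranks[j]) / se
            p = min(1.0, 2.0 * sps.norm.sf(abs(z)) * m)
            results.append(
                TestResult(
                    "dunn_bonferroni", p_value=float(p), statistic=float(z),
                    comparison=(labels[i], labels[j]),
                )
            )
    return results


def cmh_test(
    strata: Sequence, continuity_correction: bool = False
) -> TestResult:
    """Cochran-Mantel-Haenszel chi-square test on stratified 2x2 tables
    (1 df; continuity correction off by default)."""
    tables = [_as_table(s) for s in strata]
    if not tables:
        raise ValueError("need at least one stratum")
    if any(t.shape != (2, 2) for t in tables):
        raise ValueError("every stratum must be a 2x2 table")
    pooled = np.sum(tables, axis=0)
    _check_margins(pooled)
    informative = [
        t for t in tables
        if not ((t.sum(axis=1) == 0).any() or (t.sum(axis=0) == 0).any())
    ]
    if not informative:
        raise ValueError("all strata degenerate")
    st = StratifiedTable(np.stack(informative, axis=-1).astype(float))
    res = st.test_null_odds(correction=continuity_correction)
    return TestResult(
        "cmh", p_value=float(res.pvalue), statistic=float(res.statistic)
    )


def compare_subset_distributions(
    cohort_a_counts: Mapping[str, int],
    cohort_b_counts: Mapping[str, int],
    iterations: int = 100_000,
    seed: int = 0,
) -> TestResult:
    """Monte Carlo Fisher test on the subsets x cohorts table built from
    two per-subset count vectors over the same subset labels."""
    if set(cohort_a_counts) != set(cohort_b_counts):
        raise ValueError("cohorts must cover the same subset labels")
    labels = sorted(cohort_a_counts)
    table = np.array(
        [[cohort_a_counts[s], cohort_b_counts[s]] for s in labels],
        dtype=np.int64,
    )
    keep = table.sum(axis=1) > 0
    table = table[keep]
    return fisher_exact_mc(table, iterations=iterations, seed=seed)
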