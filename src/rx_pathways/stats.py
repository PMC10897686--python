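"""Pearson chi-square (1 d.f.) and Wilcoxon rank-sum with continuity correction.

Both tests are implemented directly from their definitions — the Pearson
statistic on a 2x2 table, and the Mann-Whitney/Wilcoxon statistic with
midranks for ties, tie-corrected variance and a 0.5 continuity
correction under the normal approximation. Only the reference
distributions (chi-square, normal) come from scipy.
"""

from __future__ import annotations

import dataclasses
from itertools import combinations
from math import comb

import numpy as np
from scipy import stats as _sps


@dataclasses.dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str
    detail: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self):
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")


def chi_square_df1(table, yates: bool = False) -> TestResult:
    """Pearson chi-square test of independence on a 2x2 table.

    ``table`` is ``[[a, b], [c, d]]`` (group x outcome). The statistic is
    ``sum((O - E)^2 / E)`` with expected counts from the margins; the
    p-value comes from the chi-square distribution with 1 d.f. Yates'
    continuity correction (``(|O - E| - 0.5)^2 / E``) is off by default.
    A zero row or column margin makes the table degenerate.
    """
    obs = np.asarray(table, dtype=float)
    if obs.shape != (2, 2):
        raise ValueError("chi_square_df1 requires a 2x2 table")
    if (obs < 0).any():
        raise ValueError("counts must be nonnegative")
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    total = obs.sum()
    if total <= 0 or (row == 0).any() or (col == 0).any():
        raise ValueError("degenerate table: a zero marginal")
    expected = np.outer(row, col) / total
    dev = np.abs(obs - expected)
    if yates:
        dev = np.maximum(dev - 0.5, 0.0)
    statistic = float((dev**2 / expected).sum())
    p = float(_sps.chi2.sf(statistic, df=1))
    return TestResult(
        statistic=statistic,
        p_value=p,
        method="Pearson chi-square (1 d.f.)" + (" with Yates correction" if yates else ""),
        detail={"df": 1, "expected": expected.tolist()},
    )


def _midranks(pooled: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Midranks of the pooled sample and the tie-group sizes."""
    order = np.argsort(pooled, kind="stable")
    ranks = np.empty(len(pooled), dtype=float)
    tie_sizes = []
    i = 0
    sorted_vals = pooled[order]
    while i < len(pooled):
        j = i
        while j + 1 < len(pooled) and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        midrank = (i + j) / 2 + 1
        ranks[order[i : j + 1]] = midrank
        tie_sizes.append(j - i + 1)
        i = j + 1
    return ranks, np.asarray(tie_sizes, dtype=float)


def wilcoxon_rank_sum_cc(x, y) -> TestResult:
    """Two-sided Wilcoxon rank-sum test, normal approximation with
    continuity correction and tie-corrected variance.

    The reported statistic is the Mann-Whitney U for the first sample
    (number of (x, y) pairs with x > y, ties counting half), computed
    from the midrank sum. The z-score shrinks ``U - n1*n2/2`` by 0.5
    towards zero before dividing by the tie-corrected null s.d.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks, ties = _midranks(pooled)
    rank_sum_x = float(ranks[:n1].sum())
    u = rank_sum_x - n1 * (n1 + 1) / 2
    mean_u = n1 * n2 / 2
    n = n1 + n2
    tie_term = float(((ties**3 - ties).sum())) / (n * (n - 1)) if n > 1 else 0.0
    var_u = n1 * n2 / 12 * ((n + 1) - tie_term)
    if var_u <= 0:
        # all pooled values identical: no evidence either way
        return TestResult(
            statistic=u,
            p_value=1.0,
            method="Wilcoxon rank-sum with continuity correction",
            detail={"n1": n1, "n2": n2, "z": 0.0},
        )
    centred = u - mean_u
    correction = 0.5 * np.sign(centred)
    z = (centred - correction) / np.sqrt(var_u)
    p = float(min(1.0, 2.0 * _sps.norm.sf(abs(z))))
    return TestResult(
        statistic=u,
        p_value=p,
        method="Wilcoxon rank-sum with continuity correction",
        detail={"n1": n1, "n2": n2, "z": float(z)},
    )


def wilcoxon_rank_sum_exact(x, y) -> TestResult:
    """Exact two-sided rank-sum p-value by enumerating every assignment of
    pooled ranks to the first sample. Intended for small samples (at most
    ~10 per group) as an independent check on the approximation; ties are
    handled by enumerating midrank subsets."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    n1, n2 = x.size, y.size
    if comb(n1 + n2, n1) > 2_000_000:
        raise ValueError("samples too large for exact enumeration")
    pooled = np.concatenate([x, y])
    ranks, _ = _midranks(pooled)
    rank_sum_x = float(ranks[:n1].sum())
    u_obs = rank_sum_x - n1 * (n1 + 1) / 2
    mean_u = n1 * n2 / 2
    observed_dev = abs(u_obs - mean_u)
    count = 0
    total = 0
    for subset in combinations(range(n1 + n2), n1):
        u = float(ranks[list(subset)].sum()) - n1 * (n1 + 1) / 2
        total += 1
        if abs(u - mean_u) >= observed_dev - 1e-12:
            count += 1
    return TestResult(
        statistic=u_obs,
        p_value=count / total,
        method="Wilcoxon rank-sum, exact enumeration",
        detail={"n1": n1, "n2": n2},
    )


def compare_groups(
    metrics, classes, measure: str, group_a: str, group_b: str
) -> TestResult:
    """Compare a per-patient measure between two classification groups.

    Binary measures (0/1 or boolean) go through the chi-square test on
    the 2x2 group-by-outcome table; other numeric measures through the
    Wilcoxon rank-sum test.
    """
    from .metrics import _group_masks

    merged = metrics.merge(classes, on="patient_id", validate="one_to_one")
    masks = _group_masks(merged)
    for name in (group_a, group_b):
        if name not in masks:
            raise ValueError(f"unknown group {name!r}; expected one of {sorted(masks)}")
    a = merged.loc[masks[group_a], measure].dropna()
    b = merged.loc[masks[group_b], measure].dropna()
    values = merged[measure].dropna().unique()
    if set(np.unique(values.astype(float))) <= {0.0, 1.0}:
        table = [
            [int(a.astype(float).sum()), int((1 - a.astype(float)).sum())],
            [int(b.astype(float).sum()), int((1 - b.astype(float)).sum())],
        ]
        return chi_square_df1(table)
    return wilcoxon_rank_sum_cc(a.astype(float), b.astype(float))
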