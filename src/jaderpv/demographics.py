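"""Patient-background comparison between event and non-event reports.

Continuous variables (age, height, weight, BMI) are compared with the
Wilcoxon rank-sum test (mid-ranks for ties, tie-corrected variance, normal
approximation with continuity correction; exact enumeration for small
samples). Sex is compared with Fisher's exact test. Each variable is
analysed on its complete cases, so group sizes differ per variable.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

from .contingency import ContingencyTable, fisher_exact
from .errors import UndefinedTestError

CONTINUOUS_VARIABLES = ("age_years", "height_cm", "weight_kg", "bmi")


def rank_sum_test(x, y, exact_max_n: int = 20) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    For combined sample size <= `exact_max_n` the null distribution of the
    rank sum is enumerated exactly over all group assignments (mid-ranks
    kept, two-sided by doubling the smaller tail). Otherwise the normal
    approximation with tie-corrected variance and a 0.5 continuity
    correction is used.
    """
    x = np.asarray([v for v in np.ravel(x) if not np.isnan(v)], dtype=float)
    y = np.asarray([v for v in np.ravel(y) if not np.isnan(v)], dtype=float)
    nx, ny = len(x), len(y)
    if nx == 0 or ny == 0:
        raise UndefinedTestError("rank-sum test needs both groups non-empty")
    n = nx + ny
    ranks = stats.rankdata(np.concatenate([x, y]))  # mid-ranks
    w = float(ranks[:nx].sum())

    if n <= exact_max_n:
        # exact null: every nx-subset of the pooled mid-ranks is equally likely
        total = comb(n, nx)
        count_le = count_ge = 0
        for idx in combinations(range(n), nx):
            s = ranks[list(idx)].sum()
            if s <= w + 1e-9:
                count_le += 1
            if s >= w - 1e-9:
                count_ge += 1
        p = 2.0 * min(count_le, count_ge) / total
        return float(min(p, 1.0))

    mu = nx * (n + 1) / 2.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    tie_term = float(np.sum(tie_counts ** 3 - tie_counts)) / (n * (n - 1))
    var = nx * ny / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return 1.0
    z = max(0.0, abs(w - mu) - 0.5) / np.sqrt(var)
    return float(2.0 * stats.norm.sf(z))


def sex_association_test(ct: ContingencyTable) -> float:
    """Fisher's exact p for a 2x2 sex-by-outcome table."""
    return fisher_exact(ct)


@dataclass
class GroupSummary:
    """Per-variable comparison between event and non-event reports."""

    variable: str
    n_event: int
    mean_event: float
    sd_event: float
    n_other: int
    mean_other: float
    sd_other: float
    test: str
    p_value: float
    available: bool = True


def _moments(v: np.ndarray) -> tuple[int, float, float]:
    v = v[~np.isnan(v)]
    if len(v) == 0:
        return 0, np.nan, np.nan
    sd = float(np.std(v, ddof=1)) if len(v) > 1 else np.nan
    return len(v), float(np.mean(v)), sd


def summarize_groups(cases: pd.DataFrame, outcome_terms) -> list[GroupSummary]:
    """Table-1-style comparison of demographics by event status.

    The event group contains cases whose reported terms intersect
    `outcome_terms`; each variable is summarised on its complete cases
    (n, mean, SD with the n-1 denominator) and tested with the rank-sum
    test; sex uses Fisher's exact test on the male/female counts.
    """
    terms = frozenset([outcome_terms] if isinstance(outcome_terms, str)
                      else outcome_terms)
    is_event = np.fromiter((bool(terms & s) for s in cases["events"]),
                           dtype=bool, count=len(cases))
    out: list[GroupSummary] = []

    sexed = cases["sex"].isin(["male", "female"]).to_numpy()
    female = (cases["sex"] == "female").to_numpy()
    a = int(np.sum(sexed & is_event & female))
    b = int(np.sum(sexed & is_event & ~female))
    c = int(np.sum(sexed & ~is_event & female))
    d = int(np.sum(sexed & ~is_event & ~female))
    if min(a + b, c + d) > 0:
        p_sex = sex_association_test(ContingencyTable(a, b, c, d))
    else:
        p_sex = np.nan
    out.append(GroupSummary(
        variable="female", n_event=a + b, mean_event=a / (a + b) if a + b else np.nan,
        sd_event=np.nan, n_other=c + d,
        mean_other=c / (c + d) if c + d else np.nan, sd_other=np.nan,
        test="fisher_exact", p_value=p_sex,
        available=bool(min(a + b, c + d) > 0)))

    for var in CONTINUOUS_VARIABLES:
        v = cases[var].to_numpy(dtype=float)
        xe, xo = v[is_event], v[~is_event]
        ne, me, se_ = _moments(xe)
        no, mo, so = _moments(xo)
        if ne > 0 and no > 0:
            p = rank_sum_test(xe, xo)
            avail = True
        else:
            p, avail = np.nan, False
        out.append(GroupSummary(var, ne, me, se_, no, mo, so,
                                "rank_sum", p, avail))
    return out


def summary_frame(summaries: list[GroupSummary]) -> pd.DataFrame:
    return pd.DataFrame([s.__dict__ for s in summaries])
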