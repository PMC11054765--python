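"""Group comparisons and feasibility accounting for small clinical cohorts.

The statistical layer mirrors standard practice for pilot cohorts of this
size: Mann-Whitney U with the effect size r = |z| / sqrt(n) for non-normal
continuous variables, pooled-variance Student's t for normal ones, Pearson
chi-square (no continuity correction) for categorical tables, and medians
with [p25; p75] using the (n+1)-weighted quantile convention (SPSS
"HAVERAGE", numpy method "weibull").
"""
from __future__ import annotations

import itertools
import math
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DegenerateTableError, InputError

__all__ = [
    "MannWhitneyResult", "mann_whitney_with_effect", "mann_whitney_exact_p",
    "effect_size_label", "pearson_chi_square", "two_sample_t", "median_iqr",
    "FEASIBILITY_STATUSES", "FeasibilityRecord", "feasibility_tally",
    "GroupComparison", "compare_groups",
]


@dataclass
class MannWhitneyResult:
    u: float           # U statistic of the first group
    z: float           # tie-corrected normal-approximation z-score
    p: float           # two-tailed
    r: float           # effect size |z| / sqrt(nA + nB)
    n: int

    @property
    def label(self) -> str:
        return effect_size_label(self.r)


def mann_whitney_with_effect(group_a, group_b,
                             continuity: bool = True) -> MannWhitneyResult:
    """Mann-Whitney U with z, two-tailed p and the effect size r = |z|/sqrt(n).

    z comes from the tie-corrected normal approximation; the continuity
    correction (on by default, following R's ``wilcox.test``) subtracts 0.5
    from |U - mu| before standardising, which keeps the approximation close
    to the exact null distribution down to groups of five.  Below that the
    discreteness of U makes any continuous approximation coarse -- use
    :func:`mann_whitney_exact_p` there.  When every observation is identical
    across both groups the variance vanishes and (z=0, p=1, r=0) is
    returned.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise InputError("both groups must be non-empty")
    na, nb = a.size, b.size
    n = na + nb
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    u1 = ranks[:na].sum() - na * (na + 1) / 2.0
    mu = na * nb / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts ** 3 - tie_counts).sum()) / (n * (n - 1)))
    var = na * nb / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return MannWhitneyResult(u=float(u1), z=0.0, p=1.0, r=0.0, n=n)
    d = abs(u1 - mu)
    if continuity:
        d = max(0.0, d - 0.5)
    z = math.copysign(d, u1 - mu) / math.sqrt(var)
    p = 2.0 * sps.norm.sf(abs(z))
    return MannWhitneyResult(u=float(u1), z=float(z),
                             p=float(min(p, 1.0)), r=abs(z) / math.sqrt(n), n=n)


def mann_whitney_exact_p(group_a, group_b) -> float:
    """Exact two-tailed p by full enumeration of group assignments.

    Permutation-exact for tie-free data; intended for n_a + n_b <= 12 or so
    (the enumeration is combinatorial).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    na = a.size
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    obs = ranks[:na].sum() - na * (na + 1) / 2.0
    mu = na * b.size / 2.0
    count = 0
    total = 0
    for combo in itertools.combinations(range(pooled.size), na):
        u = ranks[list(combo)].sum() - na * (na + 1) / 2.0
        if abs(u - mu) >= abs(obs - mu) - 1e-12:
            count += 1
        total += 1
    return count / total


def effect_size_label(r: float) -> str:
    """Band an effect size r into none/small/moderate/large.

    Half-open bands: [0, 0.1) none, [0.1, 0.3) small, [0.3, 0.5) moderate,
    [0.5, inf) large.
    """
    if r < 0:
        raise InputError("effect size r must be non-negative")
    if r < 0.1:
        return "none"
    if r < 0.3:
        return "small"
    if r < 0.5:
        return "moderate"
    return "large"


def pearson_chi_square(table) -> tuple[float, int, float]:
    """Pearson chi-square on a contingency table, Yates correction off.

    All-zero rows and columns (empty categories) are dropped before computing
    expected counts and degrees of freedom; a table that then collapses to a
    single row or column has no association to test.
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2:
        raise InputError("contingency table must be 2-D")
    if np.any(t < 0) or np.any(t != np.floor(t)):
        raise InputError("contingency table must hold non-negative integers")
    t = t[t.sum(axis=1) > 0][:, t.sum(axis=0) > 0]
    if t.shape[0] < 2 or t.shape[1] < 2:
        raise DegenerateTableError(
            f"table reduced to shape {t.shape}; association undefined"
        )
    chi2, p, df, _ = sps.chi2_contingency(t, correction=False)
    return float(chi2), int(df), float(p)


def two_sample_t(group_a, group_b) -> tuple[float, float]:
    """Pooled-variance two-sample t-test, two-tailed."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InputError("each group needs n >= 2")
    if np.ptp(a) == 0 and np.ptp(b) == 0 and a[0] == b[0]:
        return 0.0, 1.0
    t, p = sps.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)


def median_iqr(values, method: str = "weibull") -> tuple[float, float, float]:
    """Median and quartiles under a configurable quantile convention.

    Default "weibull" is the (n+1)-based weighted interpolation (SPSS
    HAVERAGE): for {1,2,3,4} it gives p25 = 1.25 and p75 = 3.75.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise InputError("median_iqr needs at least one value")
    q25, q50, q75 = np.quantile(arr, [0.25, 0.5, 0.75], method=method)
    return float(q50), float(q25), float(q75)


FEASIBILITY_STATUSES = (
    "complete",       # all factors for the stage measured and valid
    "non_adherent",   # participant did not follow the measurement protocol
    "technical",      # equipment/software failure or researcher error
    "combination",    # non-adherence plus a technical issue
    "refusal",        # declined the (follow-up) measurement
    "dropout",        # left the study for another reason
)


@dataclass(frozen=True)
class FeasibilityRecord:
    participant_id: str
    stage: str     # e.g. "baseline", "week4", "week8"
    status: str    # one of FEASIBILITY_STATUSES

    def __post_init__(self):
        if self.status not in FEASIBILITY_STATUSES:
            raise InputError(f"unknown feasibility status {self.status!r}")


def feasibility_tally(records) -> pd.DataFrame:
    """Counts and percentages per stage x status.

    The percentage denominator is the number of enrolled participants with a
    record at that stage, so each stage's percentages sum to 100.
    """
    records = list(records)
    if not records:
        raise InputError("no feasibility records")
    rows = []
    by_stage: dict[str, Counter] = {}
    for rec in records:
        if rec.status not in FEASIBILITY_STATUSES:
            raise InputError(f"unknown feasibility status {rec.status!r}")
        by_stage.setdefault(rec.stage, Counter())[rec.status] += 1
    for stage, counter in by_stage.items():
        n = sum(counter.values())
        for status in FEASIBILITY_STATUSES:
            c = counter.get(status, 0)
            rows.append({"stage": stage, "status": status, "count": c,
                         "n_enrolled": n, "percent": 100.0 * c / n})
    return pd.DataFrame(rows)


@dataclass
class GroupComparison:
    """One row of a healed-vs-non-healed style comparison table."""

    variable: str
    test: str                      # mann_whitney | t | chi_square
    n_a: int
    n_b: int
    median_a: tuple | None = None  # (median, p25, p75)
    median_b: tuple | None = None
    statistic: float | None = None
    z: float | None = None
    p: float | None = None
    effect_size_r: float | None = None
    effect_label: str | None = None

    def as_row(self) -> dict:
        def fmt(m):
            return None if m is None else f"{m[0]:.1f} [{m[1]:.1f}; {m[2]:.1f}]"
        return {
            "variable": self.variable, "test": self.test,
            "group_a": fmt(self.median_a), "group_b": fmt(self.median_b),
            "n_a": self.n_a, "n_b": self.n_b,
            "statistic": self.statistic, "z": self.z, "p": self.p,
            "r": self.effect_size_r, "effect": self.effect_label,
        }


def compare_groups(variable: str, group_a, group_b,
                   test: str = "mann_whitney") -> GroupComparison:
    """Compare one continuous variable between two groups.

    Values may contain NaN (missing participants); they are dropped per
    group, matching the per-variable n bookkeeping of small-cohort tables.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if a.size == 0 or b.size == 0:
        return GroupComparison(variable=variable, test=test,
                               n_a=int(a.size), n_b=int(b.size),
                               median_a=median_iqr(a) if a.size else None,
                               median_b=median_iqr(b) if b.size else None)
    if test == "mann_whitney":
        res = mann_whitney_with_effect(a, b)
        return GroupComparison(
            variable=variable, test=test, n_a=a.size, n_b=b.size,
            median_a=median_iqr(a), median_b=median_iqr(b),
            statistic=res.u, z=res.z, p=res.p,
            effect_size_r=res.r, effect_label=res.label)
    if test == "t":
        t, p = two_sample_t(a, b)
        return GroupComparison(
            variable=variable, test=test, n_a=a.size, n_b=b.size,
            median_a=median_iqr(a), median_b=median_iqr(b),
            statistic=t, p=p)
    raise InputError(f"unknown test {test!r}")
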