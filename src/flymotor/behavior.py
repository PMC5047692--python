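"""Behavioral indices and group statistics.

Implements the flight index (FI), climbing index (CI), control
normalization, and the group statistics used throughout the study:
mean ± s.e.m. summaries and the two-tailed Student's t-test.

The experimental unit for both behavioral assays is the *test* (a group of
six flies assayed together), not the individual fly: FI is the mean over
tests of the per-test mean adhesion height, and group comparisons are
performed on per-test means, so n equals the number of independent groups.

Cohort tables are tidy :class:`pandas.DataFrame` objects with columns
``condition``, ``test_id``, ``fly_id`` (flight) or ``repeat_id`` (climbing)
and ``value``; plain lists of per-test value lists are accepted everywhere a
cohort is.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ParameterError

MAX_FLIGHT_HEIGHT_CM = 17  # 19 cm cylinder with the zero line 2 cm above the bottom


@dataclass(frozen=True)
class GroupSummary:
    """mean ± s.e.m. of one index over n experimental units."""

    mean: float
    sem: float
    n: int
    index_name: str = ""

    def as_dict(self) -> dict:
        return {"mean": self.mean, "sem": self.sem, "n": self.n,
                "index_name": self.index_name}


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float
    significant: bool
    alpha: float = 0.05

    def as_dict(self) -> dict:
        return {"t": self.t, "df": self.df, "p": self.p,
                "significant": self.significant, "alpha": self.alpha}


@dataclass(frozen=True)
class NormalizedIndex:
    """Ratio of a treated index to its control, with delta-method s.e.m."""

    ratio: float
    sem: float

    @property
    def percent(self) -> float:
        return 100.0 * self.ratio


def _per_test_values(tests, id_col: str = "test_id",
                     value_col: str = "value") -> list[np.ndarray]:
    """Normalize a cohort (DataFrame or list of per-test sequences)."""
    if isinstance(tests, pd.DataFrame):
        if id_col not in tests.columns or value_col not in tests.columns:
            raise ParameterError(
                f"cohort table must have columns {id_col!r} and {value_col!r}"
            )
        return [np.asarray(g[value_col], dtype=float)
                for _, g in tests.groupby(id_col, sort=True)]
    return [np.asarray(t, dtype=float) for t in tests]


def summarize(values: Sequence[float], index_name: str = "") -> GroupSummary:
    """mean and s.e.m. (sd/sqrt(n), ddof=1) of a sample."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ParameterError("cannot summarize an empty sample")
    sem = float(np.std(arr, ddof=1) / math.sqrt(arr.size)) if arr.size > 1 else 0.0
    return GroupSummary(mean=float(arr.mean()), sem=sem, n=int(arr.size),
                        index_name=index_name)


def per_test_means(tests, id_col: str = "test_id",
                   value_col: str = "value") -> np.ndarray:
    """Mean value of each test; the experimental unit for group statistics."""
    groups = _per_test_values(tests, id_col, value_col)
    if len(groups) == 0:
        raise ParameterError("cohort contains no tests")
    for g in groups:
        if g.size == 0:
            raise ParameterError("every test must contain at least one value")
    return np.array([g.mean() for g in groups])


def flight_index(tests, max_height_cm: float = MAX_FLIGHT_HEIGHT_CM) -> GroupSummary:
    """Flight index: mean over tests of the per-test mean adhesion height.

    Heights are recorded to the closest integer in [0, max_height_cm]
    (non-fliers drop to the oiled bottom and score 0).  The returned summary
    carries the FI as ``mean``, the s.e.m. across tests, and ``n`` = number
    of tests (independent groups of flies).
    """
    groups = _per_test_values(tests, value_col="value")
    if len(groups) == 0:
        raise ParameterError("flight cohort contains no tests")
    for g in groups:
        if g.size == 0:
            raise ParameterError("every flight test must contain at least one fly")
        if np.any(g < 0) or np.any(g > max_height_cm):
            raise ParameterError(
                f"heights must lie in [0, {max_height_cm}] cm")
        if not np.allclose(g, np.round(g)):
            raise ParameterError("heights must be integers (recorded to the "
                                 "closest centimetre)")
    means = np.array([g.mean() for g in groups])
    return summarize(means, index_name="FI")


def climbing_index(tests) -> GroupSummary:
    """Climbing index: inverse of the grand-mean climb time (units 1/s).

    Each test's repeat times (default three repeats) are averaged, the
    per-test means are averaged across tests, and CI is the inverse of that
    grand mean, so larger values represent faster climbing.  The s.e.m. is
    propagated to the inverse by the delta method: sem(CI) = sem(T)/T².
    """
    groups = _per_test_values(tests, value_col="value")
    if len(groups) == 0:
        raise ParameterError("climbing cohort contains no tests")
    for g in groups:
        if g.size == 0:
            raise ParameterError("every climbing test must contain at least one repeat")
        if np.any(g <= 0):
            raise ParameterError("climb times must be strictly positive")
    means = np.array([g.mean() for g in groups])
    grand = summarize(means, index_name="mean_time_s")
    ci = 1.0 / grand.mean
    sem_ci = grand.sem / grand.mean**2
    return GroupSummary(mean=ci, sem=sem_ci, n=grand.n, index_name="CI")


def normalize_index(treated: GroupSummary, control: GroupSummary) -> NormalizedIndex:
    """Normalize a treated-group index to its control (ratio of means).

    Uncertainty is propagated by the first-order delta method for a ratio of
    independent means: var(r) ≈ (sem_t/c)² + (t·sem_c/c²)².
    """
    if control.mean == 0:
        raise ParameterError("control index is 0; cannot normalize")
    ratio = treated.mean / control.mean
    var = (treated.sem / control.mean) ** 2 \
        + (treated.mean * control.sem / control.mean**2) ** 2
    return NormalizedIndex(ratio=ratio, sem=math.sqrt(var))


# kept as the named operation for the flight assay
normalize_fi = normalize_index


def two_sample_ttest(group_a, group_b, *, alpha: float = 0.05,
                     equal_var: bool = True) -> TTestResult:
    """Two-tailed two-sample t-test on independent groups.

    The default is the classic pooled-variance Student's test:
    t = (m_a − m_b) / sqrt(s_p²(1/n_a + 1/n_b)), df = n_a + n_b − 2, with
    s_p² the pooled variance; ``equal_var=False`` switches to Welch's test
    with Satterthwaite degrees of freedom.  Significance is flagged at the
    configurable two-sided level ``alpha`` (default 0.05).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ParameterError("each group needs at least 2 values for a t-test")
    ma, mb = a.mean(), b.mean()
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if equal_var:
        df = a.size + b.size - 2.0
        sp2 = ((a.size - 1) * va + (b.size - 1) * vb) / df
        denom2 = sp2 * (1.0 / a.size + 1.0 / b.size)
    else:
        sa2, sb2 = va / a.size, vb / b.size
        denom2 = sa2 + sb2
        if denom2 > 0:
            df = denom2**2 / (sa2**2 / (a.size - 1) + sb2**2 / (b.size - 1))
        else:
            df = a.size + b.size - 2.0
    if denom2 == 0.0:
        # degenerate: zero variance in both groups
        if ma == mb:
            t, p = 0.0, 1.0
        else:
            t, p = math.copysign(math.inf, ma - mb), 0.0
    else:
        t = float((ma - mb) / math.sqrt(denom2))
        p = 2.0 * float(stats.t.sf(abs(t), df))
    return TTestResult(t=t, df=float(df), p=p, significant=p <= alpha,
                       alpha=alpha)
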