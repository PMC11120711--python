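"""Cohort statistics: group summaries, Mann-Whitney U, Fisher's exact test.

Stiffness distributions per morphological pattern / mutation group are
non-normal, so group comparisons use the Mann-Whitney U test with Bonferroni
correction over the family of pairwise comparisons; associations between
mutation frequency and categorical features use Fisher's exact test with the
probability-mass two-sided rule (the convention of mainstream statistical
software). Both engines delegate to scipy and are validated elsewhere
against exhaustive-enumeration oracles.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import InputError, ParameterError

__all__ = [
    "ContingencyTable2x2",
    "GroupSummary",
    "UTestResult",
    "fisher_exact",
    "mann_whitney",
    "summarize_groups",
]

EXACT_MW_MAX_N = 12


@dataclass(frozen=True)
class ContingencyTable2x2:
    """2x2 counts: rows = groups, columns = (mutant, wild-type)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        counts = (self.a, self.b, self.c, self.d)
        if any(int(v) != v or v < 0 for v in counts):
            raise ParameterError("contingency counts must be nonnegative integers")
        if sum(counts) == 0:
            raise ParameterError("contingency table is empty")

    @property
    def array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], int)


@dataclass(frozen=True)
class GroupSummary:
    """Descriptive statistics (kPa) for one group of ROIs."""

    group: str
    n: int
    mean: float
    sd: float
    min: float
    max: float


@dataclass(frozen=True)
class UTestResult:
    """Mann-Whitney U comparison with Bonferroni-adjusted p-value."""

    groups: tuple[str, str]
    u_statistic: float
    p_two_sided: float
    p_adjusted: float
    n_comparisons: int
    method: str  # "exact" | "normal-approx-tie-corrected"


def fisher_exact(table) -> float:
    """Two-sided Fisher's exact p-value of a 2x2 table.

    Accepts a :class:`ContingencyTable2x2` or any 2x2 array-like. Uses the
    probability-mass rule: the p-value sums the hypergeometric probabilities
    of all same-margin tables no more probable than the observed one. A zero
    row or column margin makes every same-margin table equally extreme and
    returns p = 1 with a warning.
    """
    if isinstance(table, ContingencyTable2x2):
        arr = table.array
    else:
        arr = np.asarray(table, int)
        if arr.shape != (2, 2):
            raise InputError("table must be 2x2")
        ContingencyTable2x2(*arr.ravel())  # validate
    margins = [arr[0].sum(), arr[1].sum(), arr[:, 0].sum(), arr[:, 1].sum()]
    if any(m == 0 for m in margins):
        warnings.warn("degenerate 2x2 table (zero margin): p = 1", stacklevel=2)
        return 1.0
    return float(sps.fisher_exact(arr, alternative="two-sided")[1])


def mann_whitney(
    sample_a, sample_b, n_comparisons: int = 1, groups: tuple[str, str] = ("a", "b")
) -> UTestResult:
    """Two-sided Mann-Whitney U test with Bonferroni adjustment.

    U is computed with midrank ties. The p-value is exact (full permutation
    distribution) when ``n_a + n_b <= 12`` and there are no ties, otherwise
    a normal approximation with tie and continuity corrections is used.
    ``p_adjusted = min(1, n_comparisons * p)``.
    """
    a = np.asarray(sample_a, float)
    b = np.asarray(sample_b, float)
    if a.size == 0 or b.size == 0:
        raise InputError("both samples must be non-empty")
    if n_comparisons < 1:
        raise InputError("n_comparisons must be >= 1")
    has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    if a.size + b.size <= EXACT_MW_MAX_N and not has_ties:
        method = "exact"
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact")
    else:
        method = "normal-approx-tie-corrected"
        res = sps.mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic", use_continuity=True
        )
    p = float(min(1.0, res.pvalue))
    return UTestResult(
        groups=tuple(groups),
        u_statistic=float(res.statistic),
        p_two_sided=p,
        p_adjusted=min(1.0, n_comparisons * p),
        n_comparisons=n_comparisons,
        method=method,
    )


def _group_key(df: pd.DataFrame, group_by: str) -> pd.Series:
    if group_by == "pattern":
        return df["pattern"]
    if group_by == "mutation":
        return np.where(df["mutation"] != "wt", "mutant", "wildtype")
    if group_by == "pattern_x_mutation":
        status = np.where(df["mutation"] != "wt", "mut", "wt")
        return df["pattern"] + ":" + status
    raise InputError(
        "group_by must be 'pattern', 'mutation', or 'pattern_x_mutation'"
    )


def summarize_groups(
    cohort: pd.DataFrame, group_by: str = "pattern"
) -> tuple[list[GroupSummary], list[UTestResult]]:
    """Per-group stiffness summaries plus all pairwise Mann-Whitney tests.

    Groups are ordered by label; the Bonferroni family size is the number of
    pairs. Empty groups are omitted with a warning.
    """
    if cohort.empty:
        raise InputError("cohort is empty")
    key = pd.Series(_group_key(cohort, group_by), index=cohort.index, name="group")
    values = cohort["stiffness_kpa"].astype(float)
    summaries: list[GroupSummary] = []
    samples: dict[str, np.ndarray] = {}
    for label in sorted(key.unique()):
        vals = values[key == label].to_numpy()
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            warnings.warn(f"group {label!r} has no finite stiffness values", stacklevel=2)
            continue
        samples[label] = vals
        summaries.append(
            GroupSummary(
                group=label,
                n=int(vals.size),
                mean=float(np.mean(vals)),
                sd=float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0,
                min=float(np.min(vals)),
                max=float(np.max(vals)),
            )
        )
    labels = [s.group for s in summaries]
    pairs = list(itertools.combinations(labels, 2))
    m = max(1, len(pairs))
    tests = [
        mann_whitney(samples[g1], samples[g2], n_comparisons=m, groups=(g1, g2))
        for g1, g2 in pairs
    ]
    return summaries, tests
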