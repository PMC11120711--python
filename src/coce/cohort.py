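"""Synthetic ROI cohort with the molecular/morphological structure of the study.

The cohort mirrors a 46-patient colorectal-cancer series with 54 regions of
interest (ROIs): 34 complex tubular, 6 mucinous, and 14 solid. Pattern,
grade, driver-gene, and microsatellite counts are assigned (not sampled), so
every generated cohort reproduces the observed margins exactly:

==============  ===========  ========  ======
ROI counts      complex tub  mucinous  solid
==============  ===========  ========  ======
KRAS            8            3         9
NRAS            1            -         -
BRAF            2            -         1
wild-type       23           3         4
MSI             1            -         3
==============  ===========  ========  ======

Case-level margins follow: 46 cases (33 low-grade with 10 mutant, 13
high-grade with 10 mutant), KRAS in 16 cases, NRAS in 1, BRAF in 3, MSI in 3
high-grade cases. Eight cases carry two ROIs of different patterns; one of
them (case #21) is the designated heterogeneous case whose complex-tubular
ROI is KRAS-mutant while its mucinous ROI is wild-type.

Only mean ROI stiffness is sampled: from the group normal distributions
(mutant 967 +/- 145 kPa, wild-type 751 +/- 92 kPa, or optional per-pattern
parameters), truncated by rejection at the 520 kPa tumor-cell floor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ParameterError

__all__ = [
    "CohortSpec",
    "sample_cohort",
    "PATTERNS",
    "GENES",
    "COHORT_COLUMNS",
]

PATTERNS = ("complex_tubular", "mucinous", "solid")
GENES = ("KRAS", "NRAS", "BRAF", "wt")
COHORT_COLUMNS = (
    "case_id",
    "roi_id",
    "grade",
    "pattern",
    "stiffness_kpa",
    "mutation",
    "msi",
)

# One entry per case: (grade, ((pattern, gene, msi), ...)).
# Dual-pattern cases first in construction order; the heterogeneous case is
# inserted so that it lands at case_id 21 after deterministic numbering.
_T = "complex_tubular"
_M = "mucinous"
_S = "solid"


def _table1_cases() -> list[tuple[str, tuple[tuple[str, str, bool], ...]]]:
    cases: list[tuple[str, tuple[tuple[str, str, bool], ...]]] = []
    # --- dual-pattern cases (8) ---
    # both-KRAS duals (account for the 4 ROI-level KRAS in excess of cases)
    cases += [("high", ((_T, "KRAS", False), (_S, "KRAS", False)))] * 3
    cases += [("high", ((_M, "KRAS", False), (_S, "KRAS", False)))]
    # wild-type duals; the high-grade one carries MSI in both ROIs
    cases += [("high", ((_T, "wt", True), (_S, "wt", True)))]
    cases += [("low", ((_T, "wt", False), (_S, "wt", False)))]
    cases += [("low", ((_T, "wt", False), (_M, "wt", False)))]
    # heterogeneous case: discordant KRAS between its two patterns
    hetero = ("low", ((_T, "KRAS", False), (_M, "wt", False)))
    # --- single-pattern cases (38) ---
    singles: list[tuple[str, tuple[tuple[str, str, bool], ...]]] = []
    singles += [("low", ((_T, "KRAS", False),))] * 4
    singles += [("low", ((_T, "NRAS", False),))]
    singles += [("low", ((_T, "BRAF", False),))] * 2
    singles += [("low", ((_T, "wt", False),))] * 20
    singles += [("low", ((_M, "KRAS", False),))] * 2
    singles += [("low", ((_M, "wt", False),))]
    singles += [("high", ((_S, "KRAS", True),))]
    singles += [("high", ((_S, "KRAS", False),))] * 4
    singles += [("high", ((_S, "BRAF", True),))]
    singles += [("high", ((_S, "wt", False),))] * 2
    cases += singles
    cases.insert(20, hetero)  # case_id 21 (1-based)
    return cases


TABLE1_CASES = tuple(_table1_cases())


def _default_stiffness_params() -> dict[str, tuple[float, float]]:
    return {"mutant": (967.0, 145.0), "wildtype": (751.0, 92.0)}


def _default_pattern_params() -> dict[str, tuple[float, float]]:
    return {
        "complex_tubular": (770.0, 164.0),
        "mucinous": (968.0, 234.0),
        "solid": (1039.0, 270.0),
    }


@dataclass
class CohortSpec:
    """Parameters of the synthetic cohort.

    ``stiffness_params`` maps group -> (mean kPa, sd kPa) for the
    mutation-status groups; with ``stratify_by_pattern=True`` sampling uses
    the per-pattern marginals instead. ``floor_kpa`` truncates sampling at
    the tumor-cell threshold.
    """

    n_cases: int = 46
    roi_counts_by_pattern: dict = field(
        default_factory=lambda: {
            "complex_tubular": (11, 23),
            "mucinous": (3, 3),
            "solid": (10, 4),
        }
    )
    gene_split: dict = field(
        default_factory=lambda: {"KRAS": 20, "NRAS": 1, "BRAF": 3}
    )
    msi_counts: dict = field(
        default_factory=lambda: {"complex_tubular": 1, "mucinous": 0, "solid": 3}
    )
    stiffness_params: dict = field(default_factory=_default_stiffness_params)
    pattern_params: dict = field(default_factory=_default_pattern_params)
    stratify_by_pattern: bool = False
    floor_kpa: float = 520.0

    def __post_init__(self) -> None:
        for pat, (n_mut, n_wt) in self.roi_counts_by_pattern.items():
            if pat not in PATTERNS:
                raise ParameterError(f"unknown pattern {pat!r}")
            if n_mut < 0 or n_wt < 0:
                raise ParameterError("ROI counts must be >= 0")
        n_mut_total = sum(v[0] for v in self.roi_counts_by_pattern.values())
        if sum(self.gene_split.values()) != n_mut_total:
            raise ParameterError(
                f"gene_split sums to {sum(self.gene_split.values())}, "
                f"but there are {n_mut_total} mutant ROIs"
            )
        for grp, (mean, sd) in {**self.stiffness_params, **self.pattern_params}.items():
            if sd < 0:
                raise ParameterError(f"negative sd for group {grp!r}")
            if mean <= self.floor_kpa and sd == 0:
                raise ParameterError(
                    f"degenerate mean for {grp!r} is at or below the "
                    f"{self.floor_kpa} kPa floor"
                )

    def is_default_structure(self) -> bool:
        ref = CohortSpec()
        return (
            self.n_cases == ref.n_cases
            and self.roi_counts_by_pattern == ref.roi_counts_by_pattern
            and self.gene_split == ref.gene_split
            and self.msi_counts == ref.msi_counts
        )


def _truncated_normal(rng, mean, sd, floor, size):
    """Rejection sampling of N(mean, sd^2) conditioned on > floor."""
    if sd == 0:
        return np.full(size, float(mean))
    out = np.empty(size)
    remaining = np.arange(size)
    while remaining.size:
        draw = rng.normal(mean, sd, remaining.size)
        ok = draw > floor
        out[remaining[ok]] = draw[ok]
        remaining = remaining[~ok]
    return out


def _generic_cases(spec: CohortSpec):
    """Deterministic case allocation for non-default count structures.

    ROIs are laid out pattern-by-pattern (mutant genes first, then
    wild-type); the ROI surplus over ``n_cases`` is absorbed by pairing the
    first surplus ROIs with the last ones into dual-pattern cases.
    """
    genes = []
    for gene, n in spec.gene_split.items():
        genes += [gene] * n
    rois = []
    gi = 0
    for pat in PATTERNS:
        n_mut, n_wt = spec.roi_counts_by_pattern.get(pat, (0, 0))
        for _ in range(n_mut):
            rois.append([pat, genes[gi], False])
            gi += 1
        for _ in range(n_wt):
            rois.append([pat, "wt", False])
    for pat, n_msi in spec.msi_counts.items():
        hit = 0
        for r in rois:
            if hit >= n_msi:
                break
            if r[0] == pat:
                r[2] = True
                hit += 1
    n_rois = len(rois)
    n_dual = n_rois - spec.n_cases
    if n_dual < 0:
        raise ParameterError("n_cases exceeds the total ROI count")
    cases = []
    for i in range(n_dual):
        cases.append(("low", (tuple(rois[i]), tuple(rois[n_rois - 1 - i]))))
    for i in range(n_dual, n_rois - n_dual):
        cases.append(("low", (tuple(rois[i]),)))
    return cases


def sample_cohort(spec: CohortSpec | None = None, seed: int = 0) -> pd.DataFrame:
    """Sample one cohort table; identical (spec, seed) gives identical output.

    Returns a DataFrame with columns ``case_id, roi_id, grade, pattern,
    stiffness_kpa, mutation, msi``. Counts are assigned deterministically
    from the spec; only stiffness is random.
    """
    spec = spec or CohortSpec()
    cases = TABLE1_CASES if spec.is_default_structure() else _generic_cases(spec)
    rng = np.random.default_rng(seed)
    rows = []
    for ci, (grade, rois) in enumerate(cases, start=1):
        for ri, (pattern, gene, msi) in enumerate(rois, start=1):
            rows.append(
                {
                    "case_id": ci,
                    "roi_id": f"{ci}-{ri}",
                    "grade": f"{grade}_grade",
                    "pattern": pattern,
                    "stiffness_kpa": np.nan,
                    "mutation": gene,
                    "msi": "MSI" if msi else "MSS",
                }
            )
    df = pd.DataFrame(rows, columns=list(COHORT_COLUMNS))
    # sample stiffness group-by-group in a fixed order for determinism
    if spec.stratify_by_pattern:
        for pat in PATTERNS:
            mean, sd = spec.pattern_params[pat]
            idx = df.index[df["pattern"] == pat]
            df.loc[idx, "stiffness_kpa"] = _truncated_normal(
                rng, mean, sd, spec.floor_kpa, idx.size
            )
    else:
        mut = df["mutation"] != "wt"
        for label, sel in (("mutant", mut), ("wildtype", ~mut)):
            mean, sd = spec.stiffness_params[label]
            idx = df.index[sel]
            df.loc[idx, "stiffness_kpa"] = _truncated_normal(
                rng, mean, sd, spec.floor_kpa, idx.size
            )
    return df
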