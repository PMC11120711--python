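"""End-to-end analysis: cohort -> statistics -> classification (-> images).

``run_pipeline`` mirrors the study design in silico: sample a cohort with
the observed morphological/molecular margins, summarize stiffness by group,
test the two frequency contrasts (grade and pattern) with Fisher's exact
test, evaluate stiffness as a mutation marker (ROC, Youden threshold, fixed
clinical cut-offs) against the morphology-as-marker baselines, and flag
heterogeneous cases. Optionally it also exercises the image-level chain on a
two-block phantom and records the recovered block stiffness against ground
truth. All randomness flows from a single seed; the report embeds the seed
and a configuration hash so identical runs are byte-identical.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__ as _version
from .classify import (
    flag_heterogeneous_cases,
    metrics_at_threshold,
    pattern_marker_metrics,
    roc_curve,
    youden_threshold,
)
from .config import CalibrationConfig, ClassifierConfig, SystemConfig, config_hash
from .cohort import CohortSpec, sample_cohort
from .exceptions import ParameterError
from .io import write_cohort_csv, write_report_json
from .phantom import build_phantom, simulate_compression_series, two_block_modulus
from .stats import fisher_exact, summarize_groups
from .stiffness import StiffnessMapper
from .strain import accumulate_strain

__all__ = ["RunConfig", "run_pipeline", "run_image_chain"]


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce one analysis run."""

    system: SystemConfig = field(default_factory=SystemConfig)
    calibration: CalibrationConfig = field(default_factory=CalibrationConfig)
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    cohort: CohortSpec = field(default_factory=CohortSpec)
    seed: int = 0
    include_image_chain: bool = False
    image_block_moduli_kpa: tuple[float, float] = (600.0, 1000.0)
    output_dir: str | None = None


def run_image_chain(
    config: RunConfig,
    lateral_extent_mm: float = 0.9,
    depth_extent_mm: float = 1.2,
    silicone_thickness_um: float = 300.0,
    snr_db: float | None = 25.0,
    n_steps: int = 21,
    max_pressure_kpa: float = 8.0,
) -> dict:
    """Simulate a two-block phantom and recover per-block stiffness.

    Returns the silicone-inferred standardization pressure and the median
    recovered stiffness of each tissue block next to its ground truth.
    """
    left, right = config.image_block_moduli_kpa
    system = config.system
    phantom = build_phantom(
        lateral_extent_mm=lateral_extent_mm,
        depth_extent_mm=depth_extent_mm,
        silicone_thickness_um=silicone_thickness_um,
        silicone_modulus_kpa=config.calibration.reference_modulus_kpa,
        tissue_modulus_kpa=two_block_modulus(
            left, right, lateral_extent_mm * 1000.0 / 2.0
        ),
        system=system,
        seed=config.seed,
    )
    series, truth = simulate_compression_series(
        phantom,
        system,
        surface_pressures_kpa=np.linspace(0.0, max_pressure_kpa, n_steps),
        seed=config.seed + 1,
        snr_db=snr_db,
    )
    cumulative = accumulate_strain(series, system=system)
    mapper = StiffnessMapper(
        calibration=config.calibration,
        silicone_thickness_hint_um=silicone_thickness_um,
    ).fit(cumulative)
    stiff = mapper.transform(cumulative)

    nz, nx = stiff.values_kpa.shape
    margin_z = 12  # skip the layer boundary and deep low-SNR rows
    sil_px = int(round(silicone_thickness_um / system.axial_pixel_pitch_um))
    tissue = slice(sil_px + margin_z, nz - margin_z)
    guard = 4
    halves = {
        "left": (slice(None), slice(guard, nx // 2 - guard)),
        "right": (slice(None), slice(nx // 2 + guard, nx - guard)),
    }
    medians = {}
    for name, (_, cols) in halves.items():
        block = stiff.values_kpa[tissue, cols]
        ok = stiff.valid_mask[tissue, cols]
        medians[name] = float(np.median(block[ok])) if ok.any() else float("nan")
    return {
        "pair_index": int(mapper.pair_index_),
        "achieved_pressure_kpa": float(mapper.achieved_pressure_kpa_),
        "block_median_kpa": medians,
        "block_truth_kpa": {"left": left, "right": right},
        "aliased_pairs": list(truth.aliased_pairs),
    }


def run_pipeline(config: RunConfig | None = None) -> dict:
    """Execute the full in-silico study; returns the report dictionary.

    When ``config.output_dir`` is set, the cohort CSV and the JSON report
    are written there (seed and config hash embedded for provenance).
    """
    config = config or RunConfig()
    cohort = sample_cohort(config.cohort, seed=config.seed)
    cfg = config.classifier

    # descriptive statistics + pairwise tests
    summaries = {}
    u_tests = {}
    for group_by in ("pattern", "mutation", "pattern_x_mutation"):
        s, t = summarize_groups(cohort, group_by)
        summaries[group_by] = [dataclasses.asdict(x) for x in s]
        u_tests[group_by] = [dataclasses.asdict(x) for x in t]

    # frequency contrasts (case-level grade, ROI-level pattern)
    cases = cohort.groupby("case_id").agg(
        grade=("grade", "first"),
        mutant=("mutation", lambda g: bool((g != "wt").any())),
        kras=("mutation", lambda g: bool((g == "KRAS").any())),
    )
    hg, lg = cases[cases["grade"] == "high_grade"], cases[cases["grade"] == "low_grade"]
    grade_table = [
        [int(hg["mutant"].sum()), int((~hg["mutant"]).sum())],
        [int(lg["mutant"].sum()), int((~lg["mutant"]).sum())],
    ]
    sol = cohort[cohort["pattern"] == "solid"]
    tub = cohort[cohort["pattern"] == "complex_tubular"]
    pattern_table = [
        [int((sol["mutation"] != "wt").sum()), int((sol["mutation"] == "wt").sum())],
        [int((tub["mutation"] != "wt").sum()), int((tub["mutation"] == "wt").sum())],
    ]
    fisher_tests = {
        "grade_high_vs_low": {
            "table": grade_table,
            "p_two_sided": fisher_exact(grade_table),
        },
        "pattern_solid_vs_tubular": {
            "table": pattern_table,
            "p_two_sided": fisher_exact(pattern_table),
        },
    }

    counting = {
        "n_cases": int(len(cases)),
        "n_rois": int(len(cohort)),
        "driver_mutation_cases_pct": 100.0 * float(cases["mutant"].mean()),
        "driver_mutation_rois_pct": 100.0 * float((cohort["mutation"] != "wt").mean()),
        "kras_cases_pct": 100.0 * float(cases["kras"].mean()),
        "kras_rois_pct": 100.0 * float((cohort["mutation"] == "KRAS").mean()),
    }

    # stiffness as marker: any-driver and KRAS-only tasks (in-sample metrics)
    values = cohort["stiffness_kpa"].to_numpy(float)
    roc_results = {}
    confusion = {}
    for task, positive, fixed in (
        ("any_driver", (cohort["mutation"] != "wt").to_numpy(), cfg.threshold_any_driver_kpa),
        ("kras", (cohort["mutation"] == "KRAS").to_numpy(), cfg.threshold_kras_kpa),
    ):
        roc = roc_curve(values, positive)
        thr, j = youden_threshold(roc)
        roc_results[task] = {
            "auc": roc.auc,
            "youden_threshold_kpa": thr,
            "youden_j": j,
            "n_positive": roc.n_positive,
            "n_negative": roc.n_negative,
        }
        confusion[f"{task}_at_fixed_{fixed:g}_kpa"] = metrics_at_threshold(
            values, positive, fixed
        ).as_dict()
        confusion[f"{task}_at_youden"] = metrics_at_threshold(
            values, positive, thr
        ).as_dict()
    for pattern in ("complex_tubular", "solid"):
        confusion[f"pattern_marker_{pattern}"] = pattern_marker_metrics(
            cohort, pattern
        ).as_dict()

    heterogeneity = [
        dataclasses.asdict(r) for r in flag_heterogeneous_cases(cohort, cfg)
    ]

    report = {
        "schema_version": 1,
        "group_summaries": summaries,
        "u_tests": u_tests,
        "fisher_tests": fisher_tests,
        "counting": counting,
        "roc_results": roc_results,
        "confusion_metrics": confusion,
        "heterogeneity_flags": heterogeneity,
        "provenance": {
            "seed": config.seed,
            "config_hash": config_hash(config),
            "package_version": _version,
        },
    }
    if config.include_image_chain:
        report["image_chain"] = run_image_chain(config)

    if config.output_dir is not None:
        out = Path(config.output_dir)
        try:
            out.mkdir(parents=True, exist_ok=True)
        except OSError as err:
            raise ParameterError(f"output_dir {out} is not writable: {err}") from err
        write_cohort_csv(cohort, out / "cohort.csv", seed=config.seed)
        write_report_json(report, out / "report.json")
    return report
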