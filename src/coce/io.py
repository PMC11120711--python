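"""Cohort CSV round trip, map export, and report serialization.

The cohort CSV schema is ``case_id, roi_id, grade, pattern, stiffness_kpa,
mutation, msi``; unknown columns are preserved. Files written by the package
start with a ``# coce-seed: N`` provenance comment. Strain and stiffness
maps export as 32-bit float TIFF with a JSON metadata sidecar; colorized
stiffness maps use a red (soft) -> yellow -> green -> blue -> dark-blue
(stiff) palette with the 520 kPa tumor-cell threshold pinned at the yellow
boundary.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import COHORT_COLUMNS, GENES, PATTERNS
from .exceptions import SchemaError

__all__ = [
    "read_cohort_csv",
    "write_cohort_csv",
    "write_strain_tiff",
    "write_stiffness_tiff",
    "colorize_stiffness",
    "write_report_json",
]

_PATTERN_ALIASES = {p.lower(): p for p in PATTERNS}
_PATTERN_ALIASES.update(
    {"complex tubular": "complex_tubular", "tubular": "complex_tubular"}
)
_GENE_ALIASES = {g.lower(): g for g in GENES}
_GENE_ALIASES.update({"wild-type": "wt", "wildtype": "wt", "wild_type": "wt"})


def write_cohort_csv(cohort: pd.DataFrame, path, seed: int | None = None) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# coce-seed: {-1 if seed is None else seed}\n")
        cohort.to_csv(fh, index=False)


def read_cohort_csv(path) -> pd.DataFrame:
    """Read and validate a cohort CSV.

    Case-variant pattern/mutation/MSI labels are normalized to canonical
    form with a warning; rows violating the schema (non-positive or missing
    stiffness, unknown labels) are rejected with their line numbers in a
    :class:`SchemaError`. Unknown columns pass through untouched.
    """
    path = Path(path)
    df = pd.read_csv(path, comment="#", skip_blank_lines=True)
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError([(1, f"missing required columns {missing}")])

    # map dataframe rows to 1-based file line numbers (header + comments)
    n_head = 0
    with path.open() as fh:
        for line in fh:
            n_head += 1
            if not line.startswith("#") and line.strip():
                break
    line_no = df.index.to_numpy() + n_head + 1

    problems: list[tuple[int, str]] = []
    normalized_any = False

    pat = df["pattern"].astype(str).str.strip()
    canon = pat.str.lower().map(_PATTERN_ALIASES)
    changed = canon.notna() & (canon != pat)
    normalized_any |= bool(changed.any())
    for i in df.index[canon.isna()]:
        problems.append((int(line_no[i]), f"unknown pattern {pat[i]!r}"))
    df["pattern"] = canon

    gene = df["mutation"].astype(str).str.strip()
    gcanon = gene.str.lower().map(_GENE_ALIASES)
    normalized_any |= bool((gcanon.notna() & (gcanon != gene)).any())
    for i in df.index[gcanon.isna()]:
        problems.append((int(line_no[i]), f"unknown mutation {gene[i]!r}"))
    df["mutation"] = gcanon

    msi = df["msi"].astype(str).str.strip().str.upper()
    normalized_any |= bool((msi != df["msi"]).any())
    bad_msi = ~msi.isin(["MSI", "MSS"])
    for i in df.index[bad_msi]:
        problems.append((int(line_no[i]), f"msi must be MSI or MSS, got {df['msi'][i]!r}"))
    df["msi"] = msi

    stiff = pd.to_numeric(df["stiffness_kpa"], errors="coerce")
    bad_stiff = ~(stiff > 0)
    for i in df.index[bad_stiff]:
        problems.append(
            (int(line_no[i]), f"stiffness_kpa must be > 0, got {df['stiffness_kpa'][i]!r}")
        )
    df["stiffness_kpa"] = stiff

    if problems:
        bad_rows = sorted({ln for ln, _ in problems})
        warnings.warn(
            "rejected malformed cohort rows: "
            + "; ".join(f"line {ln}: {why}" for ln, why in problems),
            stacklevel=2,
        )
        df = df[~np.isin(line_no, bad_rows)].reset_index(drop=True)
        if df.empty:
            raise SchemaError(problems)
    if normalized_any:
        warnings.warn("cohort labels normalized to canonical form", stacklevel=2)
    return df


def write_strain_tiff(strain_map, path, sidecar: bool = True) -> None:
    """Strain values + validity mask as a 2-page 32-bit float TIFF."""
    import tifffile

    path = Path(path)
    tifffile.imwrite(
        path,
        np.stack(
            [strain_map.values.astype(np.float32),
             strain_map.valid_mask.astype(np.float32)]
        ),
        photometric="minisblack",
    )
    if sidecar:
        meta = {
            "window": list(strain_map.window),
            "frame_pair": list(strain_map.frame_pair),
            "system": dataclasses.asdict(strain_map.system),
        }
        path.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def write_stiffness_tiff(stiff_map, path, sidecar: bool = True) -> None:
    """Stiffness (kPa) + cancer/reference masks as a 3-page float TIFF."""
    import tifffile

    path = Path(path)
    tifffile.imwrite(
        path,
        np.stack(
            [
                stiff_map.values_kpa.astype(np.float32),
                stiff_map.cancer_mask.astype(np.float32),
                stiff_map.reference_mask.astype(np.float32),
            ]
        ),
        photometric="minisblack",
    )
    if sidecar:
        meta = {
            "standardization_pressure_kpa": stiff_map.standardization_pressure_kpa,
            "source_frame_pair": list(stiff_map.source_frame_pair),
        }
        path.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def colorize_stiffness(stiff_map, cap_kpa: float | None = None) -> np.ndarray:
    """8-bit RGB render: red (soft) through yellow (520 kPa) to dark blue.

    The palette anchors are a display choice; the scientifically meaningful
    anchor is the tumor-cell threshold pinned at the red/yellow boundary.
    """
    from matplotlib.colors import LinearSegmentedColormap

    cap = cap_kpa or float(np.nanmax(stiff_map.values_kpa)) or 1.0
    frac520 = min(max(520.0 / cap, 0.05), 0.95)
    cmap = LinearSegmentedColormap.from_list(
        "coce",
        [
            (0.0, "#d62728"),
            (frac520, "#ffdf00"),
            (frac520 + (1 - frac520) * 0.33, "#2ca02c"),
            (frac520 + (1 - frac520) * 0.66, "#1f77b4"),
            (1.0, "#08306b"),
        ],
    )
    norm = np.clip(stiff_map.values_kpa / cap, 0, 1)
    rgb = (cmap(norm)[..., :3] * 255).astype(np.uint8)
    rgb[stiff_map.reference_mask] = (180, 180, 180)
    return rgb


def _jsonify(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonify(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return v if np.isfinite(v) else None
    return obj


def write_report_json(report_dict: dict, path) -> None:
    Path(path).write_text(json.dumps(_jsonify(report_dict), indent=1, sort_keys=True))
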