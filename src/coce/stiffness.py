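"""Silicone-calibrated Young's-modulus mapping and ROI quantification.

The reference silicone slab (pre-calibrated modulus, 100 kPa by default)
plays two roles. It converts relative strain into absolute stiffness --
tangent Young's modulus of tissue is the silicone strain times silicone
modulus divided by tissue strain -- and it acts as a local pressure sensor:
the map is formed at the compression state whose silicone-inferred pressure
first enters a standardized window (4 +/- 1 kPa by default), so that tissue
elastic nonlinearity does not bias comparisons between acquisitions. ROI
statistics are restricted to the tumor-cell mask (stiffness > 520 kPa).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skimage.draw import polygon2mask
from sklearn.base import BaseEstimator, TransformerMixin

from .config import CalibrationConfig, SystemConfig
from .exceptions import CalibrationError, InputError, SegmentationError
from .strain import StrainMap

__all__ = [
    "StiffnessMap",
    "RoiQuant",
    "segment_reference_layer",
    "select_pressure_standard_pair",
    "stiffness_from_strain",
    "quantify_roi",
    "StiffnessMapper",
]


@dataclass
class StiffnessMap:
    """Calibrated Young's-modulus map (kPa) at a standardized pressure.

    ``reference_mask`` marks silicone pixels (excluded from tissue
    statistics); ``cancer_mask`` marks tissue pixels above the tumor-cell
    threshold; ``valid_mask`` carries the strain estimator's decorrelation
    mask.
    """

    values_kpa: np.ndarray
    standardization_pressure_kpa: float
    reference_mask: np.ndarray
    cancer_mask: np.ndarray
    valid_mask: np.ndarray
    source_frame_pair: tuple[int, int]
    capped_mask: np.ndarray | None = None


@dataclass
class RoiQuant:
    """Mean stiffness of one ROI under the tumor-cell mask.

    ``mean_kpa`` is NaN (undefined marker) when no ROI pixel passes the
    mask; ``masked_fraction`` is the fraction of ROI pixels that did.
    """

    mean_kpa: float
    masked_fraction: float
    n_pixels: int


def segment_reference_layer(
    strain: StrainMap,
    silicone_thickness_hint_um: float,
    cv_bound: float = 0.35,
    min_contrast: float = 1.5,
) -> np.ndarray:
    """Locate the silicone slab as the homogeneous high-strain top band.

    The silicone is much softer than tumor tissue, so under uniform stress
    its strain is several-fold higher. Per column, the boundary is the first
    depth at which strain falls below the midpoint of the silicone and
    tissue strain levels -- for a step profile blurred by the estimator's
    box window the midpoint crossing sits at the true interface -- and the
    mask is the simply connected band above it.
    Falls back to a flat band of the hint thickness (with a "low-contrast"
    warning) when the two levels are not separable, and raises
    :class:`SegmentationError` when the detected band is laterally
    inhomogeneous or its thickness is off the hint by more than 30%.
    """
    if silicone_thickness_hint_um <= 0:
        raise InputError("silicone_thickness_hint_um must be > 0")
    vals = np.where(strain.valid_mask, strain.values, np.nan)
    nz, nx = vals.shape
    dz = strain.system.axial_pixel_pitch_um
    hint_px = silicone_thickness_hint_um / dz

    top = slice(0, max(2, int(round(hint_px / 2))))
    deep = slice(min(nz - 2, int(round(1.5 * hint_px))), nz)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        eps_sil = np.nanmedian(vals[top])
        eps_tis = np.nanmedian(vals[deep])
    if not np.isfinite(eps_sil) or not np.isfinite(eps_tis):
        raise SegmentationError("strain map too sparse to locate the reference layer")

    if eps_tis <= 0 or eps_sil / eps_tis < min_contrast:
        warnings.warn(
            "low-contrast reference layer: falling back to hint-thickness band",
            stacklevel=2,
        )
        mask = np.zeros((nz, nx), bool)
        mask[: int(round(hint_px))] = True
        return mask

    threshold = float(0.5 * (eps_sil + eps_tis))
    boundary = np.empty(nx, int)
    filled = np.where(np.isfinite(vals), vals, eps_sil)
    for j in range(nx):
        below = np.nonzero(filled[:, j] < threshold)[0]
        if not below.size:
            boundary[j] = nz
            continue
        idx = int(below[0])
        if idx == 0:
            boundary[j] = 0
            continue
        # sub-pixel crossing plus half-pixel offset of the even box window
        step = filled[idx - 1, j] - filled[idx, j]
        frac = (filled[idx - 1, j] - threshold) / step if step > 0 else 0.5
        boundary[j] = int(round(idx - 1 + frac + 0.5))
    median_b = float(np.median(boundary))
    if not (0.7 * hint_px <= median_b <= 1.3 * hint_px):
        raise SegmentationError(
            f"detected reference thickness {median_b * dz:.0f} um is outside "
            f"+/-30% of the {silicone_thickness_hint_um:.0f} um hint"
        )
    # lateral homogeneity of the per-column silicone strain
    col_means = np.array(
        [np.nanmean(vals[: max(b, 1), j]) for j, b in enumerate(boundary)]
    )
    col_means = col_means[np.isfinite(col_means)]
    if col_means.size and np.mean(col_means) > 0:
        cv = float(np.std(col_means) / np.mean(col_means))
        if cv > cv_bound:
            raise SegmentationError(
                f"reference band laterally inhomogeneous (CV {cv:.2f} > {cv_bound})"
            )
    rows = np.arange(nz)[:, None]
    return rows < boundary[None, :]


def select_pressure_standard_pair(
    cumulative_strains: list[StrainMap],
    reference_mask: np.ndarray,
    calibration: CalibrationConfig | None = None,
) -> tuple[int, float]:
    """Pick the compression state at the standardized pressure.

    Local pressure at step k is the reference modulus times the median
    cumulative silicone strain; the first step whose pressure enters
    ``target +/- tolerance`` wins. Raises :class:`CalibrationError` with the
    achieved pressure range when no step qualifies.
    """
    cal = calibration or CalibrationConfig()
    if not cumulative_strains:
        raise InputError("need at least one cumulative strain map")
    lo = cal.target_pressure_kpa - cal.pressure_tolerance_kpa
    hi = cal.target_pressure_kpa + cal.pressure_tolerance_kpa
    achieved = []
    for k, sm in enumerate(cumulative_strains):
        sel = reference_mask & sm.valid_mask
        if not sel.any():
            sel = reference_mask
        p = cal.reference_modulus_kpa * float(np.median(sm.values[sel]))
        achieved.append(p)
        if lo <= p <= hi:
            return k, p
    raise CalibrationError(
        (min(achieved), max(achieved)), cal.target_pressure_kpa, cal.pressure_tolerance_kpa
    )


def stiffness_from_strain(
    strain: StrainMap,
    reference_mask: np.ndarray,
    calibration: CalibrationConfig | None = None,
    per_column: bool = False,
    standardization_pressure_kpa: float | None = None,
) -> StiffnessMap:
    """Calibrate a strain map into Young's modulus via the silicone ratio.

    ``E(x, z) = E_ref * eps_silicone / eps_tissue(x, z)`` with the silicone
    strain taken as the global median over the reference mask (default) or
    per column (``per_column=True``, for tilted contact). Pixels whose
    tissue strain is at or below the machine floor are set to the modulus
    cap and flagged rather than raising.
    """
    cal = calibration or CalibrationConfig()
    reference_mask = np.asarray(reference_mask, bool)
    if not reference_mask.any():
        raise InputError("reference mask is empty")
    sel = reference_mask & strain.valid_mask
    if not sel.any():
        sel = reference_mask
    if per_column:
        masked = np.where(sel, strain.values, np.nan)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            eps_sil = np.nanmedian(masked, axis=0)
        eps_sil = np.where(np.isfinite(eps_sil), eps_sil, np.nanmedian(eps_sil))
        eps_sil = eps_sil[None, :]
    else:
        eps_sil = float(np.median(strain.values[sel]))
    eps_t = strain.values
    # non-positive measured tissue strain means "stiffer than resolvable":
    # mapping it to the cap keeps E a monotone function of strain, so ROI
    # medians of E and of strain stay consistent under noise
    degenerate = eps_t <= np.finfo(float).tiny * 1e6
    with np.errstate(divide="ignore", invalid="ignore"):
        e = cal.reference_modulus_kpa * eps_sil / np.where(degenerate, 1.0, eps_t)
    e = np.where(degenerate, cal.modulus_cap_kpa, e)
    capped = degenerate | (e > cal.modulus_cap_kpa)
    e = np.clip(e, 0.0, cal.modulus_cap_kpa)
    cancer = (e > cal.cancer_mask_threshold_kpa) & ~reference_mask & strain.valid_mask
    if standardization_pressure_kpa is None:
        standardization_pressure_kpa = cal.reference_modulus_kpa * float(
            np.median(strain.values[sel])
        )
    return StiffnessMap(
        values_kpa=e,
        standardization_pressure_kpa=float(standardization_pressure_kpa),
        reference_mask=reference_mask,
        cancer_mask=cancer,
        valid_mask=strain.valid_mask.copy(),
        source_frame_pair=strain.frame_pair,
        capped_mask=capped,
    )


def quantify_roi(stiff: StiffnessMap, roi_polygon) -> RoiQuant:
    """Mean stiffness over ``roi & cancer_mask``, excluding the reference.

    ``roi_polygon`` is a sequence of (x, z) vertices in 0-based image pixel
    coordinates (half-open convention). Returns a NaN mean with
    ``masked_fraction`` 0 when the tumor-cell mask does not intersect the
    ROI.
    """
    poly = np.asarray(roi_polygon, float)
    if poly.ndim != 2 or poly.shape[1] != 2 or poly.shape[0] < 3:
        raise InputError("roi_polygon must be an (n >= 3, 2) array of (x, z)")
    shape = stiff.values_kpa.shape
    # polygon2mask expects (row, col) = (z, x)
    roi = polygon2mask(shape, poly[:, ::-1])
    roi &= ~stiff.reference_mask
    n_roi = int(roi.sum())
    if n_roi == 0:
        raise InputError("ROI polygon does not intersect the tissue image")
    good = roi & stiff.cancer_mask
    n_good = int(good.sum())
    if n_good == 0:
        return RoiQuant(mean_kpa=float("nan"), masked_fraction=0.0, n_pixels=0)
    return RoiQuant(
        mean_kpa=float(np.mean(stiff.values_kpa[good])),
        masked_fraction=n_good / n_roi,
        n_pixels=n_good,
    )


class StiffnessMapper(BaseEstimator, TransformerMixin):
    """Pressure-standardized stiffness mapping (transformer).

    ``fit`` consumes the list of cumulative strain maps from a compression
    sweep, segments the reference layer, and learns the standardized
    compression state; ``transform`` calibrates that state's strain map into
    a :class:`StiffnessMap`.

    Parameters
    ----------
    calibration : CalibrationConfig
        Reference modulus, pressure window, tumor-cell threshold, cap.
    silicone_thickness_hint_um : float, default 300
        Nominal reference-layer thickness used to seed segmentation.
    per_column : bool, default False
        Use per-column silicone strain instead of the global median.
    """

    def __init__(
        self,
        calibration: CalibrationConfig | None = None,
        silicone_thickness_hint_um: float = 300.0,
        per_column: bool = False,
    ):
        self.calibration = calibration
        self.silicone_thickness_hint_um = silicone_thickness_hint_um
        self.per_column = per_column

    def _cal(self) -> CalibrationConfig:
        return self.calibration or CalibrationConfig()

    def fit(self, X: list[StrainMap], y=None) -> "StiffnessMapper":
        if not X:
            raise InputError("X must be a non-empty list of cumulative StrainMaps")
        self.reference_mask_ = segment_reference_layer(
            X[-1], self.silicone_thickness_hint_um
        )
        self.pair_index_, self.achieved_pressure_kpa_ = select_pressure_standard_pair(
            X, self.reference_mask_, self._cal()
        )
        return self

    def transform(self, X: list[StrainMap]) -> StiffnessMap:
        if not hasattr(self, "pair_index_"):
            raise InputError("StiffnessMapper must be fitted before transform")
        return stiffness_from_strain(
            X[self.pair_index_],
            self.reference_mask_,
            self._cal(),
            per_column=self.per_column,
            standardization_pressure_kpa=self.achieved_pressure_kpa_,
        )
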