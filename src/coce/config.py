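"""Configuration dataclasses shared across the pipeline.

Units are carried in field names: ``_um`` micrometres, ``_mm`` millimetres,
``_kpa`` kilopascals. All configs are frozen so they can be hashed into run
provenance records.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass

from .exceptions import ParameterError

__all__ = ["SystemConfig", "CalibrationConfig", "ClassifierConfig", "config_hash"]


@dataclass(frozen=True)
class SystemConfig:
    """Optical parameters of the swept/spectral-domain OCT system.

    Defaults emulate a 1310 nm instrument with 10 um axial and 15 um lateral
    resolution and 2 mm imaging depth. ``refractive_index`` is the group index
    used to convert interframe phase to axial displacement; it cancels in the
    silicone-calibrated stiffness ratio, so only phase realism depends on it.
    """

    center_wavelength_um: float = 1.31
    axial_resolution_um: float = 10.0
    lateral_resolution_um: float = 15.0
    imaging_depth_mm: float = 2.0
    axial_pixel_pitch_um: float = 5.0
    lateral_pixel_pitch_um: float = 7.5
    refractive_index: float = 1.4

    def __post_init__(self) -> None:
        for name in (
            "center_wavelength_um",
            "axial_resolution_um",
            "lateral_resolution_um",
            "imaging_depth_mm",
            "axial_pixel_pitch_um",
            "lateral_pixel_pitch_um",
            "refractive_index",
        ):
            if not getattr(self, name) > 0:
                raise ParameterError(f"{name} must be > 0")
        # Nyquist sampling of the axial resolution cell
        if self.axial_pixel_pitch_um > self.axial_resolution_um / 2 + 1e-12:
            raise ParameterError(
                "axial_pixel_pitch_um must not exceed axial_resolution_um / 2"
            )

    @property
    def phase_per_um(self) -> float:
        """Interframe phase (rad) per micrometre of axial displacement."""
        return 4.0 * math.pi * self.refractive_index / self.center_wavelength_um

    @property
    def strain_per_rad_per_px(self) -> float:
        """Axial strain per unit phase-difference gradient (rad/pixel)."""
        return 1.0 / (self.phase_per_um * self.axial_pixel_pitch_um)


@dataclass(frozen=True)
class CalibrationConfig:
    """Reference-layer calibration and pressure-standardization settings.

    ``reference_modulus_kpa`` is the pre-calibrated Young's modulus of the
    silicone layer; local pressure is inferred as modulus times silicone
    strain and the map is formed at ``target_pressure_kpa`` within
    ``pressure_tolerance_kpa``. ``cancer_mask_threshold_kpa`` restricts ROI
    statistics to zones stiff enough to be tumor cells; ``modulus_cap_kpa``
    bounds the ratio where tissue strain approaches zero.
    """

    reference_modulus_kpa: float = 100.0
    target_pressure_kpa: float = 4.0
    pressure_tolerance_kpa: float = 1.0
    cancer_mask_threshold_kpa: float = 520.0
    modulus_cap_kpa: float = 2000.0

    def __post_init__(self) -> None:
        for name in (
            "reference_modulus_kpa",
            "target_pressure_kpa",
            "pressure_tolerance_kpa",
            "cancer_mask_threshold_kpa",
            "modulus_cap_kpa",
        ):
            if not getattr(self, name) > 0:
                raise ParameterError(f"{name} must be > 0")
        if self.pressure_tolerance_kpa >= self.target_pressure_kpa:
            raise ParameterError("pressure_tolerance_kpa must be < target_pressure_kpa")


@dataclass(frozen=True)
class ClassifierConfig:
    """Fixed stiffness cut-offs used when screening for mutations.

    A call is positive when mean ROI stiffness is strictly above the
    threshold. 803 kPa flags any KRAS/NRAS/BRAF driver mutation, 850 kPa
    flags KRAS specifically, and 857 kPa separates solid from complex
    tubular morphology.
    """

    threshold_any_driver_kpa: float = 803.0
    threshold_kras_kpa: float = 850.0
    threshold_solid_vs_tubular_kpa: float = 857.0

    def __post_init__(self) -> None:
        for name in (
            "threshold_any_driver_kpa",
            "threshold_kras_kpa",
            "threshold_solid_vs_tubular_kpa",
        ):
            if not getattr(self, name) > 520.0:
                raise ParameterError(f"{name} must exceed the 520 kPa tumor floor")


def config_hash(*configs) -> str:
    """Stable short hash over one or more (data)class configurations."""
    payload = []
    for cfg in configs:
        if dataclasses.is_dataclass(cfg) and not isinstance(cfg, type):
            payload.append(dataclasses.asdict(cfg))
        else:
            payload.append(cfg)
    blob = json.dumps(payload, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
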