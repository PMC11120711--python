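"""Synthetic C-OCE phantom: scatterer geometry and the compression forward model.

The phantom is a two-layer medium — a soft pre-calibrated silicone slab on
top of tissue with an arbitrary lateral/axial Young's-modulus field — seeded
with point scatterers dense enough to produce fully developed speckle. The
forward model applies uniaxial compression in a uniform-stress column
approximation (per-layer strain ``eps = P / E``), displaces the scatterers,
and renders complex B-scans by depositing each scatterer's complex amplitude
under a separable Gaussian point-spread function. Interframe phase at depth z
equals ``(4 pi n / lambda0) * du(z)`` up to a global per-frame constant,
which is exactly what the phase-gradient strain estimator inverts.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .config import SystemConfig
from .exceptions import ParameterError

__all__ = [
    "ScattererPhantom",
    "FrameSeries",
    "GroundTruthRecord",
    "build_phantom",
    "simulate_compression_series",
    "uniform_modulus",
    "two_block_modulus",
]

# FWHM of a Gaussian = 2*sqrt(2*ln 2) * sigma
_FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))


def uniform_modulus(modulus_kpa: float) -> Callable:
    """Tissue modulus field constant everywhere."""

    def field_fn(x_um, z_um):
        return np.full(np.broadcast(x_um, z_um).shape, float(modulus_kpa))

    return field_fn


def two_block_modulus(left_kpa: float, right_kpa: float, split_x_um: float) -> Callable:
    """Two lateral blocks of different stiffness split at ``split_x_um``."""

    def field_fn(x_um, z_um):
        x_um, _ = np.broadcast_arrays(np.asarray(x_um, float), np.asarray(z_um, float))
        return np.where(x_um < split_x_um, float(left_kpa), float(right_kpa))

    return field_fn


@dataclass
class ScattererPhantom:
    """Ground-truth geometry and elasticity of the simulated medium.

    ``scatterer_xz_um`` holds (x, z) positions in micrometres with z
    increasing downward from the probe; ``scatterer_amplitude`` the complex
    circular-Gaussian amplitudes (unit-mean exponential intensities), giving
    Rayleigh speckle statistics. ``tissue_modulus_kpa`` is a scalar or a
    vectorized callable ``(x_um, z_um) -> kPa`` describing tissue below the
    silicone layer.
    """

    lateral_extent_mm: float
    depth_extent_mm: float
    silicone_thickness_um: float
    silicone_modulus_kpa: float
    tissue_modulus_kpa: float | Callable
    scatterer_xz_um: np.ndarray
    scatterer_amplitude: np.ndarray
    scatterer_density: float
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.lateral_extent_mm <= 0 or self.depth_extent_mm <= 0:
            raise ParameterError("phantom extents must be > 0")
        if self.silicone_thickness_um >= self.depth_extent_mm * 1000.0:
            raise ParameterError("silicone_thickness_um must be < depth extent")
        if self.silicone_modulus_kpa <= 0:
            raise ParameterError("silicone_modulus_kpa must be > 0")

    @property
    def reflectivity(self) -> np.ndarray:
        """Scatterer intensities |a|^2 (dimensionless, unit mean)."""
        return np.abs(self.scatterer_amplitude) ** 2

    def modulus_at(self, x_um, z_um) -> np.ndarray:
        """Young's modulus (kPa) at positions, silicone layer included."""
        x_um = np.asarray(x_um, float)
        z_um = np.asarray(z_um, float)
        if callable(self.tissue_modulus_kpa):
            tissue = np.asarray(self.tissue_modulus_kpa(x_um, z_um), float)
        else:
            tissue = np.full(np.broadcast(x_um, z_um).shape, float(self.tissue_modulus_kpa))
        if np.any(tissue <= 0):
            raise ParameterError("tissue modulus must be > 0 everywhere")
        return np.where(
            np.broadcast_to(z_um, tissue.shape) < self.silicone_thickness_um,
            self.silicone_modulus_kpa,
            tissue,
        )

    def modulus_grid(self, system: SystemConfig) -> np.ndarray:
        """Modulus sampled at image pixel centres, shape (nz, nx)."""
        z, x = pixel_centers(self, system)
        return self.modulus_at(x[None, :], z[:, None])


def pixel_centers(phantom: ScattererPhantom, system: SystemConfig):
    """Axial and lateral pixel-centre coordinates (um) of the image grid."""
    nz = int(round(phantom.depth_extent_mm * 1000.0 / system.axial_pixel_pitch_um))
    nx = int(round(phantom.lateral_extent_mm * 1000.0 / system.lateral_pixel_pitch_um))
    z = (np.arange(nz) + 0.5) * system.axial_pixel_pitch_um
    x = (np.arange(nx) + 0.5) * system.lateral_pixel_pitch_um
    return z, x


@dataclass
class FrameSeries:
    """Complex OCT B-scans acquired under increasing surface pressure.

    ``frames`` has shape (n_steps, nz, nx); axis 0 follows the compression
    sweep, axis 1 is depth (z, downward), axis 2 lateral position.
    """

    frames: np.ndarray
    surface_pressures_kpa: np.ndarray
    system: SystemConfig
    seed: int | None = None

    def __len__(self) -> int:
        return self.frames.shape[0]

    def save_npz(self, path) -> None:
        import dataclasses as _dc

        np.savez_compressed(
            path,
            frames=self.frames,
            pressures=self.surface_pressures_kpa,
            system_json=np.array(
                __import__("json").dumps(_dc.asdict(self.system))
            ),
            seed=np.array(-1 if self.seed is None else self.seed),
        )

    @classmethod
    def load_npz(cls, path) -> "FrameSeries":
        import json as _json

        with np.load(path, allow_pickle=False) as data:
            system = SystemConfig(**_json.loads(str(data["system_json"])))
            seed = int(data["seed"])
            return cls(
                frames=data["frames"],
                surface_pressures_kpa=data["pressures"],
                system=system,
                seed=None if seed < 0 else seed,
            )


@dataclass
class GroundTruthRecord:
    """Per-step ground truth of the forward model.

    ``strain`` (n_steps, nz, nx) is cumulative compressive strain at each
    pixel, ``displacement_um`` the cumulative axial displacement measured
    from the fixed bottom boundary (zero at the deepest pixel row edge), and
    ``aliased_pairs`` flags consecutive-frame pairs whose phase step across
    one axial resolution cell exceeds pi.
    """

    strain: np.ndarray
    displacement_um: np.ndarray
    surface_pressures_kpa: np.ndarray
    aliased_pairs: list[int] = field(default_factory=list)

    def interframe_strain(self, k: int) -> np.ndarray:
        """Ground-truth strain increment between frames k and k+1."""
        return self.strain[k + 1] - self.strain[k]


def build_phantom(
    lateral_extent_mm: float,
    depth_extent_mm: float,
    silicone_thickness_um: float = 300.0,
    silicone_modulus_kpa: float = 100.0,
    tissue_modulus_kpa: float | Callable = 750.0,
    scatterer_density: float = 10.0,
    system: SystemConfig | None = None,
    seed: int = 0,
) -> ScattererPhantom:
    """Draw a random scatterer phantom.

    The scatterer count is ``round(density * n_resolution_cells)`` with the
    cell area ``axial_resolution * lateral_resolution``; positions are i.i.d.
    uniform over the domain and amplitudes i.i.d. complex circular Gaussian
    with unit-mean intensity. Identical ``seed`` gives an identical phantom.
    """
    system = system or SystemConfig()
    if lateral_extent_mm <= 0 or depth_extent_mm <= 0:
        raise ParameterError("extents must be > 0")
    if scatterer_density < 6:
        warnings.warn(
            "scatterer_density < 6 per resolution cell: speckle may not be "
            "fully developed",
            stacklevel=2,
        )
    area_um2 = lateral_extent_mm * depth_extent_mm * 1e6
    cell_um2 = system.axial_resolution_um * system.lateral_resolution_um
    n = int(round(scatterer_density * area_um2 / cell_um2))
    rng = np.random.default_rng(seed)
    xz = np.empty((n, 2))
    xz[:, 0] = rng.uniform(0.0, lateral_extent_mm * 1000.0, n)
    xz[:, 1] = rng.uniform(0.0, depth_extent_mm * 1000.0, n)
    amp = (rng.standard_normal(n) + 1j * rng.standard_normal(n)) / math.sqrt(2.0)
    return ScattererPhantom(
        lateral_extent_mm=lateral_extent_mm,
        depth_extent_mm=depth_extent_mm,
        silicone_thickness_um=silicone_thickness_um,
        silicone_modulus_kpa=silicone_modulus_kpa,
        tissue_modulus_kpa=tissue_modulus_kpa,
        scatterer_xz_um=xz,
        scatterer_amplitude=amp,
        scatterer_density=scatterer_density,
        seed=seed,
    )


def _cumulative_strain_grid(
    phantom: ScattererPhantom,
    system: SystemConfig,
    surface_pressures_kpa: np.ndarray,
    nonlinear_beta_per_kpa: float,
) -> np.ndarray:
    """Cumulative strain per pixel for every step, shape (n_steps, nz, nx).

    Linear elasticity gives ``eps = P / E``. With the optional
    stress-stiffening toggle the tangent modulus grows with local pressure,
    ``E(P) = E0 * (1 + beta * P)``, and strain is integrated per step using
    the mid-step pressure.
    """
    e0 = phantom.modulus_grid(system)
    pressures = np.asarray(surface_pressures_kpa, float)
    out = np.empty((pressures.size,) + e0.shape)
    if nonlinear_beta_per_kpa == 0:
        for k, p in enumerate(pressures):
            out[k] = p / e0
    else:
        # integrate d(eps) = dP / E(P_mid) from 0, including the first level
        eps = np.zeros_like(e0)
        prev_p = 0.0
        for k, p in enumerate(pressures):
            dp = p - prev_p
            p_mid = 0.5 * (p + prev_p)
            eps = eps + dp / (e0 * (1.0 + nonlinear_beta_per_kpa * p_mid))
            out[k] = eps
            prev_p = p
    return out


def simulate_compression_series(
    phantom: ScattererPhantom,
    system: SystemConfig | None = None,
    surface_pressures_kpa: Sequence[float] = tuple(np.linspace(0.0, 10.0, 21)),
    seed: int = 0,
    snr_db: float | None = 25.0,
    nonlinear_beta_per_kpa: float = 0.0,
) -> tuple[FrameSeries, GroundTruthRecord]:
    """Render the complex frame series for a compression sweep.

    Per step, each layer carries uniaxial strain ``P / E`` (uniform-stress
    column); displacement is the cumulative integral of strain from the
    fixed bottom boundary. Scatterer envelopes are drawn at their optical
    position in the probe frame while the phase factor ``exp(i * 4 pi n /
    lambda0 * u)`` carries the displacement, so the interframe phase at depth
    z unwraps to ``(4 pi n / lambda0) * du(z)`` exactly on noiseless frames.
    Additive complex white Gaussian noise is scaled to ``snr_db`` relative to
    mean signal power (``None`` disables noise).
    """
    system = system or SystemConfig()
    pressures = np.asarray(surface_pressures_kpa, float)
    if pressures.ndim != 1 or pressures.size < 1:
        raise ParameterError("surface_pressures_kpa must be a 1D list")
    if np.any(np.diff(pressures) < 0):
        raise ParameterError("surface_pressures_kpa must be non-decreasing")
    if np.any(pressures < 0):
        raise ParameterError("surface pressures must be >= 0")

    dz = system.axial_pixel_pitch_um
    dx = system.lateral_pixel_pitch_um
    z, x = pixel_centers(phantom, system)
    nz, nx = z.size, x.size

    eps = _cumulative_strain_grid(phantom, system, pressures, nonlinear_beta_per_kpa)
    n_steps = pressures.size

    # displacement from the fixed bottom: u_i = dz * sum_{j >= i} eps_j
    disp = dz * np.flip(np.cumsum(np.flip(eps, axis=1), axis=1), axis=1)
    # top-down compression integral (for probe-frame optical position)
    topdown = dz * (np.cumsum(eps, axis=1) - eps)  # integral_0^{z_i - dz/2}

    # aliasing check: interframe phase step across one axial resolution cell
    aliased = []
    for k in range(n_steps - 1):
        d_eps = np.max(np.abs(eps[k + 1] - eps[k]))
        if d_eps * system.phase_per_um * system.axial_resolution_um > math.pi:
            aliased.append(k)
    if aliased:
        warnings.warn(
            f"compression steps {aliased} exceed the phase-aliasing limit",
            stacklevel=2,
        )

    sx = phantom.scatterer_xz_um[:, 0]
    sz = phantom.scatterer_xz_um[:, 1]
    amp = phantom.scatterer_amplitude
    sigma_z = system.axial_resolution_um / system.refractive_index * _FWHM_TO_SIGMA
    sigma_x = system.lateral_resolution_um * _FWHM_TO_SIGMA
    rz = max(1, int(math.ceil(3.0 * sigma_z / dz)))
    rx = max(1, int(math.ceil(3.0 * sigma_x / dx)))

    col = np.clip((sx / dx - 0.5).round().astype(int), 0, nx - 1)
    row = np.clip((sz / dz - 0.5).round().astype(int), 0, nz - 1)

    frames = np.zeros((n_steps, nz, nx), np.complex128)
    rng = np.random.default_rng(seed)
    for k in range(n_steps):
        # interpolate cumulative fields at scatterer positions (per column)
        u_s = disp[k][row, col] + (z[row] - sz) * eps[k][row, col]
        c_s = topdown[k][row, col] + (sz - (z[row] - dz / 2.0)) * eps[k][row, col]
        z_opt = sz - c_s  # optical depth in the probe frame
        phase = np.exp(1j * system.phase_per_um * u_s)
        a = amp * phase
        pz = z_opt / dz - 0.5
        px = sx / dx - 0.5
        iz0 = np.round(pz).astype(int)
        ix0 = np.round(px).astype(int)
        frame = frames[k]
        for dzi in range(-rz, rz + 1):
            izi = iz0 + dzi
            wz = np.exp(-((izi - pz) * dz) ** 2 / (2.0 * sigma_z**2))
            ok_z = (izi >= 0) & (izi < nz)
            for dxi in range(-rx, rx + 1):
                ixi = ix0 + dxi
                w = wz * np.exp(-((ixi - px) * dx) ** 2 / (2.0 * sigma_x**2))
                ok = ok_z & (ixi >= 0) & (ixi < nx)
                np.add.at(frame, (izi[ok], ixi[ok]), a[ok] * w[ok])
        if snr_db is not None:
            p_sig = np.mean(np.abs(frame) ** 2)
            sigma_n = math.sqrt(p_sig / (10.0 ** (snr_db / 10.0)) / 2.0)
            frame += sigma_n * (
                rng.standard_normal(frame.shape) + 1j * rng.standard_normal(frame.shape)
            )

    series = FrameSeries(
        frames=frames, surface_pressures_kpa=pressures, system=system, seed=seed
    )
    truth = GroundTruthRecord(
        strain=eps,
        displacement_um=disp,
        surface_pressures_kpa=pressures,
        aliased_pairs=aliased,
    )
    return series, truth
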