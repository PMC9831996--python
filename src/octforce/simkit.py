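"""Synthetic OCT phantom and elastography data generator.

Emulates the data produced by a swept-source OCT setup used for tool-tissue
force estimation experiments: gelatin phantoms of graded stiffness (and a
heterogeneous tissue-like material class), complex-valued B-scan sequences
carrying a continuously excited shear wave, volumetric palpation image
series with an indenting tool, and an asynchronously sampled force stream.

Physics is deliberately first-order: shear waves are damped travelling
sinusoids in the OCT phase at speed ``c = sqrt(E / 3 rho)`` (incompressible
medium), contact follows a Hertzian sphere law, and OCT speckle is a
smoothed exponential intensity field.  All generators are pure functions of
their specification plus a seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = [
    "DENSITY_KG_M3",
    "GELATIN_CONCENTRATIONS",
    "MaterialSpec",
    "ScanGeometry",
    "ExcitationSpec",
    "ToolTrajectory",
    "ComplexBScanSequence",
    "PalpationRecord",
    "modulus_from_concentration",
    "shear_wave_speed_from_modulus",
    "make_material",
    "sinusoidal_trajectory",
    "random_steps_trajectory",
    "force_from_indentation",
    "indentation_from_force",
    "simulate_swei_sequence",
    "simulate_palpation",
]

#: Assumed phantom density [kg m^-3] (water-like gelatin).
DENSITY_KG_M3 = 1000.0

#: The seven gelatin weight ratios of the phantom study.
GELATIN_CONCENTRATIONS = (0.05, 0.075, 0.10, 0.125, 0.15, 0.175, 0.20)

# Calibration anchors of the concentration -> Young's modulus map:
# 5 % w/w -> 17.42 kPa and 15 % w/w -> 56.04 kPa.  The map interpolates
# linearly between the anchors and extrapolates linearly beyond them.
_E_ANCHORS = ((0.05, 17420.0), (0.15, 56040.0))


def modulus_from_concentration(concentration: float) -> float:
    """Young's modulus [Pa] of a gelatin gel at a given weight ratio."""
    (c0, e0), (c1, e1) = _E_ANCHORS
    slope = (e1 - e0) / (c1 - c0)
    return e0 + slope * (concentration - c0)


def shear_wave_speed_from_modulus(youngs_modulus: float,
                                  density: float = DENSITY_KG_M3) -> float:
    """Shear wave speed ``c = sqrt(E / 3 rho)`` [m s^-1].

    Uses the incompressible approximation (Poisson ratio 0.5) so that the
    shear modulus is ``G = E / 3``.
    """
    return math.sqrt(youngs_modulus / (3.0 * density))


@dataclass(frozen=True)
class MaterialSpec:
    """Mechanical and optical description of one sample material."""

    material_id: str
    material_class: str  # "gelatin" | "tissue_like"
    youngs_modulus: float  # Pa
    density: float = DENSITY_KG_M3  # kg m^-3
    shear_wave_speed: float = 0.0  # m s^-1, consistent with modulus
    concentration: float | None = None  # w/w fraction, gelatin only
    heterogeneity_scale: float = 0.0  # 0 = homogeneous
    speckle_contrast: float = 1.0

    def __post_init__(self) -> None:
        if self.material_class not in ("gelatin", "tissue_like"):
            raise ValueError(f"unknown material class {self.material_class!r}")
        if self.youngs_modulus <= 0:
            raise ValueError("youngs_modulus must be positive")
        if self.density <= 0:
            raise ValueError("density must be positive")
        if self.heterogeneity_scale < 0:
            raise ValueError("heterogeneity_scale must be >= 0")
        expected = shear_wave_speed_from_modulus(self.youngs_modulus, self.density)
        if not math.isclose(self.shear_wave_speed, expected, rel_tol=1e-9):
            raise ValueError(
                "shear_wave_speed inconsistent with modulus: "
                f"{self.shear_wave_speed} vs sqrt(E/3rho)={expected}"
            )


def make_material(
    material_class: str,
    concentration: float | None = None,
    youngs_modulus: float | None = None,
    density: float = DENSITY_KG_M3,
    seed: int | None = None,
    material_id: str | None = None,
    heterogeneity_scale: float | None = None,
    speckle_contrast: float | None = None,
) -> MaterialSpec:
    """Create a :class:`MaterialSpec`.

    Gelatin materials take their modulus from the calibrated
    concentration map unless an explicit ``youngs_modulus`` is given.
    Tissue-like materials draw a per-sample modulus from a lognormal
    centred on 18 kPa (soft muscle range) using ``seed``, and default to a
    heterogeneous, roughened appearance.
    """
    if material_class == "gelatin":
        if youngs_modulus is None:
            if concentration is None:
                raise ValueError("gelatin needs a concentration or a modulus")
            youngs_modulus = modulus_from_concentration(concentration)
        het = 0.0 if heterogeneity_scale is None else heterogeneity_scale
        spk = 1.0 if speckle_contrast is None else speckle_contrast
        mid = material_id or (
            f"gel_{concentration*100:g}pct" if concentration is not None
            else f"gel_E{youngs_modulus:.0f}"
        )
    elif material_class == "tissue_like":
        if youngs_modulus is None:
            rng = np.random.default_rng(seed)
            # lognormal around 18 kPa, ~20 % spread
            youngs_modulus = float(18e3 * np.exp(rng.normal(0.0, 0.2)))
        het = 0.3 if heterogeneity_scale is None else heterogeneity_scale
        spk = 1.3 if speckle_contrast is None else speckle_contrast
        mid = material_id or f"tissue_{seed if seed is not None else 0}"
    else:
        raise ValueError(f"unknown material class {material_class!r}")
    if youngs_modulus <= 0:
        raise ValueError("youngs_modulus must be positive")
    return MaterialSpec(
        material_id=mid,
        material_class=material_class,
        youngs_modulus=float(youngs_modulus),
        density=density,
        shear_wave_speed=shear_wave_speed_from_modulus(youngs_modulus, density),
        concentration=concentration,
        heterogeneity_scale=het,
        speckle_contrast=spk,
    )


@dataclass(frozen=True)
class ScanGeometry:
    """Pixel grids, physical extents and sampling rates of the scanner."""

    depth_px: int
    lateral_w_px: int
    lateral_d_px: int | None  # None for 2D+T B-scan sequences
    depth_extent_mm: float
    lateral_extent_w_mm: float
    lateral_extent_d_mm: float | None
    bscan_rate_hz: float
    volume_rate_hz: float
    force_rate_hz: float = 500.0

    def __post_init__(self) -> None:
        for name in ("depth_px", "lateral_w_px"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("depth_extent_mm", "lateral_extent_w_mm",
                     "bscan_rate_hz", "volume_rate_hz", "force_rate_hz"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def axial_pitch_mm(self) -> float:
        return self.depth_extent_mm / self.depth_px

    @property
    def lateral_pitch_w_mm(self) -> float:
        return self.lateral_extent_w_mm / self.lateral_w_px

    @property
    def lateral_pitch_d_mm(self) -> float:
        if self.lateral_d_px is None or self.lateral_extent_d_mm is None:
            raise ValueError("geometry has no d axis")
        return self.lateral_extent_d_mm / self.lateral_d_px

    @classmethod
    def default_swei(cls, depth_px: int = 476, depth_extent_mm: float = 3.5,
                     bscan_rate_hz: float = 14200.0) -> "ScanGeometry":
        """SWEI B-scan geometry: 476 x 32 px over 3.5 x 3 mm at 14.2 kHz."""
        return cls(depth_px=depth_px, lateral_w_px=32, lateral_d_px=None,
                   depth_extent_mm=depth_extent_mm, lateral_extent_w_mm=3.0,
                   lateral_extent_d_mm=None, bscan_rate_hz=bscan_rate_hz,
                   volume_rate_hz=833.0)

    @classmethod
    def default_volume(cls) -> "ScanGeometry":
        """Palpation volume geometry: 476 x 32 x 32 px over 3.5 x 3 x 3 mm at 833 Hz."""
        return cls(depth_px=476, lateral_w_px=32, lateral_d_px=32,
                   depth_extent_mm=3.5, lateral_extent_w_mm=3.0,
                   lateral_extent_d_mm=3.0, bscan_rate_hz=14200.0,
                   volume_rate_hz=833.0)


@dataclass(frozen=True)
class ExcitationSpec:
    """Continuous sinusoidal shear-wave excitation at the sample surface."""

    frequency_hz: float = 1000.0
    duration_s: float = 0.8
    amplitude_rad: float = 0.5  # peak phase modulation at the source
    attenuation_length_mm: float = 3.0  # inf -> no lateral damping

    def __post_init__(self) -> None:
        if self.frequency_hz <= 0:
            raise ValueError("frequency must be positive")
        if self.duration_s <= 0:
            raise ValueError("duration must be positive")


@dataclass(frozen=True)
class ToolTrajectory:
    """Tool insertion-depth profile delta(t) [mm] over ``duration_s``.

    ``depth_profile`` accepts an array of times [s] and returns depths [mm];
    it is zero at t = 0, continuous and non-negative, and clamped to zero
    outside [0, duration].
    """

    kind: str  # "sinusoidal" | "random_steps"
    depth_profile: Callable[[np.ndarray], np.ndarray] | None
    duration_s: float
    max_depth_mm: float
    velocity_range_mm_s: tuple[float, float]
    n_cycles: int | None = None
    n_positions: int | None = None
    contact_threshold_n: float = 0.01
    seed: int | None = None

    def depths(self, t: np.ndarray) -> np.ndarray:
        if self.depth_profile is None:
            raise ValueError("trajectory carries metadata only (no profile)")
        t = np.asarray(t, dtype=float)
        d = self.depth_profile(np.clip(t, 0.0, self.duration_s))
        return np.where((t < 0) | (t > self.duration_s), 0.0, d)


def sinusoidal_trajectory(
    max_depth_mm: float = 2.5,
    n_cycles: int = 3,
    velocity_range_mm_s: tuple[float, float] = (0.5, 3.0),
    seed: int = 0,
) -> ToolTrajectory:
    """Training-style palpation: ``n_cycles`` raised-cosine indentation cycles.

    Each cycle's period is drawn so its peak insertion velocity
    ``pi * max_depth / T`` is uniform in ``velocity_range_mm_s``.
    """
    rng = np.random.default_rng(seed)
    v_peak = rng.uniform(*velocity_range_mm_s, size=n_cycles)
    periods = np.pi * max_depth_mm / v_peak
    bounds = np.concatenate([[0.0], np.cumsum(periods)])

    def profile(t: np.ndarray) -> np.ndarray:
        idx = np.clip(np.searchsorted(bounds, t, side="right") - 1, 0, n_cycles - 1)
        local = (t - bounds[idx]) / periods[idx]
        return 0.5 * max_depth_mm * (1.0 - np.cos(2.0 * np.pi * local))

    return ToolTrajectory(
        kind="sinusoidal", depth_profile=profile, duration_s=float(bounds[-1]),
        max_depth_mm=max_depth_mm, velocity_range_mm_s=velocity_range_mm_s,
        n_cycles=n_cycles, seed=seed,
    )


def random_steps_trajectory(
    n_positions: int = 20,
    depth_range_mm: tuple[float, float] = (0.5, 2.5),
    velocity_range_mm_s: tuple[float, float] = (2.0, 7.0),
    dwell_s: float = 0.05,
    seed: int = 0,
) -> ToolTrajectory:
    """Test-style palpation: constant-velocity moves to random target depths."""
    rng = np.random.default_rng(seed)
    targets = rng.uniform(*depth_range_mm, size=n_positions)
    velocities = rng.uniform(*velocity_range_mm_s, size=n_positions)
    knots_t = [0.0]
    knots_d = [0.0]
    for d, v in zip(targets, velocities):
        travel = abs(d - knots_d[-1]) / v
        knots_t.append(knots_t[-1] + travel)
        knots_d.append(float(d))
        knots_t.append(knots_t[-1] + dwell_s)
        knots_d.append(float(d))
    kt = np.asarray(knots_t)
    kd = np.asarray(knots_d)

    def profile(t: np.ndarray) -> np.ndarray:
        return np.interp(t, kt, kd)

    return ToolTrajectory(
        kind="random_steps", depth_profile=profile, duration_s=float(kt[-1]),
        max_depth_mm=float(depth_range_mm[1]),
        velocity_range_mm_s=velocity_range_mm_s,
        n_positions=n_positions, seed=seed,
    )


# ---------------------------------------------------------------------------
# Contact mechanics
# ---------------------------------------------------------------------------

def force_from_indentation(
    material: MaterialSpec,
    indentation_depth_mm: float | np.ndarray,
    tool_radius_mm: float = 1.0,
    poisson_ratio: float = 0.5,
) -> float | np.ndarray:
    """Hertzian sphere contact force [N] at indentation depth [mm].

    ``F = (4/3) * E / (1 - nu^2) * sqrt(R) * delta^(3/2)`` with the tool tip
    modelled as a sphere of radius ``tool_radius_mm``.
    """
    delta = np.asarray(indentation_depth_mm, dtype=float)
    if np.any(delta < 0):
        raise ValueError("indentation depth must be non-negative")
    e_star = material.youngs_modulus / (1.0 - poisson_ratio**2)
    f = (4.0 / 3.0) * e_star * math.sqrt(tool_radius_mm * 1e-3) * (delta * 1e-3) ** 1.5
    return float(f) if np.isscalar(indentation_depth_mm) else f


def indentation_from_force(
    material: MaterialSpec,
    force_n: float | np.ndarray,
    tool_radius_mm: float = 1.0,
    poisson_ratio: float = 0.5,
) -> float | np.ndarray:
    """Inverse of :func:`force_from_indentation`; returns depth [mm]."""
    f = np.asarray(force_n, dtype=float)
    if np.any(f < 0):
        raise ValueError("force must be non-negative")
    e_star = material.youngs_modulus / (1.0 - poisson_ratio**2)
    delta_m = (3.0 * f / (4.0 * e_star * math.sqrt(tool_radius_mm * 1e-3))) ** (2.0 / 3.0)
    out = delta_m * 1e3
    return float(out) if np.isscalar(force_n) else out


# ---------------------------------------------------------------------------
# Speckle
# ---------------------------------------------------------------------------

def _speckle(shape: tuple[int, ...], rng: np.random.Generator,
             corr_px: float = 1.5, contrast: float = 1.0) -> np.ndarray:
    """Smoothed exponential-intensity speckle field, mean ~1, min clipped."""
    raw = rng.exponential(1.0, size=shape)
    smooth = gaussian_filter(raw, sigma=corr_px)
    smooth /= smooth.mean()
    out = 1.0 + contrast * (smooth - 1.0)
    return np.clip(out, 0.05, None)


# ---------------------------------------------------------------------------
# SWEI B-scan sequences
# ---------------------------------------------------------------------------

@dataclass
class ComplexBScanSequence:
    """Complex 2D+T OCT data whose phase encodes axial shear-wave motion.

    ``data`` has shape (depth, lateral_w, time), complex64.
    ``surface_depth_px`` gives the sample surface row per lateral position.
    """

    data: np.ndarray
    geometry: ScanGeometry
    excitation: ExcitationSpec
    surface_depth_px: np.ndarray | None = None

    @property
    def n_time(self) -> int:
        return self.data.shape[2]


MIN_SWEI_SAMPLES = 800


def swei_phase_field(
    material: MaterialSpec,
    geometry: ScanGeometry,
    excitation: ExcitationSpec,
    n_time: int | None = None,
) -> np.ndarray:
    """Analytic phase [rad] of the travelling shear wave, shape (w, time).

    ``phi(x, t) = A exp(-x / L) sin(2 pi f (t - x / c))`` with lateral
    position x [m], wave speed c from the material, and damping length L.
    Used both by the generator and as the oracle in unwrapping tests.
    """
    if n_time is None:
        n_time = int(round(excitation.duration_s * geometry.bscan_rate_hz))
    x = np.arange(geometry.lateral_w_px) * geometry.lateral_pitch_w_mm * 1e-3
    t = np.arange(n_time) / geometry.bscan_rate_hz
    c = material.shear_wave_speed
    f = excitation.frequency_hz
    if math.isinf(excitation.attenuation_length_mm):
        env = np.ones_like(x)
    else:
        env = np.exp(-x / (excitation.attenuation_length_mm * 1e-3))
    return (excitation.amplitude_rad * env[:, None]
            * np.sin(2.0 * np.pi * f * (t[None, :] - x[:, None] / c)))


def simulate_swei_sequence(
    material: MaterialSpec,
    geometry: ScanGeometry | None = None,
    excitation: ExcitationSpec | None = None,
    noise_snr_db: float | None = 20.0,
    seed: int = 0,
    surface_depth_px: int = 8,
    surface_tilt_px: float = 0.0,
) -> ComplexBScanSequence:
    """Simulate a complex B-scan sequence with a forward-travelling shear wave.

    ``noise_snr_db=None`` produces a noiseless sequence.  The wave phase is
    applied below the surface only; magnitude carries static speckle with a
    bright surface line so the surface is detectable by maximum intensity.
    """
    geometry = geometry or ScanGeometry.default_swei()
    excitation = excitation or ExcitationSpec()
    if noise_snr_db is not None and not math.isfinite(noise_snr_db):
        raise ValueError("noise SNR must be finite (or None for noiseless)")
    n_time = int(round(excitation.duration_s * geometry.bscan_rate_hz))
    if n_time < MIN_SWEI_SAMPLES:
        raise ValueError(
            f"duration*bscan_rate = {n_time} < {MIN_SWEI_SAMPLES} samples"
        )
    h, w = geometry.depth_px, geometry.lateral_w_px
    surf = np.round(surface_depth_px + surface_tilt_px * np.arange(w)).astype(int)
    if np.any(surf < 0) or np.any(surf >= h):
        raise ValueError("surface outside depth range")

    rng = np.random.default_rng(seed)
    z = np.arange(h)[:, None]
    below = z >= surf[None, :]
    mag = 0.02 + 0.9 * below * _speckle((h, w), rng,
                                        contrast=material.speckle_contrast)
    mag[surf, np.arange(w)] *= 3.0  # specular surface reflection

    phase = swei_phase_field(material, geometry, excitation, n_time)  # (w, T)
    data = (mag[:, :, None].astype(np.float32)
            * np.exp(1j * (below[:, :, None] * phase[None, :, :])).astype(np.complex64))

    if noise_snr_db is not None:
        sig_power = float(np.mean(np.abs(data) ** 2))
        noise_power = sig_power / (10.0 ** (noise_snr_db / 10.0))
        scale = math.sqrt(noise_power / 2.0)
        noise = (rng.standard_normal(data.shape) +
                 1j * rng.standard_normal(data.shape)).astype(np.complex64)
        data = data + scale * noise

    return ComplexBScanSequence(
        data=data.astype(np.complex64), geometry=geometry,
        excitation=excitation, surface_depth_px=surf,
    )


# ---------------------------------------------------------------------------
# Palpation volume sequences
# ---------------------------------------------------------------------------

@dataclass
class PalpationRecord:
    """One (sample, location) palpation episode.

    Volumes are intensity arrays (depth, w, d); the reference volume is
    rendered at zero indentation (zero force) before the palpation starts.
    Force and volume streams have independent, jittered timestamp origins.
    """

    sample_id: str
    location_id: str
    material: MaterialSpec
    geometry: ScanGeometry
    volume_timestamps: np.ndarray  # (T,) s
    volumes: np.ndarray  # (T, h, w, d) float32
    reference_timestamp: float
    reference_volume: np.ndarray  # (h, w, d) float32
    force_timestamps: np.ndarray  # (N,) s
    forces: np.ndarray  # (N,) Newton, non-negative along the tool axis
    trajectory: ToolTrajectory
    rng_seed: int
    swei_sequence: ComplexBScanSequence | None = None
    phase_velocity: float | None = None  # optional cached SWEI estimate

    @property
    def record_id(self) -> str:
        return f"{self.sample_id}/{self.location_id}/{self.trajectory.kind}"


def _surface_height_field(material: MaterialSpec, w: int, d: int,
                          base_px: float, rng: np.random.Generator) -> np.ndarray:
    """Resting surface depth [px] per lateral position (rough if heterogeneous)."""
    h0 = np.full((w, d), base_px, dtype=float)
    if material.heterogeneity_scale > 0:
        rough = gaussian_filter(rng.standard_normal((w, d)), sigma=2.0)
        rough /= max(np.abs(rough).max(), 1e-9)
        h0 += material.heterogeneity_scale * 12.0 * rough
    return h0


def simulate_palpation(
    material: MaterialSpec,
    geometry: ScanGeometry,
    trajectory: ToolTrajectory,
    noise: float = 0.02,
    seed: int | None = 0,
    sample_id: str = "S0",
    location_id: str = "L0",
    surface_depth_mm: float = 0.5,
    bowl_sigma_mm: float = 0.75,
    tool_radius_mm: float = 1.0,
    with_swei: bool = False,
    swei_geometry: ScanGeometry | None = None,
    excitation: ExcitationSpec | None = None,
    swei_snr_db: float = 20.0,
) -> PalpationRecord:
    """Render a palpation episode: volumes, reference, and force stream.

    The sample surface indents under the tool with a Gaussian-bowl profile
    (depth = trajectory indentation on the tool axis, width ``bowl_sigma_mm``)
    and the sub-surface speckle column translates with the surface.  Forces
    follow the Hertzian contact law sampled on the 500 Hz force clock.
    """
    if geometry.lateral_d_px is None:
        raise ValueError("palpation needs a volumetric geometry")
    if trajectory.max_depth_mm + surface_depth_mm >= geometry.depth_extent_mm:
        raise ValueError("trajectory exceeds the imaging depth")
    if noise > 0 and seed is None:
        raise ValueError("a seed is required when noise > 0")
    rng = np.random.default_rng(seed)

    h, w, d = geometry.depth_px, geometry.lateral_w_px, geometry.lateral_d_px
    ax_pitch = geometry.axial_pitch_mm
    base_px = surface_depth_mm / ax_pitch
    h0 = _surface_height_field(material, w, d, base_px, rng)

    # static per-column texture: dark above the surface, bright surface
    # line, speckled bulk beneath
    z = np.arange(h, dtype=float)[:, None, None]
    below = z >= h0[None, :, :]
    spk = _speckle((h, w, d), rng, contrast=material.speckle_contrast)
    surface_line = np.exp(-0.5 * ((z - h0[None, :, :]) / 1.0) ** 2)
    tex = (0.03 + 0.55 * below * spk + 0.9 * surface_line).astype(np.float32)

    # Gaussian indentation bowl around the tool axis (FOV centre)
    wy = (np.arange(w) - (w - 1) / 2.0) * geometry.lateral_pitch_w_mm
    dy = (np.arange(d) - (d - 1) / 2.0) * geometry.lateral_pitch_d_mm
    bowl = np.exp(-(wy[:, None] ** 2 + dy[None, :] ** 2) / (2.0 * bowl_sigma_mm**2))

    wi = np.arange(w)[None, :, None]
    di = np.arange(d)[None, None, :]

    def render(shift_px: float, vol_rng: np.random.Generator) -> np.ndarray:
        zq = z - shift_px * bowl[None, :, :]
        zq = np.clip(zq, 0.0, h - 1.000001)
        z0 = zq.astype(int)
        frac = (zq - z0).astype(np.float32)
        vol = tex[z0, wi, di] * (1.0 - frac) + tex[z0 + 1, wi, di] * frac
        if noise > 0:
            vol = vol + vol_rng.normal(0.0, noise, size=vol.shape).astype(np.float32)
        return np.clip(vol, 0.0, None).astype(np.float32)

    # asynchronous clocks with jittered origins so force labels need
    # genuine interpolation
    t0_vol = rng.uniform(0.0, 1.0 / geometry.volume_rate_hz)
    n_vol = max(1, int(np.floor((trajectory.duration_s - t0_vol)
                                * geometry.volume_rate_hz)) + 1)
    vol_t = t0_vol + np.arange(n_vol) / geometry.volume_rate_hz

    t0_force = -0.2 + rng.uniform(0.0, 1.0 / geometry.force_rate_hz)
    n_force = int(np.ceil((trajectory.duration_s + 0.4) * geometry.force_rate_hz))
    force_t = t0_force + np.arange(n_force) / geometry.force_rate_hz
    forces = force_from_indentation(material, trajectory.depths(force_t),
                                    tool_radius_mm=tool_radius_mm)

    ref_t = float(force_t[0])
    reference = render(0.0, rng)
    shifts_px = trajectory.depths(vol_t) / ax_pitch
    volumes = np.stack([render(s, rng) for s in shifts_px])

    swei_seq = None
    if with_swei:
        child = int(rng.integers(0, 2**31 - 1))
        swei_seq = simulate_swei_sequence(
            material, swei_geometry or ScanGeometry.default_swei(),
            excitation or ExcitationSpec(), noise_snr_db=swei_snr_db, seed=child,
        )

    return PalpationRecord(
        sample_id=sample_id, location_id=location_id, material=material,
        geometry=geometry, volume_timestamps=vol_t, volumes=volumes,
        reference_timestamp=ref_t, reference_volume=reference,
        force_timestamps=force_t, forces=np.asarray(forces),
        trajectory=trajectory, rng_seed=seed if seed is not None else -1,
        swei_sequence=swei_seq,
    )
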