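"""Shear-wave phase-velocity estimation from complex B-scan sequences.

The estimator follows the k-space dominant-component approach: crop a band
of pixels beneath the sample surface, temporally unwrap the phase of the
complex OCT signal, average over depth to obtain a 2D space-time phase map,
and for randomly sampled temporal subsets locate the dominant component of
the 2D Fourier transform.  The phase velocity is ``v = f / k`` at the peak,
with wavenumber k in cycles per metre so no 2-pi factor appears; the
reported velocity is the mean over all subsets.

Zero-padding the DFT (time axis to 4096, lateral axis to 256 by default)
interpolates the spectrum: the raw lateral axis has only 32 px over 3 mm,
a wavenumber quantisation of 333 m^-1 that would dominate the velocity
error otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .simkit import ComplexBScanSequence, MIN_SWEI_SAMPLES

__all__ = [
    "SweiError",
    "SweiParams",
    "SpaceTimePhaseMap",
    "KSpace",
    "PhaseVelocityEstimate",
    "crop_beneath_surface",
    "detect_surface",
    "unwrap_and_average",
    "sample_subsets",
    "compute_kspace",
    "filter_kspace",
    "peak_velocity",
    "estimate_phase_velocity",
    "velocity_bin_tolerance",
]


class SweiError(RuntimeError):
    """Raised when the estimator cannot produce a velocity."""


@dataclass(frozen=True)
class SweiParams:
    """Tunable parameters of the phase-velocity estimator."""

    crop_px: int = 32
    n_subsets: int = 30
    subset_length: int = 800
    pad_time: int = 4096
    pad_lateral: int = 256
    highpass_hz: float = 100.0
    velocity_range_m_s: tuple[float, float] = (0.5, 15.0)
    threshold_frac: float = 0.10
    flip_propagation: bool = False  # set for waves travelling along -w


@dataclass
class SpaceTimePhaseMap:
    """Depth-averaged unwrapped phase, shape (lateral_w, time)."""

    phase: np.ndarray  # radians
    lateral_pitch_m: float
    dt_s: float

    @property
    def n_time(self) -> int:
        return self.phase.shape[1]


@dataclass
class KSpace:
    """Amplitude spectrum over (temporal frequency, wavenumber).

    Axes are restricted to the quadrant of the forward-travelling wave;
    ``k_axis`` is in cycles per metre, ascending.
    """

    amplitude: np.ndarray  # (n_f, n_k), >= 0
    f_axis: np.ndarray  # Hz, ascending, > 0
    k_axis: np.ndarray  # m^-1, ascending, > 0
    filters_applied: list[str] = field(default_factory=list)


@dataclass
class PhaseVelocityEstimate:
    """Mean phase velocity over subsets, with the per-subset spread kept."""

    velocity: float  # m s^-1, mean of subset_velocities
    subset_velocities: list[float]
    peak_f: float  # Hz, from the first evaluated subset
    peak_k: float  # m^-1
    n_subsets: int
    subset_length: int
    seed: int


def detect_surface(seq: ComplexBScanSequence) -> np.ndarray:
    """Surface row per lateral position via time-averaged maximum intensity."""
    mag = np.abs(seq.data).mean(axis=2)  # (h, w)
    if np.any(mag.max(axis=0) == 0):
        raise SweiError("surface undetectable: all-zero magnitude column")
    return np.argmax(mag, axis=0)


def crop_beneath_surface(seq: ComplexBScanSequence, crop_px: int = 32) -> ComplexBScanSequence:
    """Keep ``crop_px`` rows beneath the (possibly tilted) surface per column."""
    surf = seq.surface_depth_px
    if surf is None:
        surf = detect_surface(seq)
    surf = np.asarray(surf, dtype=int)
    h = seq.data.shape[0]
    if np.any(surf + crop_px > h):
        raise SweiError(
            f"surface too deep to crop {crop_px} px (max surface {surf.max()}, depth {h})"
        )
    rows = surf[None, :] + np.arange(crop_px)[:, None]  # (crop, w)
    cols = np.arange(seq.data.shape[1])[None, :]
    cropped = seq.data[rows, cols, :]
    return ComplexBScanSequence(
        data=cropped, geometry=seq.geometry, excitation=seq.excitation,
        surface_depth_px=np.zeros_like(surf),
    )


def _fill_zero_magnitude(data: np.ndarray) -> np.ndarray:
    """Linearly interpolate zero-magnitude samples along time (in-phase/quadrature)."""
    zero = np.abs(data) == 0
    if not zero.any():
        return data
    out = data.copy()
    t = np.arange(data.shape[-1])
    bad_pixels = np.argwhere(zero.any(axis=-1))
    for z, x in bad_pixels:
        series = out[z, x]
        good = ~zero[z, x]
        if not good.any():
            raise SweiError(f"angle undefined: all-zero pixel ({z}, {x})")
        re = np.interp(t, t[good], series.real[good])
        im = np.interp(t, t[good], series.imag[good])
        out[z, x] = re + 1j * im
    return out


def unwrap_and_average(seq: ComplexBScanSequence) -> SpaceTimePhaseMap:
    """Temporally unwrap the phase per pixel, then average along depth."""
    if seq.n_time < 2:
        raise SweiError("need at least 2 time samples")
    data = _fill_zero_magnitude(seq.data)
    phase = np.unwrap(np.angle(data), axis=-1)
    mean_phase = phase.mean(axis=0)  # (w, time)
    return SpaceTimePhaseMap(
        phase=mean_phase,
        lateral_pitch_m=seq.geometry.lateral_pitch_w_mm * 1e-3,
        dt_s=1.0 / seq.geometry.bscan_rate_hz,
    )


def sample_subsets(
    phase_map: SpaceTimePhaseMap,
    n_subsets: int = 30,
    subset_length: int = 800,
    seed: int = 0,
) -> list[SpaceTimePhaseMap]:
    """Contiguous temporal windows with uniform start indices (with replacement)."""
    n_t = phase_map.n_time
    if n_t < subset_length:
        raise SweiError(f"sequence length {n_t} < subset length {subset_length}")
    rng = np.random.default_rng(seed)
    starts = rng.integers(0, n_t - subset_length + 1, size=n_subsets)
    return [
        SpaceTimePhaseMap(
            phase=phase_map.phase[:, s:s + subset_length],
            lateral_pitch_m=phase_map.lateral_pitch_m, dt_s=phase_map.dt_s,
        )
        for s in starts
    ]


def compute_kspace(
    subset: SpaceTimePhaseMap,
    pad_time: int = 4096,
    pad_lateral: int = 256,
    flip_propagation: bool = False,
) -> KSpace:
    """2D DFT amplitude of the space-time phase, forward-wave quadrant only.

    A wave ``sin(2 pi (f t - k x))`` travelling along +w appears at
    (+f, -k) under the numpy FFT sign convention; that quadrant is
    extracted and its wavenumbers reported as positive magnitudes.
    """
    if not np.all(np.isfinite(subset.phase)):
        raise SweiError("phase map contains non-finite values")
    arr = subset.phase.T  # (time, lateral)
    arr = arr - arr.mean()
    nt = max(pad_time, arr.shape[0])
    nx = max(pad_lateral, arr.shape[1])
    # the phase map is real, so A(f, -k) = conj A(-f, k): the half-spectrum
    # from an rFFT along the lateral axis carries both quadrants
    spec = np.fft.fft(np.fft.rfft(arr, n=nx, axis=1), n=nt, axis=0)
    f_full = np.fft.fftfreq(nt, d=subset.dt_s)
    k_half = np.fft.rfftfreq(nx, d=subset.lateral_pitch_m)

    k_idx = np.arange(1, (nx + 1) // 2)  # k > 0, Nyquist excluded
    k_axis = k_half[k_idx]
    if flip_propagation:
        f_idx = np.where(f_full > 0)[0]
        f_axis = f_full[f_idx]
    else:
        # forward wave sits at (f > 0, k < 0) == conj of (f < 0, k > 0)
        f_idx = np.where(f_full < 0)[0][::-1]
        f_axis = -f_full[f_idx]
    amp = np.abs(spec[np.ix_(f_idx, k_idx)])
    return KSpace(amplitude=amp, f_axis=f_axis, k_axis=k_axis,
                  filters_applied=[])


def filter_kspace(
    kspace: KSpace,
    highpass_hz: float = 100.0,
    velocity_range_m_s: tuple[float, float] = (0.5, 15.0),
    threshold_frac: float = 0.10,
) -> KSpace:
    """High-pass, admissible-velocity sector, and relative-amplitude threshold.

    Bins with |f| below the cutoff, with f/k outside the velocity sector, or
    with amplitude below ``threshold_frac`` of the running maximum are zeroed.
    """
    if kspace.filters_applied:
        raise SweiError("filters already applied to this k-space")
    v_min, v_max = velocity_range_m_s
    if v_min >= v_max:
        raise SweiError("empty velocity sector (v_min >= v_max)")
    amp = kspace.amplitude.copy()
    amp[np.abs(kspace.f_axis) < highpass_hz, :] = 0.0
    v = kspace.f_axis[:, None] / kspace.k_axis[None, :]
    amp[(v < v_min) | (v > v_max)] = 0.0
    peak = amp.max()
    if peak > 0:
        amp[amp < threshold_frac * peak] = 0.0
    return KSpace(
        amplitude=amp, f_axis=kspace.f_axis, k_axis=kspace.k_axis,
        filters_applied=["highpass", "velocity_sector", "threshold"],
    )


def peak_velocity(kspace: KSpace) -> tuple[float, float, float]:
    """Velocity ``f_i / k_j`` at the maximum-amplitude bin.

    Ties are broken deterministically by lowest frequency, then lowest
    wavenumber (row-major order of the amplitude array).
    """
    amp = kspace.amplitude
    peak = amp.max(initial=0.0)
    if peak <= 0.0:
        raise SweiError("no peak: all-zero spectrum")
    i, j = np.unravel_index(int(np.argmax(amp)), amp.shape)
    f = float(kspace.f_axis[i])
    k = float(kspace.k_axis[j])
    return f / k, f, k


def estimate_phase_velocity(
    seq: ComplexBScanSequence,
    params: SweiParams | None = None,
    seed: int = 0,
) -> PhaseVelocityEstimate:
    """Full estimator: crop, unwrap, subset sampling, per-subset k-space peak.

    Subsets whose filtered spectrum is empty are skipped; the estimate fails
    if more than half of the subsets yield no peak.
    """
    params = params or SweiParams()
    if seq.n_time < MIN_SWEI_SAMPLES:
        raise SweiError(f"sequence shorter than {MIN_SWEI_SAMPLES} samples")
    cropped = crop_beneath_surface(seq, params.crop_px)
    phase_map = unwrap_and_average(cropped)
    subsets = sample_subsets(phase_map, params.n_subsets,
                             params.subset_length, seed)
    velocities: list[float] = []
    peak_f = peak_k = None
    failures = 0
    for sub in subsets:
        ks = compute_kspace(sub, params.pad_time, params.pad_lateral,
                            params.flip_propagation)
        ks = filter_kspace(ks, params.highpass_hz, params.velocity_range_m_s,
                           params.threshold_frac)
        try:
            v, f, k = peak_velocity(ks)
        except SweiError:
            failures += 1
            continue
        velocities.append(v)
        if peak_f is None:
            peak_f, peak_k = f, k
    if failures > len(subsets) // 2:
        raise SweiError(f"no peak in {failures}/{len(subsets)} subsets")
    return PhaseVelocityEstimate(
        velocity=float(np.mean(velocities)),
        subset_velocities=[float(v) for v in velocities],
        peak_f=float(peak_f), peak_k=float(peak_k),
        n_subsets=params.n_subsets, subset_length=params.subset_length,
        seed=seed,
    )


def velocity_bin_tolerance(
    c: float,
    excitation_hz: float,
    params: SweiParams | None = None,
    dt_s: float = 1.0 / 14200.0,
    lateral_pitch_m: float = 3e-3 / 32,
) -> float:
    """Spectral-bin velocity tolerance ``c * max(df/f0, dk/k0)`` on padded axes."""
    params = params or SweiParams()
    df = 1.0 / (params.pad_time * dt_s)
    dk = 1.0 / (params.pad_lateral * lateral_pitch_m)
    k0 = excitation_hz / c
    return c * max(df / excitation_hz, dk / k0)
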