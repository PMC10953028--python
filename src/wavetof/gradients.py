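"""Sinusoidal wave-encoding gradients, their moments, and flow phase.

Wave encoding plays a sine gradient on the phase axis (y) and a cosine
gradient on the partition axis (z) during the readout, turning every
readout line into a corkscrew through k-space.  This module synthesizes
those waveforms on the ADC time grid, integrates their zeroth- and
first-order moments, predicts the readout-direction point-spread-function
spread, and evaluates the first-moment phase that flowing spins acquire
(the mechanism behind readout-direction ghosting in angiography).

Units follow common protocol conventions: gradient amplitudes in mT/m,
times in ms, bandwidth in Hz/pixel, velocities in mm/s.  Conversions to
SI happen inside the functions that need them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Proton gyromagnetic ratio, Hz/T.
GAMMA_HZ_PER_T = 42.577478518e6


class HardwareInfeasibleError(ValueError):
    """A synthesized waveform exceeds a gradient-hardware limit."""


@dataclass(frozen=True)
class WaveParams:
    """Protocol-level description of the wave-encoding gradients.

    Parameters
    ----------
    g_max : float
        Absolute wave gradient amplitude, mT/m.
    n_cyc : int
        Integer number of full sine cycles during the readout.
    bw_per_pixel : float
        Readout bandwidth, Hz/pixel.  The readout duration is
        ``1 / bw_per_pixel`` seconds (n_read samples at a total
        bandwidth of ``bw_per_pixel * n_read``).
    n_read : int
        Nominal number of readout samples.
    os_factor : int
        Readout oversampling factor; the ADC grid has
        ``n_read * os_factor`` samples.
    slew_limit : float
        Maximum slew rate, T/m/s.
    gamma : float
        Gyromagnetic ratio, Hz/T.
    """

    g_max: float
    n_cyc: int
    bw_per_pixel: float
    n_read: int
    os_factor: int = 6
    slew_limit: float = 200.0
    gamma: float = GAMMA_HZ_PER_T

    def __post_init__(self) -> None:
        if self.g_max < 0:
            raise ValueError("g_max must be >= 0")
        if int(self.n_cyc) != self.n_cyc or self.n_cyc < 1:
            raise ValueError("n_cyc must be a positive integer")
        if self.bw_per_pixel <= 0:
            raise ValueError("bw_per_pixel must be > 0")
        if self.n_read < 1:
            raise ValueError("n_read must be >= 1")
        if self.os_factor < 1:
            raise ValueError("os_factor must be >= 1")

    @property
    def duration_ms(self) -> float:
        """Readout duration in ms (= 1e3 / bw_per_pixel)."""
        return 1e3 / self.bw_per_pixel

    @property
    def wave_freq_hz(self) -> float:
        """Wave oscillation frequency n_cyc / T_read in Hz."""
        return self.n_cyc * self.bw_per_pixel

    @property
    def n_adc(self) -> int:
        """Number of ADC samples (oversampled readout)."""
        return self.n_read * self.os_factor


@dataclass(frozen=True)
class GradientWaveform:
    """Sampled wave gradients on a uniform ADC time grid.

    ``gy`` is sine-like (zero at t=0), ``gz`` cosine-like (extremum at
    t=0); both in mT/m, ``t`` in ms.
    """

    t: np.ndarray
    gy: np.ndarray
    gz: np.ndarray

    def __post_init__(self) -> None:
        if not (len(self.t) == len(self.gy) == len(self.gz)):
            raise ValueError("t, gy, gz must have identical length")


@dataclass(frozen=True)
class MomentSeries:
    """Cumulative gradient moments per axis.

    m0 = int G dt (mT*ms/m), m1 = int G*t dt (mT*ms^2/m); both start at
    zero at t=0.
    """

    t: np.ndarray
    m0_y: np.ndarray
    m0_z: np.ndarray
    m1_y: np.ndarray
    m1_z: np.ndarray


@dataclass(frozen=True)
class HardwareReport:
    """Peak amplitude/slew of a waveform against hardware limits."""

    peak_amp_mT_per_m: float
    peak_slew_T_per_m_per_s: float
    amp_limit: float
    slew_limit: float
    amp_ok: bool = field(init=False)
    slew_ok: bool = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "amp_ok", self.peak_amp_mT_per_m <= self.amp_limit)
        object.__setattr__(
            self, "slew_ok", self.peak_slew_T_per_m_per_s <= self.slew_limit
        )

    @property
    def ok(self) -> bool:
        return self.amp_ok and self.slew_ok


def _check_uniform(t: np.ndarray) -> float:
    dt = np.diff(t)
    if len(dt) == 0:
        raise ValueError("need at least two time samples")
    if not np.allclose(dt, dt[0], rtol=1e-9, atol=1e-12 * abs(dt[0])):
        raise ValueError("time grid must be uniform")
    return float(dt[0])


def synthesize_waveforms(params: WaveParams) -> GradientWaveform:
    """Synthesize the quadrature sine/cosine wave gradients.

    gy(t) = G_max sin(2 pi f t), gz(t) = G_max cos(2 pi f t) with
    f = n_cyc / T_read, sampled at the oversampled ADC rate.  Raises
    :class:`HardwareInfeasibleError` if the implied peak slew
    ``2 pi f G_max`` exceeds ``params.slew_limit``.
    """
    n = params.n_adc
    t_ms = np.arange(n) * params.duration_ms / n
    f_hz = params.wave_freq_hz
    phase = 2.0 * np.pi * f_hz * t_ms * 1e-3
    gy = params.g_max * np.sin(phase)
    gz = params.g_max * np.cos(phase)
    peak_slew = params.g_max * 1e-3 * 2.0 * np.pi * f_hz  # T/m/s
    if peak_slew > params.slew_limit:
        raise HardwareInfeasibleError(
            f"wave gradients (gy and gz) require peak slew {peak_slew:.1f} T/m/s "
            f"> limit {params.slew_limit:.1f} T/m/s"
        )
    return GradientWaveform(t=t_ms, gy=gy, gz=gz)


def compute_moments(wave: GradientWaveform) -> MomentSeries:
    """Cumulative zeroth and first gradient moments per axis.

    Trapezoid-rule cumulative integrals, anchored at m0(0)=m1(0)=0.
    Output units mT*ms/m and mT*ms^2/m.
    """
    from scipy.integrate import cumulative_trapezoid

    _check_uniform(wave.t)
    t = wave.t

    def _m0(g: np.ndarray) -> np.ndarray:
        return cumulative_trapezoid(g, t, initial=0.0)

    def _m1(g: np.ndarray) -> np.ndarray:
        return cumulative_trapezoid(g * t, t, initial=0.0)

    return MomentSeries(
        t=t, m0_y=_m0(wave.gy), m0_z=_m0(wave.gz), m1_y=_m1(wave.gy), m1_z=_m1(wave.gz)
    )


def readout_gradient_mT_per_m(params: WaveParams, fov_x_mm: float) -> float:
    """Readout gradient implied by the pixel bandwidth and pixel size.

    G_read = bw_per_pixel / (gamma * dx) with dx = FOV_x / n_read.
    """
    dx_m = fov_x_mm * 1e-3 / params.n_read
    return params.bw_per_pixel / (params.gamma * dx_m) * 1e3


def psf_spread_extent(
    params: WaveParams, fov_x_mm: float, fov_y_mm: float, fov_z_mm: float
) -> float:
    """Readout-direction spread-out range of the wave PSF, in mm.

    The wave phase is linear in the instantaneous gradient: a voxel at
    (y, z) is displaced along x by dx(t) = (gy(t) y + gz(t) z) / G_read.
    The spread-out range reported here is the maximum one-sided
    displacement over the FOV corner voxels (y = +/- FOV_y/2,
    z = +/- FOV_z/2), evaluated on the sampled trajectory.  It is
    bounded by (G_max / G_read) * (|y| + |z|) and grows linearly in
    G_max and in either phase-direction FOV.
    """
    for name, fov in (("fov_x", fov_x_mm), ("fov_y", fov_y_mm), ("fov_z", fov_z_mm)):
        if fov <= 0:
            raise ValueError(f"{name} must be > 0")
    if params.g_max == 0:
        return 0.0
    wave = synthesize_waveforms(params)
    g_read = readout_gradient_mT_per_m(params, fov_x_mm)
    y = fov_y_mm / 2.0
    z = fov_z_mm / 2.0
    best = 0.0
    for sy in (-1.0, 1.0):
        for sz in (-1.0, 1.0):
            dx = (wave.gy * sy * y + wave.gz * sz * z) / g_read
            best = max(best, float(np.max(np.abs(dx))))
    return best


def max_wrap_free_g_max(
    params: WaveParams, fov_x_mm: float, fov_y_mm: float, fov_z_mm: float
) -> float:
    """Largest wave amplitude whose PSF spread fits the oversampled FOV.

    A voxel at the FOV corner is displaced by at most
    (G_max/G_read)(|y|+|z|); requiring displaced signal to stay inside
    the oversampled readout FOV (|x| + spread <= os_factor * FOV_x / 2)
    bounds G_max.  This is the design rule behind readout oversampling:
    the spread must not cause pixel wraparound.
    """
    g_read = readout_gradient_mT_per_m(params, fov_x_mm)
    margin = (params.os_factor - 1) * fov_x_mm / 2.0
    reach = (fov_y_mm + fov_z_mm) / 2.0
    return g_read * margin / reach


def flow_phase_series(
    moments: MomentSeries, velocity_mm_per_s, gamma: float = GAMMA_HZ_PER_T
) -> np.ndarray:
    """Per-ADC-sample phase of a spin moving at constant velocity.

    phi(t) = 2 pi gamma (m1_y(t) v_y + m1_z(t) v_z), radians, with the
    moments converted to SI.  Only the phase-axis (y) and partition-axis
    (z) wave moments contribute; the zeroth-moment position phase is the
    PSF and is handled by the encoding operator.  ``velocity_mm_per_s``
    is a length-2 or length-3 vector; component 0 (readout) is ignored,
    the last two components are (v_y, v_z).
    """
    v = np.asarray(velocity_mm_per_s, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("velocity must be finite")
    if v.shape == (3,):
        vy, vz = v[1], v[2]
    elif v.shape == (2,):
        vy, vz = v[0], v[1]
    else:
        raise ValueError("velocity must be a 2- or 3-vector")
    # mT*ms^2/m -> T*s^2/m is 1e-9; mm/s -> m/s is 1e-3
    m1y_si = moments.m1_y * 1e-9
    m1z_si = moments.m1_z * 1e-9
    return 2.0 * np.pi * gamma * (m1y_si * vy * 1e-3 + m1z_si * vz * 1e-3)


def check_hardware_limits(
    wave: GradientWaveform, slew_limit: float = 200.0, amp_limit: float = 80.0
) -> HardwareReport:
    """Peak amplitude (mT/m) and slew (T/m/s) versus scanner limits.

    Slew is measured by finite differences of the sampled waveform.
    """
    peak_amp = float(max(np.max(np.abs(wave.gy)), np.max(np.abs(wave.gz)), 0.0))
    if len(wave.t) >= 2:
        dt_s = _check_uniform(wave.t) * 1e-3
        slew_y = np.max(np.abs(np.diff(wave.gy))) * 1e-3 / dt_s
        slew_z = np.max(np.abs(np.diff(wave.gz))) * 1e-3 / dt_s
        peak_slew = float(max(slew_y, slew_z))
    else:
        peak_slew = 0.0
    return HardwareReport(
        peak_amp_mT_per_m=peak_amp,
        peak_slew_T_per_m_per_s=peak_slew,
        amp_limit=amp_limit,
        slew_limit=slew_limit,
    )
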