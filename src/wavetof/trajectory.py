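"""Corkscrew k-space trajectory: nominal synthesis, gradient-chain
imperfections, and projection-based calibration.

The wave gradients integrate to sinusoidal k-space deflections
ky_wave(t), kz_wave(t) riding on the linear readout kx(t) — a corkscrew.
Real gradient chains add timing delays and eddy-current distortions, so
the actual trajectory must be measured.  The calibration implemented
here follows the classic projection scheme: acquire projections along
each phase axis with and without the wave gradients; the phase
difference at a known offset r is -2 pi k_wave(t) r, from which k_wave
is recovered either at a single reference offset or by a least-squares
phase-slope fit over several offsets (default, more noise-robust).
Offsets must be small enough that the wave phase advances by less than
pi between ADC samples (|r| < 1/(2 max|dk| per sample)), or the temporal
phase unwrapping becomes ambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .gradients import GradientWaveform, WaveParams, synthesize_waveforms


@dataclass(frozen=True)
class Trajectory:
    """Wave k-space deflections per oversampled readout sample.

    All arrays share one length; units cycles/m.  ``kx`` spans the
    oversampled readout symmetric about the echo; ``ky_wave`` and
    ``kz_wave`` are the wave deflections with their temporal mean
    removed (a constant k-offset only contributes a static per-row
    phase, never a displacement, and demeaning keeps the deflections
    bounded by the integrated-sine amplitude gamma*G_max/(2 pi f)).
    """

    kx: np.ndarray
    ky_wave: np.ndarray
    kz_wave: np.ndarray

    def __post_init__(self) -> None:
        if not (len(self.kx) == len(self.ky_wave) == len(self.kz_wave)):
            raise ValueError("kx, ky_wave, kz_wave must have identical length")


@dataclass(frozen=True)
class GradientImperfection:
    """Timing delay and exponential eddy-current model per axis.

    delay_us applies to both axes; eddy currents are modelled as
    G_out = G - sum_i amp_i * (G * h_i) with h_i(t) = exp(-t/tau_i)/tau_i.
    """

    delay_us: float = 0.0
    eddy_amps: tuple = ()
    eddy_taus_ms: tuple = ()

    def __post_init__(self) -> None:
        if not np.isfinite(self.delay_us):
            raise ValueError("delay must be finite")
        if len(self.eddy_amps) != len(self.eddy_taus_ms):
            raise ValueError("eddy_amps and eddy_taus_ms must pair up")
        if any(tau <= 0 for tau in self.eddy_taus_ms):
            raise ValueError("eddy time constants must be > 0")


@dataclass(frozen=True)
class CalibrationScans:
    """Projection signals with/without wave gradients, per axis.

    ``offsets_mm[axis]`` are the slice/reference positions; the signal
    arrays have shape (n_offsets, n_t).  Axes are 'y' and 'z'.
    """

    offsets_mm: dict
    with_wave: dict
    without_wave: dict
    gamma: float


def nominal_trajectory(params: WaveParams, fov_x_mm: float = 200.0) -> Trajectory:
    """Integrate the nominal wave gradients into a corkscrew trajectory.

    ky_wave(t) = gamma * int gy dt', kz_wave likewise (cycles/m, mean
    removed); kx spans [-n_read/(2 FOV_x), n_read/(2 FOV_x)) at the
    oversampled spacing.
    """
    wave = synthesize_waveforms(params)
    return trajectory_from_waveform(wave, params, fov_x_mm)


def trajectory_from_waveform(
    wave: GradientWaveform, params: WaveParams, fov_x_mm: float = 200.0
) -> Trajectory:
    """Integrate an arbitrary sampled waveform into wave deflections."""
    t_s = wave.t * 1e-3
    gy_si = wave.gy * 1e-3
    gz_si = wave.gz * 1e-3
    ky = params.gamma * cumulative_trapezoid(gy_si, t_s, initial=0.0)
    kz = params.gamma * cumulative_trapezoid(gz_si, t_s, initial=0.0)
    ky -= ky.mean()
    kz -= kz.mean()
    n = len(wave.t)
    dkx = params.n_read / (fov_x_mm * 1e-3) / n
    kx = (np.arange(n) - n // 2) * dkx
    return Trajectory(kx=kx, ky_wave=ky, kz_wave=kz)


def apply_imperfection(
    wave: GradientWaveform, imp: GradientImperfection
) -> GradientWaveform:
    """Corrupt a waveform with a timing delay and eddy-current decay.

    The delay shifts the waveform later in time (zero outside the
    readout window); each eddy term subtracts the waveform convolved
    with a normalized decaying exponential, scaled by its amplitude.
    """
    t = wave.t
    dt = float(t[1] - t[0]) if len(t) > 1 else 1.0
    if abs(imp.delay_us) * 1e-3 > t[-1] - t[0]:
        raise ValueError("delay larger than the readout window")

    def _distort(g: np.ndarray) -> np.ndarray:
        out = np.interp(t - imp.delay_us * 1e-3, t, g, left=0.0, right=0.0)
        for amp, tau in zip(imp.eddy_amps, imp.eddy_taus_ms):
            tk = np.arange(len(t)) * dt
            kernel = np.exp(-tk / tau) / tau * dt
            out = out - amp * np.convolve(out, kernel)[: len(t)]
        return out

    return GradientWaveform(t=t, gy=_distort(wave.gy), gz=_distort(wave.gz))


def simulate_calibration_scans(
    traj_true: Trajectory,
    offsets_mm=(-40.0, -20.0, 20.0, 40.0),
    weights=None,
    gamma: float = 42.577478518e6,
    noise_sigma: float = 0.0,
    rng=None,
) -> CalibrationScans:
    """Simulate thin-slice projection scans with and without the waves.

    For each axis (y, z) and each slice offset r, the with-wave signal
    is w * exp(-i 2 pi k_wave(t) r) and the without-wave signal is the
    constant w (the common readout carrier and relaxation cancel in the
    with/without ratio and are omitted).  Optional iid complex Gaussian
    noise of SD ``noise_sigma`` (relative to unit weight) is added.
    """
    offsets = np.atleast_1d(np.asarray(offsets_mm, dtype=float))
    if offsets.size == 0:
        raise ValueError("need at least one slice offset")
    w = np.ones_like(offsets) if weights is None else np.asarray(weights, float)
    if np.any(w <= 0):
        raise ValueError("profile weights must be positive")
    if rng is None:
        rng = np.random.default_rng(0)

    with_wave, without_wave, offs = {}, {}, {}
    for axis, k_wave in (("y", traj_true.ky_wave), ("z", traj_true.kz_wave)):
        phase = -2.0 * np.pi * np.outer(offsets * 1e-3, k_wave)
        s_with = w[:, None] * np.exp(1j * phase)
        s_without = w[:, None] * np.ones((1, len(k_wave)), complex)
        if noise_sigma > 0:
            for s in (s_with, s_without):
                s += noise_sigma / np.sqrt(2.0) * (
                    rng.standard_normal(s.shape) + 1j * rng.standard_normal(s.shape)
                )
        with_wave[axis] = s_with
        without_wave[axis] = s_without
        offs[axis] = offsets.copy()
    return CalibrationScans(
        offsets_mm=offs, with_wave=with_wave, without_wave=without_wave, gamma=gamma
    )


def estimate_trajectory(
    scans: CalibrationScans, kx: np.ndarray | None = None, method: str = "slope"
) -> Trajectory:
    """Recover the wave trajectory from calibration projections.

    method='slope' (default): unwrap the with/without phase difference
    at every offset and least-squares fit its slope versus position per
    time point; method='offset': use the single offset of largest |r|.
    The recovered deflections are demeaned to match the trajectory
    convention.
    """
    if method not in ("slope", "offset"):
        raise ValueError("method must be 'slope' or 'offset'")
    est = {}
    for axis in ("y", "z"):
        offsets = scans.offsets_mm[axis] * 1e-3
        s_w = scans.with_wave[axis]
        s_o = scans.without_wave[axis]
        mag = np.abs(s_o)
        if np.any(mag.max(axis=1) < 1e-12):
            raise ValueError(f"vanishing reference signal on axis {axis}")
        phase = np.unwrap(np.angle(s_w / s_o), axis=1)
        if method == "offset" or len(offsets) == 1:
            i = int(np.argmax(np.abs(offsets)))
            if abs(offsets[i]) < 1e-12:
                raise ValueError("reference offset is at isocenter; ill-conditioned")
            k = phase[i] / (-2.0 * np.pi * offsets[i])
        else:
            # phi(r, t) = -2 pi k(t) r : per-t slope over offsets
            denom = np.sum(offsets**2)
            k = (offsets @ phase) / (-2.0 * np.pi * denom)
        est[axis] = k - k.mean()
    n = len(est["y"])
    kx_out = np.arange(n, dtype=float) if kx is None else np.asarray(kx, float)
    return Trajectory(kx=kx_out, ky_wave=est["y"], kz_wave=est["z"])
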