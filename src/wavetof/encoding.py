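"""The wave-encoding forward model and its adjoint.

An accelerated wave acquisition of image s is modelled as

    k = M . F_z . F_y . PSF . F_x . C . s

per coil: multiply by the coil sensitivity C, Fourier transform along
the readout axis into hybrid (kx, y, z) space, multiply by the
unit-modulus wave PSF exp(-i 2 pi (ky_wave(kx) y + kz_wave(kx) z)),
Fourier transform along the two phase axes, and apply the ky-kz
sampling mask M.  The image lives on the readout-oversampled x grid
during encoding (zero-padded symmetrically) so wave voxel spreading
never wraps around.  With zero wave amplitude the model reduces to
Cartesian SENSE encoding.

All FFTs are centered and orthonormal, so the adjoint of the full-mask,
PSF-free, single-uniform-coil operator is its inverse.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from functools import cached_property

import numpy as np

from ._fft import cfftn, crop_axis, icfftn, pad_axis
from .sampling import SamplingMask, achieved_acceleration, full_mask
from .trajectory import Trajectory


@dataclass(frozen=True)
class CoilMaps:
    """Complex coil sensitivities (n_coil, nx, ny, nz) with an object
    support mask; root-sum-of-squares is <= 1 everywhere and the maps
    vanish outside the support."""

    maps: np.ndarray
    support: np.ndarray

    def __post_init__(self) -> None:
        if self.maps.ndim != 4:
            raise ValueError("maps must be (n_coil, nx, ny, nz)")
        if self.support.shape != self.maps.shape[1:]:
            raise ValueError("support shape must match map volume shape")

    @property
    def n_coil(self) -> int:
        return self.maps.shape[0]

    def rss(self) -> np.ndarray:
        return np.sqrt(np.sum(np.abs(self.maps) ** 2, axis=0))


@dataclass(frozen=True)
class HybridPSF:
    """Unit-modulus wave modulation over (kx_oversampled, y, z)."""

    psf: np.ndarray

    def __post_init__(self) -> None:
        if self.psf.ndim != 3:
            raise ValueError("psf must be (kx_os, ny, nz)")


@dataclass(frozen=True)
class KSpaceVolume:
    """Multi-coil wave k-space data (n_coil, kx_os, ky, kz) plus the
    acquisition metadata needed to rebuild its encoding operator."""

    data: np.ndarray
    fov_mm: tuple
    os_factor: int
    mask: SamplingMask | None = None


def build_psf(
    traj: Trajectory, fov_y_mm: float, fov_z_mm: float, n_y: int, n_z: int
) -> HybridPSF:
    """Hybrid-space PSF from the wave trajectory.

    psf[kx, y, z] = exp(-i 2 pi (ky_wave(kx) y + kz_wave(kx) z)) with
    y, z the physical voxel-centre coordinates (i - N//2) * FOV/N.
    """
    y = (np.arange(n_y) - n_y // 2) * (fov_y_mm * 1e-3 / n_y)
    z = (np.arange(n_z) - n_z // 2) * (fov_z_mm * 1e-3 / n_z)
    phase = traj.ky_wave[:, None, None] * y[None, :, None] + traj.kz_wave[
        :, None, None
    ] * z[None, None, :]
    return HybridPSF(psf=np.exp(-2j * np.pi * phase))


@dataclass(frozen=True)
class EncodingOperator:
    """Masked, PSF-modulated, coil-weighted Fourier encoding.

    Maps a complex image on the nominal (nx, ny, nz) grid to multi-coil
    k-space (n_coil, nx*os_factor, ny, nz).  ``psf=None`` means no wave
    (Cartesian SENSE); ``mask=None`` means fully sampled.
    """

    coils: CoilMaps
    psf: HybridPSF | None = None
    mask: SamplingMask | None = None
    os_factor: int = 1

    def __post_init__(self) -> None:
        nx, ny, nz = self.coils.maps.shape[1:]
        if self.psf is not None:
            if self.psf.psf.shape != (nx * self.os_factor, ny, nz):
                raise ValueError(
                    f"psf shape {self.psf.psf.shape} inconsistent with grid "
                    f"({nx}*{self.os_factor}, {ny}, {nz})"
                )
        if self.mask is not None and self.mask.grid.shape != (ny, nz):
            raise ValueError("mask shape must be (ny, nz)")

    @property
    def image_shape(self) -> tuple:
        return self.coils.maps.shape[1:]

    @property
    def kspace_shape(self) -> tuple:
        nx, ny, nz = self.image_shape
        return (self.coils.n_coil, nx * self.os_factor, ny, nz)

    def with_mask(self, mask: SamplingMask | None) -> "EncodingOperator":
        return replace(self, mask=mask)

    @property
    def R_achieved(self) -> float:
        if self.mask is None:
            return 1.0
        return achieved_acceleration(self.mask)

    def astype(self, dtype) -> "EncodingOperator":
        """Cast the operator components (single precision speeds up the
        iterative solvers; oracle-level checks should stay in double)."""
        coils = CoilMaps(
            maps=self.coils.maps.astype(dtype), support=self.coils.support
        )
        psf = None if self.psf is None else HybridPSF(psf=self.psf.psf.astype(dtype))
        return replace(self, coils=coils, psf=psf)

    # -- operator application -------------------------------------------------
    # FFT shifts are fused: the input is ifftshifted once, the PSF and
    # mask are cached in unshifted index order, and the output is
    # fftshifted once; equivalent to centered orthonormal FFTs per axis.

    @cached_property
    def _psf_unshifted(self):
        return np.fft.ifftshift(self.psf.psf, axes=(0, 1, 2)) if self.psf is not None else None

    @cached_property
    def _mask_unshifted(self):
        return np.fft.ifftshift(self.mask.grid) if self.mask is not None else None

    def forward(self, image: np.ndarray) -> np.ndarray:
        nx, ny, nz = self.image_shape
        if image.shape != (nx, ny, nz):
            raise ValueError(f"image shape {image.shape} != {(nx, ny, nz)}")
        weighted = self.coils.maps * image[None]
        weighted = pad_axis(weighted, 1, nx * self.os_factor)
        h = np.fft.ifftshift(weighted, axes=(1, 2, 3))
        h = np.fft.fftn(h, axes=(1,), norm="ortho")
        if self.psf is not None:
            h *= self._psf_unshifted[None]
        h = np.fft.fftn(h, axes=(2, 3), norm="ortho")
        if self.mask is not None:
            h *= self._mask_unshifted[None, None]
        return np.fft.fftshift(h, axes=(1, 2, 3))

    def adjoint(self, kspace: np.ndarray) -> np.ndarray:
        if kspace.shape != self.kspace_shape:
            raise ValueError(f"kspace shape {kspace.shape} != {self.kspace_shape}")
        h = np.fft.ifftshift(kspace, axes=(1, 2, 3))
        if self.mask is not None:
            h = h * self._mask_unshifted[None, None]
        h = np.fft.ifftn(h, axes=(2, 3), norm="ortho")
        if self.psf is not None:
            h *= np.conj(self._psf_unshifted)[None]
        h = np.fft.ifftn(h, axes=(1,), norm="ortho")
        weighted = np.fft.fftshift(h, axes=(1, 2, 3))
        weighted = crop_axis(weighted, 1, self.image_shape[0])
        return np.sum(np.conj(self.coils.maps) * weighted, axis=0)

    def as_linear_operator(self):
        """scipy LinearOperator view on flattened complex vectors."""
        from scipy.sparse.linalg import LinearOperator

        img_shape = self.image_shape
        ksp_shape = self.kspace_shape
        n_img = int(np.prod(img_shape))
        n_ksp = int(np.prod(ksp_shape))
        return LinearOperator(
            (n_ksp, n_img),
            matvec=lambda v: self.forward(v.reshape(img_shape)).ravel(),
            rmatvec=lambda v: self.adjoint(v.reshape(ksp_shape)).ravel(),
            dtype=np.result_type(self.coils.maps.dtype, np.complex64),
        )


def forward(image: np.ndarray, op: EncodingOperator) -> np.ndarray:
    """Functional alias for ``op.forward(image)``."""
    return op.forward(image)


def adjoint(kspace: np.ndarray, op: EncodingOperator) -> np.ndarray:
    """Functional alias for ``op.adjoint(kspace)``."""
    return op.adjoint(kspace)


def deconvolve_to_cartesian(
    kspace: np.ndarray, psf: HybridPSF, n_x: int, mask: SamplingMask | None = None
) -> np.ndarray:
    """Synthesize a fully sampled Cartesian dataset from wave data.

    Transforms fully sampled wave k-space to hybrid (kx, y, z), removes
    the unit-modulus PSF by conjugate multiplication, crops the readout
    oversampling to the nominal FOV, and returns Cartesian k-space of
    shape (n_coil, n_x, ny, nz).  Only defined for fully sampled input.
    """
    if mask is not None and not bool(np.all(mask.grid)):
        raise ValueError("deconvolution requires a fully sampled dataset")
    if kspace.ndim != 4:
        raise ValueError("kspace must be (n_coil, kx_os, ky, kz)")
    hybrid = icfftn(kspace, axes=(2, 3))
    hybrid = hybrid * np.conj(psf.psf)[None]
    x_domain = icfftn(hybrid, axes=1)
    x_domain = crop_axis(x_domain, 1, n_x)
    return cfftn(x_domain, axes=(1, 2, 3))


def cartesian_operator(coils: CoilMaps, mask: SamplingMask | None = None) -> EncodingOperator:
    """PSF-free, non-oversampled SENSE operator on the nominal grid."""
    return EncodingOperator(coils=coils, psf=None, mask=mask, os_factor=1)


def wave_operator(
    coils: CoilMaps,
    traj: Trajectory,
    fov_mm: tuple,
    os_factor: int,
    mask: SamplingMask | None = None,
) -> EncodingOperator:
    """Wave encoding operator from a trajectory and grid geometry."""
    _, ny, nz = coils.maps.shape[1:]
    psf = build_psf(traj, fov_mm[1], fov_mm[2], ny, nz)
    return EncodingOperator(coils=coils, psf=psf, mask=mask, os_factor=os_factor)


__all__ = [
    "CoilMaps",
    "HybridPSF",
    "KSpaceVolume",
    "EncodingOperator",
    "build_psf",
    "forward",
    "adjoint",
    "deconvolve_to_cartesian",
    "cartesian_operator",
    "wave_operator",
    "full_mask",
]
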