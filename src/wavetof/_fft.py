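"""Centered, orthonormal FFT helpers.

DC sits at index floor(N/2) on every axis and forward/inverse are exact
adjoints (norm="ortho"), so the encoding adjoint equals the inverse on
full sampling.
"""

from __future__ import annotations

import numpy as np


def cfftn(x: np.ndarray, axes) -> np.ndarray:
    axes = tuple(np.atleast_1d(axes))
    return np.fft.fftshift(
        np.fft.fftn(np.fft.ifftshift(x, axes=axes), axes=axes, norm="ortho"), axes=axes
    )


def icfftn(x: np.ndarray, axes) -> np.ndarray:
    axes = tuple(np.atleast_1d(axes))
    return np.fft.fftshift(
        np.fft.ifftn(np.fft.ifftshift(x, axes=axes), axes=axes, norm="ortho"), axes=axes
    )


def pad_axis(x: np.ndarray, axis: int, n_out: int) -> np.ndarray:
    """Zero-pad symmetrically (centered convention) along one axis."""
    n_in = x.shape[axis]
    if n_out == n_in:
        return x
    if n_out < n_in:
        raise ValueError("pad target smaller than input")
    left = (n_out - n_in) // 2
    pads = [(0, 0)] * x.ndim
    pads[axis] = (left, n_out - n_in - left)
    return np.pad(x, pads)


def crop_axis(x: np.ndarray, axis: int, n_out: int) -> np.ndarray:
    """Centered crop along one axis (adjoint of :func:`pad_axis`)."""
    n_in = x.shape[axis]
    if n_out == n_in:
        return x
    if n_out > n_in:
        raise ValueError("crop target larger than input")
    left = (n_in - n_out) // 2
    sl = [slice(None)] * x.ndim
    sl[axis] = slice(left, left + n_out)
    return x[tuple(sl)]
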