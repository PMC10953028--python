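"""Image reconstruction: iterative least squares (wave-CAIPI / 2D-CAIPI)
and sparsity-regularized nonlinear conjugate gradient (CS-wave / CS).

Least squares solves  min_s || A s - k ||_2^2  with a Krylov solver
(LSQR-family); the same code path covers wave (PSF in A) and Cartesian
(no PSF) operators.  The CS problem adds L1 penalties in the
finite-difference gradient and Haar wavelet domains,

    min_s || A s - k ||_2^2 + gamma_G ||G s||_1 + gamma_W ||W s||_1,

solved by Fletcher-Reeves NLCG with a smoothed modulus
|u| ~ sqrt(|u|^2 + eps) and a backtracking Armijo line search, the
standard sparse-MRI recipe.  Complex images are handled throughout with
Wirtinger-convention gradients (L1 on the complex modulus).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pywt

from .encoding import EncodingOperator


@dataclass(frozen=True)
class ReconParams:
    """Solver settings; defaults follow the wave-TOF protocol."""

    ls_tol: float = 1e-3
    ls_maxiter: int = 200
    gamma_G: float = 3e-4
    gamma_W: float = 3e-4
    cs_tol: float = 3e-3
    cs_maxiter: int = 100
    l1_smooth_eps: float = 1e-15
    wavelet_levels: int = 3
    ls_alpha: float = 0.01  # Armijo sufficient-decrease constant
    ls_shrink: float = 0.6  # backtracking shrink factor
    nlcg_restart: int = 50

    def __post_init__(self) -> None:
        if self.ls_tol <= 0 or self.cs_tol <= 0:
            raise ValueError("tolerances must be > 0")
        if self.gamma_G < 0 or self.gamma_W < 0:
            raise ValueError("regularization weights must be >= 0")


@dataclass
class ReconResult:
    """A reconstructed complex volume plus solver diagnostics."""

    image: np.ndarray
    residual_history: list = field(default_factory=list)
    converged: bool = False
    iterations_used: int = 0
    method: str = ""


class SolverError(RuntimeError):
    pass


def recon_least_squares(
    kspace: np.ndarray, op: EncodingOperator, params: ReconParams | None = None
) -> ReconResult:
    """Solve min_s ||A s - k||_2^2 with LSQR (Krylov least squares).

    The stopping tolerance ``ls_tol`` is on the relative residual
    ||A s - k|| / ||k|| (so on consistent, noiseless data the solve runs
    until the data are matched to that accuracy); ``ls_maxiter`` caps
    the iteration count, which is what terminates noisy solves.  With
    the PSF present this is the wave-CAIPI reconstruction; without it,
    plain 2D-CAIPI SENSE.
    """
    from scipy.sparse.linalg import lsqr

    params = params or ReconParams()
    A = op.as_linear_operator()
    b = kspace.ravel()
    sol = lsqr(A, b, atol=0.0, btol=params.ls_tol, iter_lim=params.ls_maxiter)
    x, istop, itn, r1norm = sol[0], sol[1], sol[2], sol[3]
    if not np.all(np.isfinite(x)):
        raise SolverError(f"least-squares solve diverged at iteration {itn}")
    return ReconResult(
        image=x.reshape(op.image_shape),
        residual_history=[float(r1norm)],
        converged=istop in (1, 2),
        iterations_used=int(itn),
        method="least_squares",
    )


def zero_filled_recon(kspace: np.ndarray, op: EncodingOperator) -> np.ndarray:
    """Adjoint (zero-filled) reconstruction with coil-power normalization."""
    img = op.adjoint(kspace)
    power = np.sum(np.abs(op.coils.maps) ** 2, axis=0)
    out = np.zeros_like(img)
    nz = power > 1e-8 * power.max() if power.max() > 0 else power > 0
    out[nz] = img[nz] / power[nz]
    return out


# -- sparsifying transforms ---------------------------------------------------


def grad3(x: np.ndarray) -> np.ndarray:
    """Anisotropic forward differences on all axes, zero-padded boundary.

    Returns an array (3, nx, ny, nz).
    """
    out = np.zeros((3,) + x.shape, dtype=x.dtype)
    out[0, :-1] = x[1:] - x[:-1]
    out[1, :, :-1] = x[:, 1:] - x[:, :-1]
    out[2, :, :, :-1] = x[:, :, 1:] - x[:, :, :-1]
    return out


def grad3_adjoint(g: np.ndarray) -> np.ndarray:
    """Exact adjoint of :func:`grad3` (negative divergence)."""
    out = np.zeros(g.shape[1:], dtype=g.dtype)
    out[1:] += g[0, :-1]
    out[:-1] -= g[0, :-1]
    out[:, 1:] += g[1, :, :-1]
    out[:, :-1] -= g[1, :, :-1]
    out[:, :, 1:] += g[2, :, :, :-1]
    out[:, :, :-1] -= g[2, :, :, :-1]
    return out


class HaarTransform:
    """Orthonormal multi-level Haar wavelet on complex volumes
    (periodization boundary), vectorized via coeffs_to_array."""

    def __init__(self, shape, levels: int = 3):
        self.shape = shape
        self.levels = max(1, min(levels, pywt.dwtn_max_level(shape, "haar")))
        coeffs = pywt.wavedecn(
            np.zeros(shape), "haar", mode="periodization", level=self.levels
        )
        _, self._slices = pywt.coeffs_to_array(coeffs)

    def forward(self, x: np.ndarray) -> np.ndarray:
        coeffs = pywt.wavedecn(x, "haar", mode="periodization", level=self.levels)
        arr, _ = pywt.coeffs_to_array(coeffs)
        return arr

    def adjoint(self, arr: np.ndarray) -> np.ndarray:
        coeffs = pywt.array_to_coeffs(arr, self._slices, output_format="wavedecn")
        return pywt.waverecn(coeffs, "haar", mode="periodization")


def _smooth_abs(u: np.ndarray, eps: float) -> np.ndarray:
    return np.sqrt(np.abs(u) ** 2 + eps)


def recon_cs(
    kspace: np.ndarray,
    op: EncodingOperator,
    params: ReconParams | None = None,
    x0: np.ndarray | None = None,
) -> ReconResult:
    """Sparsity-regularized reconstruction by smoothed-L1 NLCG.

    Objective: ||A s - k||^2 + gamma_G ||G s||_1 + gamma_W ||W s||_1
    with G the finite-difference gradient and W a 3-level Haar wavelet.
    Fletcher-Reeves directions with periodic restart and a backtracking
    Armijo line search; the recorded objective history is monotone
    non-increasing.  Deterministic: initialized at the zero-filled
    adjoint (or ``x0``).
    """
    params = params or ReconParams()
    if op.mask is not None and op.mask.kind == "caipi":
        import warnings

        warnings.warn(
            "CS reconstruction expects incoherent (Poisson-disc) sampling; "
            "got a CAIPI lattice mask",
            stacklevel=2,
        )
    haar = HaarTransform(op.image_shape, params.wavelet_levels)
    eps = params.l1_smooth_eps
    gG, gW = params.gamma_G, params.gamma_W

    def _penalties(x):
        """(G x, W x) for the active penalties (None when disabled)."""
        return (
            grad3(x) if gG > 0 else None,
            haar.forward(x) if gW > 0 else None,
        )

    def _objective_parts(r2_terms, Gx, Wx):
        f = r2_terms
        if Gx is not None:
            f += gG * float(np.sum(_smooth_abs(Gx, eps)))
        if Wx is not None:
            f += gW * float(np.sum(_smooth_abs(Wx, eps)))
        return f

    def _gradient(r, Gx, Wx):
        g = 2.0 * op.adjoint(r)
        if Gx is not None:
            g = g + gG * grad3_adjoint(Gx / _smooth_abs(Gx, eps))
        if Wx is not None:
            g = g + gW * haar.adjoint(Wx / _smooth_abs(Wx, eps))
        return g

    dtype = np.result_type(kspace.dtype, np.complex64)
    x = np.array(x0 if x0 is not None else zero_filled_recon(kspace, op), dtype=dtype)
    r = op.forward(x) - kspace
    Gx, Wx = _penalties(x)
    r2 = float(np.vdot(r, r).real)
    f = _objective_parts(r2, Gx, Wx)
    g = _gradient(r, Gx, Wx)
    d = -g
    g_norm2 = float(np.vdot(g, g).real)
    g0_norm = np.sqrt(g_norm2)
    history = [f]
    converged = False
    it = 0
    for it in range(1, params.cs_maxiter + 1):
        gd = float(np.vdot(g, d).real)
        if gd >= 0:  # not a descent direction: restart on steepest descent
            d = -g
            gd = -g_norm2
        # One expensive application of A per iteration; along the line
        # x + t d the data term is an exact quadratic in t and the
        # penalty inputs are linear, so the Armijo search is transform-free.
        Ad = op.forward(d)
        Gd, Wd = _penalties(d)
        cross = float(np.vdot(r, Ad).real)
        Ad2 = float(np.vdot(Ad, Ad).real)
        t = -cross / Ad2 if Ad2 > 0 else 1.0  # exact data-term minimizer
        if t <= 0:
            t = 1.0

        def line_f(t):
            val = r2 + 2.0 * t * cross + t * t * Ad2
            return _objective_parts(
                val,
                Gx + t * Gd if Gx is not None else None,
                Wx + t * Wd if Wx is not None else None,
            )

        n_ls = 0
        while True:
            f_new = line_f(t)
            if f_new <= f + params.ls_alpha * t * gd:
                break
            t *= params.ls_shrink
            n_ls += 1
            if n_ls > 80:
                raise SolverError(
                    f"line search failed at NLCG iteration {it} (f={f:.3e})"
                )
        x = x + t * d
        r = r + t * Ad
        if Gx is not None:
            Gx = Gx + t * Gd
        if Wx is not None:
            Wx = Wx + t * Wd
        r2 = float(np.vdot(r, r).real)
        f = _objective_parts(r2, Gx, Wx)
        history.append(f)
        g_new = _gradient(r, Gx, Wx)
        g_new_norm2 = float(np.vdot(g_new, g_new).real)
        if np.sqrt(g_new_norm2) <= params.cs_tol * max(g0_norm, 1e-30):
            g = g_new
            converged = True
            break
        beta = g_new_norm2 / max(g_norm2, 1e-300)
        if it % params.nlcg_restart == 0:
            beta = 0.0
        d = -g_new + beta * d
        g, g_norm2 = g_new, g_new_norm2
    return ReconResult(
        image=x,
        residual_history=history,
        converged=converged,
        iterations_used=it,
        method="cs",
    )
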