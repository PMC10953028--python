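"""ky-kz undersampling masks: 2D-CAIPI lattices and variable-density
Poisson-disc patterns.

2D-CAIPI samples a sheared lattice: every R_y-th ky line, with the kz
positions of successive sampled lines staggered by a CAIPI shift, which
spreads aliasing along both phase axes.  CS-style sampling uses
pseudo-random variable-density Poisson discs whose exclusion radius
grows with k-space radius, leaving the centre dense and the periphery
sparse while avoiding sample clustering.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class SamplingMask:
    """Binary ky-kz sampling pattern with its acceleration bookkeeping."""

    grid: np.ndarray  # bool, (n_ky, n_kz)
    R_nominal: float
    kind: str  # "caipi" | "poisson" | "full"
    calib_size: int = 0
    seed: int | None = None

    def __post_init__(self) -> None:
        g = np.asarray(self.grid)
        if g.dtype != bool:
            raise ValueError("mask grid must be boolean")

    @property
    def R_achieved(self) -> float:
        return achieved_acceleration(self)

    @property
    def n_sampled(self) -> int:
        return int(self.grid.sum())


def achieved_acceleration(mask: SamplingMask | np.ndarray) -> float:
    """n_total / n_sampled of a mask."""
    grid = mask.grid if isinstance(mask, SamplingMask) else np.asarray(mask)
    if grid.size == 0:
        raise ValueError("empty mask grid")
    n_sampled = int(np.count_nonzero(grid))
    if n_sampled == 0:
        raise ValueError("mask samples nothing")
    return grid.size / n_sampled


def full_mask(n_ky: int, n_kz: int) -> SamplingMask:
    """Fully sampled (R=1) mask."""
    return SamplingMask(grid=np.ones((n_ky, n_kz), bool), R_nominal=1.0, kind="full")


def caipi_mask(
    n_ky: int, n_kz: int, R_y: int, R_z: int, caipi_shift: int = 1
) -> SamplingMask:
    """2D-CAIPI lattice: sample iff ky % R_y == 0 and
    kz % R_z == ((ky // R_y) * caipi_shift) % R_z.

    On grids commensurate with the lattice period the density is exactly
    1/(R_y R_z).
    """
    if R_y < 1 or R_z < 1:
        raise ValueError("acceleration factors must be >= 1")
    if not (0 <= caipi_shift < R_z):
        raise ValueError("caipi_shift must satisfy 0 <= shift < R_z")
    ky = np.arange(n_ky)[:, None]
    kz = np.arange(n_kz)[None, :]
    on_ky = ky % R_y == 0
    target = ((ky // R_y) * caipi_shift) % R_z
    grid = on_ky & (kz % R_z == target)
    return SamplingMask(grid=grid, R_nominal=float(R_y * R_z), kind="caipi")


#: Lattice factorizations with the lowest mean g-factor for each total R.
CAIPI_DEFAULTS = {4: (2, 2, 1), 6: (2, 3, 1), 8: (2, 4, 1)}


def caipi_mask_for_R(n_ky: int, n_kz: int, R: int) -> SamplingMask:
    """2D-CAIPI mask using the default (R_y, R_z, shift) for total R."""
    if R == 1:
        return full_mask(n_ky, n_kz)
    if R not in CAIPI_DEFAULTS:
        raise ValueError(f"no default CAIPI factorization for R={R}")
    ry, rz, shift = CAIPI_DEFAULTS[R]
    return caipi_mask(n_ky, n_kz, ry, rz, shift)


def _poisson_try(
    n_ky: int, n_kz: int, r0: float, alpha: float, calib_size: int, rng,
    within: np.ndarray | None = None,
) -> np.ndarray:
    """One dart-throwing pass with radius law r(k) = r0 (1 + alpha k/k_max)."""
    ky, kz = np.meshgrid(np.arange(n_ky), np.arange(n_kz), indexing="ij")
    cy, cz = n_ky // 2, n_kz // 2
    krad = np.sqrt(((ky - cy) / (n_ky / 2.0)) ** 2 + ((kz - cz) / (n_kz / 2.0)) ** 2)
    krad = krad / max(krad.max(), 1e-12)
    radius = r0 * (1.0 + alpha * krad)

    grid = np.zeros((n_ky, n_kz), bool)
    if calib_size > 0:
        y0, y1 = cy - calib_size // 2, cy - calib_size // 2 + calib_size
        z0, z1 = cz - calib_size // 2, cz - calib_size // 2 + calib_size
        grid[max(y0, 0) : y1, max(z0, 0) : z1] = True

    accepted = np.argwhere(grid).astype(float)
    order = rng.permutation(n_ky * n_kz)
    cell = max(r0, 1.0)
    for idx in order:
        iy, iz = divmod(int(idx), n_kz)
        if grid[iy, iz]:
            continue
        if within is not None and not within[iy, iz]:
            continue
        r_here = radius[iy, iz]
        if len(accepted):
            d2 = (accepted[:, 0] - iy) ** 2 + (accepted[:, 1] - iz) ** 2
            if np.min(d2) < r_here**2:
                continue
        grid[iy, iz] = True
        accepted = np.vstack([accepted, [float(iy), float(iz)]])
    del cell
    return grid


def poisson_disc_mask(
    n_ky: int,
    n_kz: int,
    R: float,
    calib_size: int = 0,
    seed: int = 0,
    alpha: float = 2.0,
    density_tol: float = 0.05,
    max_tries: int = 40,
    within: np.ndarray | None = None,
) -> SamplingMask:
    """Variable-density Poisson-disc mask hitting acceleration R.

    The exclusion radius (in ky-kz index units) grows linearly with
    normalized k-space radius, r(k) = r0 (1 + alpha |k|/|k|_max); r0 is
    bisected until the achieved acceleration is within ``density_tol``
    of R.  Deterministic for a fixed seed.  A centred ``calib_size`` x
    ``calib_size`` block, if requested, is always fully sampled.

    ``within`` restricts candidate points to an existing mask, which is
    how nested mask sequences (higher R a subset of lower R) are built;
    see :func:`nested_poisson_masks`.
    """
    if R < 1:
        raise ValueError("R must be >= 1")
    if R == 1:
        m = full_mask(n_ky, n_kz)
        return SamplingMask(
            grid=m.grid, R_nominal=1.0, kind="poisson", calib_size=calib_size, seed=seed
        )
    target = n_ky * n_kz / R
    lo, hi = 0.0, float(max(n_ky, n_kz))
    best = None
    best_err = np.inf
    for trial in range(max_tries):
        r0 = 0.5 * (lo + hi) if trial else np.sqrt(R) * 0.8
        rng = np.random.default_rng(seed)
        grid = _poisson_try(n_ky, n_kz, r0, alpha, calib_size, rng, within)
        n = grid.sum()
        err = abs(n - target) / target
        if err < best_err:
            best, best_err = grid, err
        if err <= density_tol:
            break
        if n > target:  # too dense -> larger radius
            lo = r0
        else:
            hi = r0
        if trial == 0:
            lo, hi = (r0, hi) if n > target else (0.0, r0)
    if best is None or best_err > density_tol:
        raise RuntimeError(
            f"could not reach R={R} within {density_tol:.0%} "
            f"(best error {best_err:.0%} after {max_tries} tries)"
        )
    return SamplingMask(
        grid=best, R_nominal=float(R), kind="poisson", calib_size=calib_size, seed=seed
    )


def nested_poisson_masks(
    n_ky: int, n_kz: int, R_values, calib_size: int = 0, seed: int = 0
) -> dict:
    """Poisson-disc masks for several accelerations, nested by design.

    The mask at each higher R is drawn only from the sample locations of
    the previous (denser) mask, so acquiring at a higher acceleration
    never adds information: quality comparisons across R then isolate
    the undersampling effect from mask-realization luck.  Returns
    ``{R: SamplingMask}`` for R_values sorted ascending.
    """
    out = {}
    within = None
    for R in sorted(R_values):
        m = poisson_disc_mask(
            n_ky, n_kz, R, calib_size=calib_size, seed=seed, within=within
        )
        out[R] = m
        within = m.grid
    return out
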