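"""Image-quality evaluation for angiographic reconstructions.

Implements the evaluation battery used to compare accelerated TOF
schemes: Monte-Carlo pseudo-replica g-factor maps, contrast-to-
background ratio (CBR = (mean_vessel - mean_background)/SD_background),
structural similarity (SSIM) and vessel-masked SSIM on maximum
intensity projections (MIPs), plus the threshold-based vessel
segmentation of the fully sampled reference MIP.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy import ndimage
from skimage.metrics import structural_similarity

from .encoding import EncodingOperator


@dataclass
class GFactorMap:
    """Per-voxel noise-amplification map with region summaries."""

    g: np.ndarray
    valid: np.ndarray
    g_mean: float
    g_max: float
    n_replicas: int
    seed: int


@dataclass
class QualityReport:
    """CBR/SSIM summary for one reconstruction at one acceleration."""

    method: str
    R: float
    cbr: float
    ssim: float
    vessel_ssim: float

    def to_dict(self) -> dict:
        return asdict(self)


def mip(volume: np.ndarray, axis: int = 2) -> np.ndarray:
    """Maximum intensity projection of a magnitude volume along an axis."""
    vol = np.asarray(volume)
    if vol.ndim != 3:
        raise ValueError("expected a 3D volume")
    return np.max(np.abs(vol), axis=axis)


def cbr(
    source_volume: np.ndarray, vessel_mask: np.ndarray, background_mask: np.ndarray
) -> float:
    """Contrast-to-background ratio on magnitude source images.

    (mean_vessel - mean_background) / SD_background; invariant to a
    global additive offset.
    """
    vessel_mask = np.asarray(vessel_mask, bool)
    background_mask = np.asarray(background_mask, bool)
    if not vessel_mask.any() or not background_mask.any():
        raise ValueError("vessel and background masks must be non-empty")
    if np.any(vessel_mask & background_mask):
        raise ValueError("vessel and background masks must be disjoint")
    mag = np.abs(source_volume)
    sd_bg = float(np.std(mag[background_mask]))
    if sd_bg == 0:
        raise ValueError("background SD is zero; CBR undefined")
    return float((mag[vessel_mask].mean() - mag[background_mask].mean()) / sd_bg)


#: Gaussian-window half-width: win_size = 2*ceil(3*sigma)+1, pad = half
_SSIM_PAD = 5


def _ssim_map(a: np.ndarray, b: np.ndarray, data_range=None):
    """Local SSIM map cropped to the filter-valid interior (the same
    region the reference scalar averages over)."""
    if a.shape != b.shape:
        raise ValueError("images must share a shape")
    if data_range is None:
        data_range = max(a.max(), b.max()) - min(a.min(), b.min())
        if data_range == 0:
            data_range = 1.0
    _, smap = structural_similarity(
        a,
        b,
        gaussian_weights=True,
        sigma=1.5,
        use_sample_covariance=False,
        K1=0.01,
        K2=0.03,
        data_range=data_range,
        full=True,
    )
    p = _SSIM_PAD
    return smap[tuple(slice(p, s - p) for s in smap.shape)]


def ssim(mip_a: np.ndarray, mip_b: np.ndarray, data_range=None) -> float:
    """Mean local SSIM (Gaussian window, sigma=1.5, K1=0.01, K2=0.03)."""
    return float(np.mean(_ssim_map(np.abs(mip_a), np.abs(mip_b), data_range)))


def vessel_masked_ssim(
    mip_a: np.ndarray, mip_b: np.ndarray, vessel_mask: np.ndarray, data_range=None
) -> float:
    """Local SSIM map averaged over vessel pixels only."""
    vessel_mask = np.asarray(vessel_mask, bool)
    if not vessel_mask.any():
        raise ValueError("vessel mask is empty")
    smap = _ssim_map(np.abs(mip_a), np.abs(mip_b), data_range)
    p = _SSIM_PAD
    mask = vessel_mask[tuple(slice(p, s - p) for s in vessel_mask.shape)]
    if not mask.any():
        raise ValueError("vessel mask is empty inside the SSIM-valid interior")
    return float(np.mean(smap[mask]))


def make_vessel_mask(
    reference_mip: np.ndarray, n_sd: float = 2.0, min_size: int = 5, n_passes: int = 2
) -> np.ndarray:
    """Segment vessels in the fully sampled reference MIP.

    Threshold at mean + ``n_sd`` * SD, then drop connected components
    smaller than ``min_size`` pixels.  The statistics are refined over
    ``n_passes``: after the first cut, mean and SD are recomputed over
    the sub-threshold (background) pixels only, so bright vessels do
    not inflate their own threshold.  Invariant to global intensity
    scaling; deterministic.
    """
    from skimage.morphology import remove_small_objects

    img = np.abs(np.asarray(reference_mip, float))
    below = np.ones(img.shape, bool)
    thr = np.inf
    for _ in range(max(n_passes, 1)):
        thr = img[below].mean() + n_sd * img[below].std()
        new_below = img <= thr
        if new_below.sum() == 0 or np.array_equal(new_below, below):
            break
        below = new_below
    mask = img > thr
    mask = remove_small_objects(mask, max_size=min_size - 1)
    if not mask.any():
        raise ValueError("vessel segmentation produced an empty mask")
    return mask


def background_mask_from_vessels(
    support: np.ndarray, vessel_mask: np.ndarray, dilation: int = 2
) -> np.ndarray:
    """Static-background region: support minus the dilated vessel mask."""
    grown = ndimage.binary_dilation(vessel_mask, iterations=dilation)
    return np.asarray(support, bool) & ~grown


def gfactor_pseudo_replica(
    op: EncodingOperator,
    recon_fn,
    n_replicas: int = 100,
    noise_sigma: float = 1.0,
    seed: int = 0,
    roi: np.ndarray | None = None,
) -> GFactorMap:
    """Monte-Carlo pseudo-replica g-factor map.

    Pure-noise k-space replicas (iid complex Gaussian, SD
    ``noise_sigma`` per complex sample, identity coil covariance) are
    pushed through the accelerated pipeline (``op`` with its mask) and
    through the fully sampled pipeline (``op`` with the mask removed);

        g = SD_accel / (SD_full * sqrt(R_achieved))

    per voxel, with SDs taken across replicas of the complex
    reconstruction.  Voxels where SD_full vanishes are marked invalid
    and excluded from g_mean/g_max, which are evaluated inside ``roi``
    (default: the coil-map support).
    """
    rng = np.random.default_rng(seed)
    op_full = op.with_mask(None)
    R = op.R_achieved
    shape = op.kspace_shape

    def _noise():
        return noise_sigma / np.sqrt(2.0) * (
            rng.standard_normal(shape) + 1j * rng.standard_normal(shape)
        )

    acc = np.zeros(op.image_shape + (n_replicas,), complex)
    ful = np.zeros_like(acc)
    for i in range(n_replicas):
        n = _noise()
        acc[..., i] = recon_fn(n * (op.mask.grid if op.mask is not None else 1.0), op)
        ful[..., i] = recon_fn(n, op_full)

    def _sd(stack):
        return np.sqrt(np.var(stack.real, axis=-1) + np.var(stack.imag, axis=-1))

    sd_a, sd_f = _sd(acc), _sd(ful)
    valid = sd_f > 1e-12 * max(sd_f.max(), 1e-30)
    g = np.zeros_like(sd_a)
    g[valid] = sd_a[valid] / (sd_f[valid] * np.sqrt(R))
    region = valid if roi is None else (valid & np.asarray(roi, bool))
    if roi is None and op.coils.support is not None:
        region = valid & np.asarray(op.coils.support, bool)
    if not region.any():
        raise ValueError("no valid voxels in the g-factor region of interest")
    return GFactorMap(
        g=g,
        valid=valid,
        g_mean=float(g[region].mean()),
        g_max=float(g[region].max()),
        n_replicas=n_replicas,
        seed=seed,
    )
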