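"""File I/O: HDF5 containers for k-space/trajectories/masks, NIfTI and
PNG image export, CSV/JSON metric tables, YAML protocol configs, and
waveform CSV export."""

from __future__ import annotations

import csv
import json
from pathlib import Path

import h5py
import numpy as np
import yaml

from .gradients import GradientWaveform, WaveParams
from .sampling import SamplingMask
from .trajectory import Trajectory


# -- HDF5 ---------------------------------------------------------------------

def save_kspace(path, data: np.ndarray, fov_mm, os_factor: int) -> None:
    with h5py.File(path, "w") as f:
        d = f.create_dataset("kspace/data", data=data.astype(np.complex64))
        d.attrs["os_factor"] = os_factor
        d.attrs["fov_mm"] = np.asarray(fov_mm, float)


def load_kspace(path):
    with h5py.File(path, "r") as f:
        d = f["kspace/data"]
        return np.asarray(d).astype(np.complex128), tuple(d.attrs["fov_mm"]), int(
            d.attrs["os_factor"]
        )


def save_trajectory(path, traj: Trajectory, fov_mm=None) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("traj/kx", data=traj.kx)
        f.create_dataset("traj/ky_wave", data=traj.ky_wave)
        f.create_dataset("traj/kz_wave", data=traj.kz_wave)
        if fov_mm is not None:
            f["traj"].attrs["fov_mm"] = np.asarray(fov_mm, float)


def load_trajectory(path) -> Trajectory:
    with h5py.File(path, "r") as f:
        return Trajectory(
            kx=np.asarray(f["traj/kx"]),
            ky_wave=np.asarray(f["traj/ky_wave"]),
            kz_wave=np.asarray(f["traj/kz_wave"]),
        )


def save_mask(path, mask: SamplingMask) -> None:
    with h5py.File(path, "w") as f:
        d = f.create_dataset("mask/grid", data=mask.grid.astype(np.uint8))
        d.attrs["R_nominal"] = mask.R_nominal
        d.attrs["kind"] = mask.kind
        d.attrs["seed"] = -1 if mask.seed is None else mask.seed
        d.attrs["calib_size"] = mask.calib_size


def load_mask(path) -> SamplingMask:
    with h5py.File(path, "r") as f:
        d = f["mask/grid"]
        seed = int(d.attrs["seed"])
        return SamplingMask(
            grid=np.asarray(d).astype(bool),
            R_nominal=float(d.attrs["R_nominal"]),
            kind=str(d.attrs["kind"]),
            calib_size=int(d.attrs["calib_size"]),
            seed=None if seed < 0 else seed,
        )


# -- images -------------------------------------------------------------------

def save_nifti(path, volume: np.ndarray, voxel_mm=(1.0, 1.0, 1.0)) -> None:
    import nibabel as nib

    affine = np.diag(list(voxel_mm) + [1.0])
    nib.save(nib.Nifti1Image(np.abs(volume).astype(np.float32), affine), str(path))


def save_png(path, image: np.ndarray) -> None:
    import imageio.v3 as iio

    img = np.abs(np.asarray(image, float))
    rng = img.max() - img.min()
    scaled = (255 * (img - img.min()) / (rng if rng > 0 else 1.0)).astype(np.uint8)
    iio.imwrite(str(path), scaled)


# -- tables and configs -------------------------------------------------------

def save_reports_csv(path, rows: list) -> None:
    if not rows:
        raise ValueError("no rows to write")
    with open(path, "w", newline="") as f:
        writer = csv.DictWriter(f, fieldnames=list(rows[0]))
        writer.writeheader()
        writer.writerows(rows)


def save_reports_json(path, rows: list) -> None:
    Path(path).write_text(json.dumps(rows, indent=2))


def wave_params_from_yaml(path) -> WaveParams:
    """Read protocol parameters from the ``wave:`` block of a YAML file."""
    cfg = yaml.safe_load(Path(path).read_text())
    if "wave" not in cfg:
        raise KeyError("config has no 'wave:' block")
    return WaveParams(**cfg["wave"])


def export_waveform_csv(prefix, wave: GradientWaveform) -> None:
    """Two-column CSV (t_ms, g_mT_per_m) per axis: <prefix>_gy.csv / _gz.csv."""
    for axis, g in (("gy", wave.gy), ("gz", wave.gz)):
        with open(f"{prefix}_{axis}.csv", "w", newline="") as f:
            writer = csv.writer(f)
            writer.writerow(["t_ms", "g_mT_per_m"])
            writer.writerows(zip(wave.t, g))
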