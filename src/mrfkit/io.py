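"""NIfTI and file-format glue.

Volumes are written float32 with NaN at masked-out voxels; the reporting
mask is stored as a separate uint8 volume.  4-D image series are stored as
complex64 NIfTI.  The affine encodes the 1 x 1 x 5 mm voxel geometry
unless an input affine is supplied.
"""

from __future__ import annotations

import hashlib
import logging
from pathlib import Path

import nibabel as nib
import numpy as np

from mrfkit.matching import ParameterMap

__all__ = [
    "default_affine",
    "write_parameter_map",
    "read_parameter_map",
    "write_volume",
    "read_volume",
    "write_series",
    "read_series",
    "sha256_of",
]

logger = logging.getLogger(__name__)

MAP_VOLUMES = ("t1", "t2", "m0", "score")


def default_affine(voxel_size_mm=(1.0, 1.0, 5.0)) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = voxel_size_mm
    return aff


def write_volume(data: np.ndarray, path: str | Path, affine=None) -> Path:
    path = Path(path)
    if affine is None:
        affine = default_affine()
    img = nib.Nifti1Image(np.asarray(data), affine)
    nib.save(img, str(path))
    return path


def read_volume(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asanyarray(img.dataobj), img.affine


def write_series(series: np.ndarray, path: str | Path, affine=None) -> Path:
    """Write a 4-D complex series as complex64 NIfTI."""
    series = np.asarray(series)
    if series.ndim != 4:
        raise ValueError("series must be 4-D (x, y, slices, time)")
    return write_volume(series.astype(np.complex64), path, affine)


def read_series(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    data, affine = read_volume(path)
    if data.ndim != 4:
        raise ValueError(f"{path}: expected a 4-D series, got {data.ndim}-D")
    return data, affine


def write_parameter_map(
    pmap: ParameterMap, out_dir: str | Path, affine=None, prefix: str = ""
) -> dict[str, Path]:
    """Write t1/t2/m0/score (float32, NaN where masked) and mask (uint8)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if affine is None:
        affine = default_affine(pmap.voxel_size_mm)
    volumes = {
        "t1": pmap.masked(pmap.t1_ms),
        "t2": pmap.masked(pmap.t2_ms),
        "m0": pmap.masked(pmap.m0_magnitude),
        "score": pmap.masked(pmap.score),
    }
    paths = {}
    for name, vol in volumes.items():
        p = out_dir / f"{prefix}{name}.nii.gz"
        write_volume(vol.astype(np.float32), p, affine)
        paths[name] = p
    p = out_dir / f"{prefix}mask.nii.gz"
    write_volume(pmap.mask.astype(np.uint8), p, affine)
    paths["mask"] = p
    return paths


def read_parameter_map(
    map_dir: str | Path, prefix: str = "", voxel_size_mm=(1.0, 1.0, 5.0)
) -> ParameterMap:
    """Inverse of :func:`write_parameter_map`.

    A missing mask volume defaults to all-true (with a warning); missing
    value volumes are an error.  Shapes and affines must agree across the
    map's volumes.
    """
    map_dir = Path(map_dir)
    data = {}
    affines = {}
    for name in MAP_VOLUMES:
        p = map_dir / f"{prefix}{name}.nii.gz"
        if not p.exists():
            raise FileNotFoundError(f"parameter-map volume missing: {p}")
        data[name], affines[name] = read_volume(p)
        if data[name].ndim != 3:
            raise ValueError(f"{p}: parameter-map volumes must be 3-D")
    mask_path = map_dir / f"{prefix}mask.nii.gz"
    if mask_path.exists():
        mask, mask_aff = read_volume(mask_path)
        mask = mask.astype(bool)
        affines["mask"] = mask_aff
    else:
        logger.warning("%s missing; defaulting mask to all-true", mask_path)
        mask = np.ones(data["t1"].shape, dtype=bool)

    shapes = {v.shape for v in data.values()} | {mask.shape}
    if len(shapes) != 1:
        raise ValueError(f"parameter-map volumes have inconsistent shapes: {shapes}")
    ref = next(iter(affines.values()))
    for name, aff in affines.items():
        if not np.allclose(aff, ref, atol=1e-4):
            raise ValueError(f"affine of {name} volume differs from the others")

    values = {k: np.nan_to_num(np.asarray(v, dtype=float)) for k, v in data.items()}
    return ParameterMap(
        t1_ms=values["t1"],
        t2_ms=values["t2"],
        m0_magnitude=values["m0"],
        score=values["score"],
        mask=mask,
        voxel_size_mm=tuple(voxel_size_mm),
    )


def sha256_of(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
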