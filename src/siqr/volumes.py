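"""Registered 3D volumes, subject tables, and the smooth analysis mask.

All volumes in a cohort live on one common voxel grid (subjects are assumed
pre-registered to a template; only shape and voxel size are validated here,
never orientation).  Masked voxels are vectorised in a fixed raster order:
the first axis (x) varies fastest, then y, then z.  This matches the
Kronecker ordering ``S3 (x) S2 (x) S1`` of the tensor-product basis design,
so rows of the design matrix align with vectorised voxels.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "Volume3D",
    "SmoothMask",
    "CohortError",
    "DegenerateMaskError",
    "read_volume",
    "write_volume",
    "read_cohort",
    "build_smooth_mask",
    "mask_vectorize",
    "mask_embed",
]


class CohortError(ValueError):
    """Inconsistent cohort: shape/voxel-size mismatch or a failed table join."""


class DegenerateMaskError(ValueError):
    """A mask with no active voxels."""


@dataclass(frozen=True)
class Volume3D:
    """A single registered 3D image on a regular voxel grid.

    Parameters
    ----------
    data : ndarray, shape (P1, P2, P3)
        Image intensities (e.g. tensor-based-morphometry relative volumes).
        Must be finite everywhere.
    voxel_size_mm : tuple of float
        Physical voxel edge lengths.  Voxel centres sit at integer grid
        indices; physical coordinate = index * voxel_size_mm.
    orientation_tag : str
        Free-form label for the axis convention (not interpreted).
    """

    data: np.ndarray
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    orientation_tag: str = "RAS"

    def __post_init__(self) -> None:
        arr = np.asarray(self.data, dtype=np.float64)
        if arr.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={arr.ndim}")
        if min(arr.shape) < 1:
            raise ValueError("all dimensions must be >= 1")
        if not np.all(np.isfinite(arr)):
            raise ValueError("volume contains non-finite values")
        vs = tuple(float(v) for v in np.atleast_1d(self.voxel_size_mm).ravel())
        if len(vs) == 1:
            vs = vs * 3
        if len(vs) != 3 or any(v <= 0 for v in vs):
            raise ValueError("voxel_size_mm must be a positive triple")
        object.__setattr__(self, "data", arr)
        object.__setattr__(self, "voxel_size_mm", vs)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def affine(self) -> np.ndarray:
        return np.diag([*self.voxel_size_mm, 1.0])


@dataclass(frozen=True)
class SmoothMask:
    """Boolean analysis mask with a regularised (Gaussian-smoothed) boundary."""

    indicator: np.ndarray
    sigma_voxels: float
    threshold: float
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        ind = np.asarray(self.indicator, dtype=bool)
        if ind.ndim != 3:
            raise ValueError("mask indicator must be 3D")
        if not ind.any():
            raise DegenerateMaskError("mask has no active voxels")
        object.__setattr__(self, "indicator", ind)
        object.__setattr__(
            self, "voxel_size_mm", tuple(float(v) for v in self.voxel_size_mm)
        )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.indicator.shape

    @property
    def n_active(self) -> int:
        return int(self.indicator.sum())

    @property
    def flat(self) -> np.ndarray:
        """Mask flattened in raster (x-fastest) order."""
        return self.indicator.reshape(-1, order="F")


def read_volume(path: str | Path) -> Volume3D:
    """Load a NIfTI volume; voxel sizes are taken from the header zooms."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj, dtype=np.float64)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    return Volume3D(data=data, voxel_size_mm=zooms)


def write_volume(volume: Volume3D, path: str | Path) -> Path:
    """Write a volume to NIfTI-1 with a diagonal voxel-size affine."""
    img = nib.Nifti1Image(volume.data, affine=volume.affine)
    img.header.set_zooms(volume.voxel_size_mm)
    nib.save(img, str(path))
    return Path(path)


_NII_SUFFIX = re.compile(r"\.nii(\.gz)?$")


def _stem(path: str | Path) -> str:
    return _NII_SUFFIX.sub("", Path(path).name)


def read_cohort(
    volume_paths: Sequence[str | Path], table_path: str | Path
) -> tuple[list[Volume3D], pd.DataFrame]:
    """Read a cohort of volumes plus the subject table, validating consistency.

    The subject table is a delimited text file with header ``id,age,group``.
    Volume files are matched to table rows by filename stem; the returned
    volume list follows the table's row order.  The call fails atomically:
    any inconsistency raises before anything is returned.
    """
    table = pd.read_csv(table_path, dtype={"id": str})
    required = {"id", "age", "group"}
    if not required.issubset(table.columns):
        raise CohortError(f"subject table must have columns {sorted(required)}")
    if table["id"].duplicated().any():
        dup = table.loc[table["id"].duplicated(), "id"].iloc[0]
        raise CohortError(f"duplicate subject id in table: {dup!r}")
    ages = pd.to_numeric(table["age"], errors="coerce")
    if not np.all(np.isfinite(ages)) or (ages <= 0).any():
        raise CohortError("ages must be finite and positive")
    table = table.assign(age=ages.astype(float))

    by_id: dict[str, Volume3D] = {}
    for p in volume_paths:
        sid = _stem(p)
        if sid in by_id:
            raise CohortError(f"duplicate volume for id {sid!r}")
        by_id[sid] = read_volume(p)

    missing = set(table["id"]) - set(by_id)
    if missing:
        raise CohortError(f"table ids with no volume: {sorted(missing)[:5]}")
    extra = set(by_id) - set(table["id"])
    if extra:
        raise CohortError(f"volumes with no table row: {sorted(extra)[:5]}")

    volumes = [by_id[sid] for sid in table["id"]]
    ref = volumes[0]
    for sid, vol in zip(table["id"], volumes):
        if vol.shape != ref.shape:
            raise CohortError(
                f"volume {sid!r} has shape {vol.shape}, expected {ref.shape}"
            )
        if not np.allclose(vol.voxel_size_mm, ref.voxel_size_mm):
            raise CohortError(f"volume {sid!r} voxel size differs from cohort")
    return volumes, table.reset_index(drop=True)


def build_smooth_mask(
    raw_mask: Volume3D, sigma_voxels: float = 2.0, threshold: float = 0.5
) -> SmoothMask:
    """Regularise a raw binary mask by Gaussian smoothing and thresholding.

    The raw indicator (any nonzero voxel counts as inside) is convolved with
    an isotropic Gaussian kernel of standard deviation ``sigma_voxels`` (in
    voxel units, reflective boundary handling) and thresholded, which smooths
    ragged boundaries.  Deterministic given its inputs.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    raw = (raw_mask.data != 0).astype(np.float64)
    if not raw.any():
        raise DegenerateMaskError("raw mask has no nonzero voxels")
    if sigma_voxels > 0:
        smoothed = ndimage.gaussian_filter(raw, sigma=sigma_voxels, mode="reflect")
    else:
        smoothed = raw
    indicator = smoothed > threshold
    if not indicator.any():
        raise DegenerateMaskError("smoothed mask is empty at this threshold")
    return SmoothMask(
        indicator=indicator,
        sigma_voxels=float(sigma_voxels),
        threshold=float(threshold),
        voxel_size_mm=raw_mask.voxel_size_mm,
    )


def mask_vectorize(volume: Volume3D, mask: SmoothMask) -> np.ndarray:
    """Extract masked voxel values as a vector in raster (x-fastest) order."""
    if volume.shape != mask.shape:
        raise ValueError(f"volume shape {volume.shape} != mask shape {mask.shape}")
    return volume.data.reshape(-1, order="F")[mask.flat]


def mask_embed(vector: np.ndarray, mask: SmoothMask) -> Volume3D:
    """Embed a masked vector back onto the grid, zero outside the mask."""
    vector = np.asarray(vector, dtype=np.float64)
    if vector.shape != (mask.n_active,):
        raise ValueError(
            f"vector length {vector.shape} does not match n_active={mask.n_active}"
        )
    flat = np.zeros(int(np.prod(mask.shape)), dtype=np.float64)
    flat[mask.flat] = vector
    return Volume3D(
        data=flat.reshape(mask.shape, order="F"), voxel_size_mm=mask.voxel_size_mm
    )
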