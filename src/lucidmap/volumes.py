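"""Volumetric containers and NIfTI-1 I/O.

All in-memory volumes live on a single canonical grid convention: data are
reoriented to RAS+ on load (x increasing to the subject's right, y anterior,
z superior), so downstream modules never have to reason about storage
orientation.  Display-side left/right conventions are handled at render time.

Multi-volume operations throughout the package require *pre-aligned* grids:
identical shapes and affines agreeing to :data:`GRID_ATOL_MM` millimetres.
No resampling is performed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

GRID_ATOL_MM = 1e-4

STAT_TYPES = ("Z", "t")


class GridAlignmentError(ValueError):
    """Raised when volumes expected to share a grid do not."""


@dataclass
class Volume3D:
    """A 3D scalar grid with a voxel-to-world affine (mm)."""

    data: np.ndarray
    affine: np.ndarray
    space_label: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"expected 3D data, got ndim={self.data.ndim}")
        if min(self.data.shape) < 1:
            raise ValueError(f"degenerate shape {self.data.shape}")
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine is singular")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_sizes_mm(self) -> np.ndarray:
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    def voxel_to_mm(self, ijk) -> np.ndarray:
        ijk = np.atleast_2d(np.asarray(ijk, dtype=float))
        xyz = nib.affines.apply_affine(self.affine, ijk)
        return np.squeeze(xyz)

    def mm_to_voxel(self, xyz) -> np.ndarray:
        xyz = np.atleast_2d(np.asarray(xyz, dtype=float))
        inv = np.linalg.inv(self.affine)
        ijk = nib.affines.apply_affine(inv, xyz)
        return np.squeeze(ijk)

    def like(self, data: np.ndarray) -> "Volume3D":
        """New volume with the same grid but different data."""
        return Volume3D(data=data, affine=self.affine.copy(),
                        space_label=self.space_label)


@dataclass
class StatVolume:
    """Statistic map: Z or t (with degrees of freedom), always two-sided."""

    vol: Volume3D
    stat_type: str
    df: int | None = None

    def __post_init__(self) -> None:
        if self.stat_type not in STAT_TYPES:
            raise ValueError(f"stat_type must be one of {STAT_TYPES}")
        if self.stat_type == "t":
            if self.df is None:
                raise ValueError("df is required for t statistic maps")
            if int(self.df) < 1:
                raise ValueError("df must be a positive integer")
            self.df = int(self.df)
        elif self.df is not None:
            raise ValueError("df must be omitted for Z maps")

    @property
    def data(self) -> np.ndarray:
        return self.vol.data


@dataclass
class EffectVolume:
    """Effect-estimate map in physical units (e.g. 'BOLD % signal change')."""

    vol: Volume3D
    units: str

    def __post_init__(self) -> None:
        if not self.units:
            raise ValueError("units must be non-empty")

    @property
    def data(self) -> np.ndarray:
        return self.vol.data


@dataclass
class MaskVolume:
    """Binary volume; values exactly 0/1."""

    vol: Volume3D

    def __post_init__(self) -> None:
        vals = np.unique(self.vol.data)
        if not np.all(np.isin(vals, (0.0, 1.0))):
            raise ValueError("mask values must be exactly 0 or 1")

    @classmethod
    def from_data(cls, data: np.ndarray, affine: np.ndarray,
                  space_label: str = "") -> "MaskVolume":
        binar = (np.asarray(data) != 0).astype(np.float64)
        return cls(Volume3D(binar, affine, space_label))

    @property
    def data(self) -> np.ndarray:
        return self.vol.data

    @property
    def bool_data(self) -> np.ndarray:
        return self.vol.data > 0

    @property
    def n_foreground(self) -> int:
        return int(self.vol.data.sum())


AnyVolume = Volume3D | StatVolume | EffectVolume | MaskVolume


def _base_vol(v: AnyVolume) -> Volume3D:
    return v if isinstance(v, Volume3D) else v.vol


def grids_aligned(a: AnyVolume, b: AnyVolume, atol: float = GRID_ATOL_MM) -> bool:
    va, vb = _base_vol(a), _base_vol(b)
    return va.shape == vb.shape and np.allclose(va.affine, vb.affine, atol=atol)


def require_aligned(*vols: AnyVolume, what: str = "volumes") -> None:
    """Reject inputs whose (shape, affine) differ beyond tolerance."""
    ref = _base_vol(vols[0])
    for v in vols[1:]:
        if not grids_aligned(ref, v):
            raise GridAlignmentError(
                f"{what} are not on a common grid: "
                f"{ref.shape} vs {_base_vol(v).shape} "
                f"(affines must agree to {GRID_ATOL_MM} mm)")


def default_affine(shape, voxel_mm: float = 2.0) -> np.ndarray:
    """RAS+ affine with isotropic voxels, grid centre at the origin."""
    aff = np.diag([voxel_mm, voxel_mm, voxel_mm, 1.0])
    aff[:3, 3] = -voxel_mm * (np.asarray(shape, dtype=float) - 1) / 2.0
    return aff


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suf in (".nii.gz", ".nii"):
        if name.endswith(suf):
            return path.with_name(name[: -len(suf)] + ".json")
    return path.with_suffix(".json")


def read_volume(path, expected_kind: str, *, stat_type: str | None = None,
                df: int | None = None, units: str | None = None,
                space_label: str = "") -> AnyVolume:
    """Read a NIfTI-1 volume as a stat, effect, or mask container.

    Metadata (stat_type/df/units) is taken from explicit arguments first,
    then from a JSON sidecar next to the file.  A 4D image with a single
    frame is accepted as 3D.  Data are reoriented to RAS+ and promoted to
    float64; masks are binarized by (value != 0).
    """
    path = Path(path)
    if expected_kind not in ("stat", "effect", "mask"):
        raise ValueError(f"unknown kind {expected_kind!r}")
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.as_closest_canonical(nib.load(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4:
        if data.shape[3] != 1:
            raise ValueError(
                f"{path} is 4D with {data.shape[3]} frames; expected a single 3D volume")
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"{path} has unsupported dimensionality {data.ndim}")
    data = np.asarray(data, dtype=np.float64)

    meta: dict = {}
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        with open(sidecar) as fh:
            meta = json.load(fh)
    stat_type = stat_type if stat_type is not None else meta.get("stat_type")
    df = df if df is not None else meta.get("df")
    units = units if units is not None else meta.get("units")
    space_label = space_label or meta.get("space_label", "")

    if not np.all(np.isfinite(data)):
        n_bad = int((~np.isfinite(data)).sum())
        warnings.warn(f"{path}: {n_bad} non-finite voxel(s) present",
                      RuntimeWarning, stacklevel=2)

    vol = Volume3D(data, np.asarray(img.affine, dtype=np.float64), space_label)
    if expected_kind == "mask":
        return MaskVolume.from_data(vol.data, vol.affine, space_label)
    if expected_kind == "effect":
        return EffectVolume(vol, units=units or "arbitrary")
    if stat_type is None:
        raise ValueError(f"{path}: stat_type (Z or t) required for a stat map")
    return StatVolume(vol, stat_type=stat_type, df=df)


def write_volume(vol: AnyVolume, path) -> Path:
    """Write a volume to NIfTI-1 plus a JSON metadata sidecar.

    Stat/effect maps are stored as float32, masks as uint8 (standard
    neuroimaging practice; bounded file sizes).
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    base = _base_vol(vol)
    meta: dict = {"space_label": base.space_label}
    if isinstance(vol, MaskVolume):
        arr = base.data.astype(np.uint8)
        meta["kind"] = "mask"
    else:
        arr = base.data.astype(np.float32)
        if isinstance(vol, StatVolume):
            meta.update(kind="stat", stat_type=vol.stat_type)
            if vol.df is not None:
                meta["df"] = vol.df
        elif isinstance(vol, EffectVolume):
            meta.update(kind="effect", units=vol.units)
        else:
            meta["kind"] = "raw"
    img = nib.Nifti1Image(arr, base.affine)
    nib.save(img, path)
    with open(_sidecar_path(path), "w") as fh:
        json.dump(meta, fh, indent=1, sort_keys=True)
    return path
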