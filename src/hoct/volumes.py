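"""Image volumes, voxel grids, VOI masks and resampling.

Conventions used throughout the package:

* arrays are indexed ``[ix, iy, iz]`` with the slice axis last;
* voxel indices are 0-based and a voxel's value lives at its center;
* world coordinates are millimetres, axes aligned with the array
  (oblique orientations are not supported);
* the world position of voxel ``(i, j, k)`` is ``origin + index * spacing``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
from scipy import ndimage

__all__ = [
    "VoxelGrid",
    "CTVolume",
    "VOIMask",
    "VOIStats",
    "read_ct_series",
    "read_mask",
    "write_nifti",
    "make_cylinder_mask",
    "exclude_slices",
    "voi_stats",
    "resample_trilinear",
]

_AXES = {"x": 0, "y": 1, "z": 2}


@dataclass(frozen=True)
class VoxelGrid:
    """Regular axis-aligned voxel lattice in world (mm) coordinates."""

    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float]
    shape: tuple[int, int, int]

    def __post_init__(self) -> None:
        if len(self.spacing_mm) != 3 or len(self.origin_mm) != 3 or len(self.shape) != 3:
            raise ValueError("spacing, origin and shape must be length-3")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacings must be positive, got {self.spacing_mm}")
        if any(int(n) != n or n < 1 for n in self.shape):
            raise ValueError(f"shape must be positive integers, got {self.shape}")
        object.__setattr__(self, "spacing_mm", tuple(float(s) for s in self.spacing_mm))
        object.__setattr__(self, "origin_mm", tuple(float(o) for o in self.origin_mm))
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))

    @property
    def voxel_volume_mm3(self) -> float:
        sx, sy, sz = self.spacing_mm
        return sx * sy * sz

    @property
    def voxel_volume_ml(self) -> float:
        """Voxel volume in millilitres (1 mL = 1000 mm³)."""
        return self.voxel_volume_mm3 / 1000.0

    def axis_coords(self, axis: int) -> np.ndarray:
        """World coordinates (mm) of voxel centers along one axis."""
        return self.origin_mm[axis] + self.spacing_mm[axis] * np.arange(self.shape[axis])

    def center_coords(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Broadcastable meshgrid of voxel-center world coordinates."""
        return np.meshgrid(*(self.axis_coords(a) for a in range(3)), indexing="ij", sparse=True)

    def extent_mm(self) -> tuple[tuple[float, float], ...]:
        """Per-axis world extent spanned by voxel centers (closed intervals)."""
        return tuple(
            (self.origin_mm[a], self.origin_mm[a] + self.spacing_mm[a] * (self.shape[a] - 1))
            for a in range(3)
        )


def _check_array(grid: VoxelGrid, arr: np.ndarray, what: str) -> None:
    if tuple(arr.shape) != grid.shape:
        raise ValueError(f"{what} shape {arr.shape} does not match grid shape {grid.shape}")


@dataclass
class CTVolume:
    """A 3-D CT volume in Hounsfield units on a :class:`VoxelGrid`.

    ``hu_min_limit``/``hu_max_limit`` record the scanner's representable HU
    range (e.g. −1024..3071 on a 12-bit system); stored values must lie
    within it.
    """

    grid: VoxelGrid
    values: np.ndarray
    hu_min_limit: float = -1024.0
    hu_max_limit: float = 3071.0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        _check_array(self.grid, self.values, "values")
        if self.hu_min_limit >= self.hu_max_limit:
            raise ValueError("hu_min_limit must be below hu_max_limit")
        lo, hi = float(self.values.min()), float(self.values.max())
        if lo < self.hu_min_limit - 1e-9 or hi > self.hu_max_limit + 1e-9:
            raise ValueError(
                f"HU values [{lo}, {hi}] exceed scanner limits "
                f"[{self.hu_min_limit}, {self.hu_max_limit}]"
            )


@dataclass
class VOIMask:
    """Boolean volume-of-interest mask sharing a grid with its target volume."""

    grid: VoxelGrid
    included: np.ndarray

    def __post_init__(self) -> None:
        self.included = np.asarray(self.included, dtype=bool)
        _check_array(self.grid, self.included, "mask")

    @property
    def n_voxels(self) -> int:
        return int(self.included.sum())

    @property
    def volume_ml(self) -> float:
        return self.n_voxels * self.grid.voxel_volume_ml

    def __and__(self, other: "VOIMask") -> "VOIMask":
        if other.grid != self.grid:
            raise ValueError("masks live on different grids")
        return VOIMask(self.grid, self.included & other.included)

    def __or__(self, other: "VOIMask") -> "VOIMask":
        if other.grid != self.grid:
            raise ValueError("masks live on different grids")
        return VOIMask(self.grid, self.included | other.included)


@dataclass(frozen=True)
class VOIStats:
    """Descriptive HU statistics over a VOI (sample SD, n−1 denominator)."""

    mean_hu: float
    sd_hu: float
    min_hu: float
    max_hu: float
    ci95: tuple[float, float]
    n_voxels: int


def voi_stats(volume: CTVolume, mask: VOIMask) -> VOIStats:
    """Mean/SD/min/max HU over the included voxels of ``mask``.

    The SD uses the sample convention (n−1); the 95% confidence interval is
    the normal approximation mean ± 1.96·SD/√n (per-VOI n is typically in
    the thousands).
    """
    if mask.grid != volume.grid:
        raise ValueError("mask grid does not match volume grid")
    vals = volume.values[mask.included]
    if vals.size == 0:
        raise ValueError("mask selects no voxels")
    mean = float(vals.mean())
    sd = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
    half = 1.96 * sd / np.sqrt(vals.size)
    return VOIStats(
        mean_hu=mean,
        sd_hu=sd,
        min_hu=float(vals.min()),
        max_hu=float(vals.max()),
        ci95=(mean - half, mean + half),
        n_voxels=int(vals.size),
    )


def make_cylinder_mask(
    grid: VoxelGrid,
    center_mm: tuple[float, float, float],
    diameter_mm: float,
    length_mm: float,
    axis: Literal["x", "y", "z"] = "z",
) -> VOIMask:
    """Cylindrical VOI; a voxel is included iff its *center* lies inside.

    Mirrors the ⌀ 11 mm, 100 mm² analysis masks drawn around calibration
    tubes.  Raises if the cylinder contains no voxel centers.
    """
    if diameter_mm <= 0 or length_mm <= 0:
        raise ValueError("diameter and length must be positive")
    ax = _AXES[axis]
    radial = [a for a in range(3) if a != ax]
    coords = grid.center_coords()
    r2 = sum((coords[a] - center_mm[a]) ** 2 for a in radial)
    along = np.abs(coords[ax] - center_mm[ax])
    included = (r2 <= (diameter_mm / 2.0) ** 2) & (along <= length_mm / 2.0)
    included = np.broadcast_to(included, grid.shape).copy()
    if not included.any():
        raise ValueError("cylinder lies outside the grid (no voxel centers included)")
    return VOIMask(grid, included)


def exclude_slices(volume: CTVolume, keep_range: tuple[int, int]) -> CTVolume:
    """Keep only slices ``keep_range[0] .. keep_range[1]`` (inclusive) along z.

    Used to drop tapered tube bottoms, caps and air bubbles and to trim tube
    datasets to a common length.  The grid origin shifts so world positions
    of retained voxels are unchanged.
    """
    lo, hi = keep_range
    nz = volume.grid.shape[2]
    if not (0 <= lo <= hi < nz):
        raise ValueError(f"keep_range {keep_range} empty or out of bounds for {nz} slices")
    new_vals = volume.values[:, :, lo : hi + 1]
    g = volume.grid
    new_grid = VoxelGrid(
        spacing_mm=g.spacing_mm,
        origin_mm=(g.origin_mm[0], g.origin_mm[1], g.origin_mm[2] + lo * g.spacing_mm[2]),
        shape=(g.shape[0], g.shape[1], hi - lo + 1),
    )
    return CTVolume(new_grid, new_vals.copy(), volume.hu_min_limit, volume.hu_max_limit,
                    dict(volume.metadata))


def resample_trilinear(
    values: np.ndarray,
    source: VoxelGrid,
    target: VoxelGrid,
    conserve_total: bool = False,
) -> np.ndarray:
    """Trilinear resampling of a scalar field onto another grid.

    Values are interpolated at the target voxel centers; points outside the
    source extent evaluate to 0.  With ``conserve_total`` the output is
    rescaled so its sum equals the source sum exactly — required for
    activity maps, where total becquerels must be preserved when matching
    the map to the kernel resolution.
    """
    values = np.asarray(values, dtype=float)
    _check_array(source, values, "values")
    src_ext = source.extent_mm()
    tgt_ext = target.extent_mm()
    for a in range(3):
        if tgt_ext[a][1] < src_ext[a][0] or tgt_ext[a][0] > src_ext[a][1]:
            raise ValueError("target grid does not overlap the source extent")
    # target voxel centers in fractional source-index coordinates
    idx = [
        (target.axis_coords(a) - source.origin_mm[a]) / source.spacing_mm[a]
        for a in range(3)
    ]
    ii, jj, kk = np.meshgrid(*idx, indexing="ij")
    out = ndimage.map_coordinates(
        values, [ii, jj, kk], order=1, mode="constant", cval=0.0
    )
    if conserve_total:
        src_total = values.sum()
        out_total = out.sum()
        if src_total != 0.0:
            if out_total == 0.0:
                raise ValueError("cannot conserve total: resampled field sums to zero")
            out *= src_total / out_total
    return out


def _resample_ct(volume: CTVolume, target: VoxelGrid) -> CTVolume:
    vals = resample_trilinear(volume.values, volume.grid, target)
    vals = np.clip(vals, volume.hu_min_limit, volume.hu_max_limit)
    return CTVolume(target, vals, volume.hu_min_limit, volume.hu_max_limit,
                    dict(volume.metadata))


CTVolume.resample = _resample_ct  # type: ignore[attr-defined]


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def _grid_from_nifti(img) -> VoxelGrid:
    aff = img.affine
    rot = aff[:3, :3]
    if not np.allclose(rot - np.diag(np.diag(rot)), 0.0, atol=1e-6):
        raise ValueError("oblique NIfTI orientations are not supported (non-diagonal affine)")
    spacing = np.abs(np.diag(rot))
    return VoxelGrid(tuple(spacing), tuple(aff[:3, 3]), tuple(img.shape[:3]))


def _nifti_affine(grid: VoxelGrid) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = grid.spacing_mm
    aff[:3, 3] = grid.origin_mm
    return aff


def write_nifti(obj: CTVolume | VOIMask, path: str | Path) -> None:
    """Write a volume or mask as NIfTI-1 (masks as uint8 labels).

    NIfTI headers cannot carry acquisition provenance, so a CT volume's
    metadata (scanner, kVp, kernel, ...) is persisted in a
    ``<path>.meta.json`` sidecar and restored on read.
    """
    import json

    import nibabel as nib

    if isinstance(obj, VOIMask):
        data = obj.included.astype(np.uint8)
    else:
        data = obj.values
    nib.save(nib.Nifti1Image(data, _nifti_affine(obj.grid)), str(path))
    if isinstance(obj, CTVolume) and obj.metadata:
        sidecar = Path(str(path) + ".meta.json")
        sidecar.write_text(json.dumps(
            {"hu_min_limit": obj.hu_min_limit, "hu_max_limit": obj.hu_max_limit,
             "metadata": {k: v for k, v in obj.metadata.items()
                          if isinstance(v, (str, int, float, bool, type(None)))}}
        ))


def _read_nifti_volume(path: Path, hu_min_limit: float, hu_max_limit: float) -> CTVolume:
    import json

    import nibabel as nib

    img = nib.load(str(path))
    grid = _grid_from_nifti(img)
    vals = np.asarray(img.get_fdata(), dtype=float)
    meta = {"source": str(path)}
    sidecar = Path(str(path) + ".meta.json")
    if sidecar.exists():
        d = json.loads(sidecar.read_text())
        meta.update(d.get("metadata", {}))
        hu_min_limit = float(d.get("hu_min_limit", hu_min_limit))
        hu_max_limit = float(d.get("hu_max_limit", hu_max_limit))
    return CTVolume(grid, vals, hu_min_limit, hu_max_limit, meta)


def read_mask(path: str | Path) -> VOIMask:
    """Read a NIfTI label image as a VOI mask (nonzero voxels are included)."""
    import nibabel as nib

    img = nib.load(str(path))
    grid = _grid_from_nifti(img)
    return VOIMask(grid, np.asarray(img.get_fdata()) != 0)


def _read_dicom_series(path: Path) -> CTVolume:
    import pydicom

    files = sorted(p for p in path.iterdir() if p.is_file() and p.suffix.lower() in (".dcm", ""))
    if not files:
        raise ValueError(f"no DICOM files found in {path}")
    slices = [pydicom.dcmread(str(p)) for p in files]
    uids = {ds.SeriesInstanceUID for ds in slices}
    if len(uids) > 1:
        raise ValueError(f"directory mixes multiple DICOM series: {sorted(uids)}")
    modality = getattr(slices[0], "Modality", "")
    if modality != "CT":
        warnings.warn(f"series modality is {modality!r}, expected CT", stacklevel=3)
    slices.sort(key=lambda ds: float(ds.ImagePositionPatient[2]))
    zs = np.array([float(ds.ImagePositionPatient[2]) for ds in slices])
    if len(zs) > 1:
        dz = np.diff(zs)
        if np.ptp(dz) > 1e-3:
            raise ValueError(f"non-uniform slice spacing: increments range {dz.min()}..{dz.max()}")
        slice_spacing = float(dz.mean())
    else:
        slice_spacing = float(getattr(slices[0], "SliceThickness", 1.0))
    ps = [float(v) for v in slices[0].PixelSpacing]  # (row, col) = (y, x)
    planes = []
    for ds in slices:
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        planes.append(ds.pixel_array.astype(float) * slope + intercept)
    # DICOM planes are (rows=y, cols=x); reorder to (x, y, z)
    vol = np.stack(planes, axis=-1).transpose(1, 0, 2)
    origin = tuple(float(v) for v in slices[0].ImagePositionPatient)
    grid = VoxelGrid((ps[1], ps[0], slice_spacing), origin, vol.shape)
    meta = {
        "source": str(path),
        "modality": modality,
        "scanner": getattr(slices[0], "ManufacturerModelName", None),
        "kvp": getattr(slices[0], "KVP", None),
        "kernel": getattr(slices[0], "ConvolutionKernel", None),
        "slice_thickness_mm": float(getattr(slices[0], "SliceThickness", slice_spacing)),
    }
    lo = float(min(vol.min(), -1024.0))
    hi = float(max(vol.max(), 3071.0))
    return CTVolume(grid, vol, lo, hi, meta)


def read_ct_series(
    path: str | Path,
    format: Literal["dicom", "nifti"] | None = None,
    hu_min_limit: float = -1024.0,
    hu_max_limit: float = 3071.0,
) -> CTVolume:
    """Read a CT volume from a DICOM series directory or a NIfTI file.

    DICOM stored values are converted to HU with the affine rescale
    ``raw × RescaleSlope + RescaleIntercept`` from tags (0028,1053) and
    (0028,1052); the grid is populated from PixelSpacing and the slice
    positions, which must be uniformly spaced.
    """
    path = Path(path)
    if format is None:
        format = "dicom" if path.is_dir() else "nifti"
    if format == "dicom":
        return _read_dicom_series(path)
    return _read_nifti_volume(path, hu_min_limit, hu_max_limit)
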