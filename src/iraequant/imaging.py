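"""Volume and mask containers, SUV computation, grid alignment, masked extraction.

Conventions
-----------
* Arrays are indexed ``(i, j, k)``; axis ``a`` of the array maps to world
  axis ``a`` (axis-aligned grids only).
* World coordinates are in millimetres; the *centre* of voxel ``(0, 0, 0)``
  sits at ``origin``, and voxel ``(i, j, k)`` at ``origin + index * spacing``.
* SUV is in g/mL: activity concentration (Bq/mL, decay-corrected to
  injection time) times body weight (g) divided by injected dose (Bq).
  Decay correction is assumed to have been applied during reconstruction;
  this module never re-corrects.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .errors import AlignmentError, EmptyOrganError, InvalidMetadataError

#: Integer label codes for the three target organs; 0 is background.
ORGAN_LABELS = {"bowel": 1, "lung": 2, "thyroid": 3}
LABEL_ORGANS = {v: k for k, v in ORGAN_LABELS.items()}
ORGANS = tuple(ORGAN_LABELS)


def organ_code(organ: int | str) -> int:
    """Normalise an organ name or integer label to the integer code."""
    if isinstance(organ, str):
        try:
            return ORGAN_LABELS[organ]
        except KeyError:
            raise KeyError(f"unknown organ {organ!r}; expected one of {ORGANS}") from None
    code = int(organ)
    if code not in LABEL_ORGANS:
        raise KeyError(f"unknown organ label {code}; expected one of {sorted(LABEL_ORGANS)}")
    return code


@dataclass(frozen=True)
class ImageGrid:
    """Axis-aligned 3-D voxel lattice: dims (voxels), spacing and origin (mm)."""

    dims: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        object.__setattr__(self, "dims", tuple(int(d) for d in self.dims))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))
        if len(self.dims) != 3 or any(d < 1 for d in self.dims):
            raise ValueError(f"dims must be three integers >= 1, got {self.dims}")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive reals, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.dims

    def axis_coords(self, axis: int) -> np.ndarray:
        """World coordinates (mm) of voxel centres along one axis."""
        return self.origin[axis] + self.spacing[axis] * np.arange(self.dims[axis])

    def world_extent(self, axis: int) -> tuple[float, float]:
        """(min, max) voxel-centre world coordinate along one axis."""
        c = self.axis_coords(axis)
        return float(c[0]), float(c[-1])

    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[:3, :3] = np.diag(self.spacing)
        aff[:3, 3] = self.origin
        return aff

    def same_as(self, other: "ImageGrid", tol: float = 1e-6) -> bool:
        return (
            self.dims == other.dims
            and np.allclose(self.spacing, other.spacing, atol=tol)
            and np.allclose(self.origin, other.origin, atol=tol)
        )


@dataclass(frozen=True)
class ScanMeta:
    """Per-scan metadata; ``scan_day`` is the day offset from treatment start."""

    patient_id: str
    scan_day: int
    weight_g: float = 70_000.0
    dose_bq: float = 3.5e8
    suv_precomputed: bool = False

    def __post_init__(self):
        if not (self.weight_g > 0 and self.dose_bq > 0):
            raise InvalidMetadataError(
                f"weight_g and dose_bq must be positive, got "
                f"weight_g={self.weight_g}, dose_bq={self.dose_bq}"
            )


@dataclass
class ActivityVolume:
    """Decay-corrected activity concentration image (Bq/mL)."""

    grid: ImageGrid
    voxels: np.ndarray

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels, dtype=np.float32)
        if self.voxels.shape != self.grid.dims:
            raise ValueError(f"voxel shape {self.voxels.shape} != grid dims {self.grid.dims}")
        if np.any(self.voxels < 0):
            raise ValueError("activity must be non-negative")


@dataclass
class SUVVolume:
    """Standardised-uptake-value image (g/mL) with its acquisition metadata."""

    grid: ImageGrid
    voxels: np.ndarray
    meta: ScanMeta

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels, dtype=np.float32)
        if self.voxels.shape != self.grid.dims:
            raise ValueError(f"voxel shape {self.voxels.shape} != grid dims {self.grid.dims}")
        if np.any(self.voxels < 0):
            raise ValueError("SUV must be non-negative")


@dataclass
class OrganMask:
    """Integer-labelled organ mask; codes per :data:`ORGAN_LABELS`, 0 = background."""

    grid: ImageGrid
    labels: np.ndarray

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            self.labels = self.labels.astype(np.int16)
        if self.labels.shape != self.grid.dims:
            raise ValueError(f"label shape {self.labels.shape} != grid dims {self.grid.dims}")
        bad = set(np.unique(self.labels)) - ({0} | set(LABEL_ORGANS))
        if bad:
            raise ValueError(f"unknown label values {sorted(bad)}")

    def organ_voxels(self, organ: int | str) -> np.ndarray:
        """Boolean mask of the voxels carrying the organ label."""
        return self.labels == organ_code(organ)

    def organ_counts(self) -> dict[str, int]:
        return {name: int(np.sum(self.labels == code)) for name, code in ORGAN_LABELS.items()}


def compute_suv(activity: ActivityVolume, meta: ScanMeta) -> SUVVolume:
    """Normalise activity by patient weight and injected dose.

    SUV [g/mL] = activity [Bq/mL] * weight [g] / dose [Bq]; linear in
    activity and inversely linear in dose.
    """
    suv = activity.voxels * (meta.weight_g / meta.dose_bq)
    return SUVVolume(grid=activity.grid, voxels=suv, meta=meta)


def resample_mask_to(mask: OrganMask, target: ImageGrid) -> OrganMask:
    """Nearest-neighbour resampling of a label mask onto ``target``.

    Each target voxel takes the label of the nearest source voxel centre;
    target voxels falling outside the source lattice become background.
    Never introduces labels absent from the source; idempotent when the
    grids already match.
    """
    if mask.grid.same_as(target):
        return OrganMask(grid=target, labels=mask.labels.copy())
    for axis in range(3):
        slo, shi = mask.grid.world_extent(axis)
        tlo, thi = target.world_extent(axis)
        half = mask.grid.spacing[axis] / 2
        if thi < slo - half or tlo > shi + half:
            raise AlignmentError(
                f"source and target grids are disjoint in world space along axis {axis}"
            )
    out = np.zeros(target.dims, dtype=mask.labels.dtype)
    idx, valid = [], []
    for axis in range(3):
        t = target.axis_coords(axis)
        i = np.rint((t - mask.grid.origin[axis]) / mask.grid.spacing[axis]).astype(int)
        ok = (i >= 0) & (i < mask.grid.dims[axis])
        idx.append(i[ok])
        valid.append(np.nonzero(ok)[0])
    out[np.ix_(*valid)] = mask.labels[np.ix_(*idx)]
    return OrganMask(grid=target, labels=out)


def extract_masked_values(suv: SUVVolume, mask: OrganMask, organ: int | str) -> np.ndarray:
    """SUV values at the voxels carrying the organ label (order unspecified).

    Raises :class:`EmptyOrganError` when the organ has no voxels, and
    :class:`AlignmentError` when the volume and mask are on different grids
    (resample the mask first).
    """
    if not suv.grid.same_as(mask.grid):
        raise AlignmentError("SUV volume and mask are on different grids; resample the mask first")
    values = suv.voxels[mask.organ_voxels(organ)]
    if values.size == 0:
        raise EmptyOrganError(f"organ {organ!r} has no voxels in the mask")
    return np.asarray(values, dtype=float)


# ---------------------------------------------------------------------------
# NIfTI and sidecar-CSV I/O


def save_volume(vol: SUVVolume | ActivityVolume, path: str | Path) -> None:
    nib.save(nib.Nifti1Image(np.asarray(vol.voxels, dtype=np.float32), vol.grid.affine()), str(path))


def save_mask(mask: OrganMask, path: str | Path) -> None:
    nib.save(nib.Nifti1Image(mask.labels.astype(np.int16), mask.grid.affine()), str(path))


def _grid_from_affine(affine: np.ndarray, shape) -> ImageGrid:
    lin = affine[:3, :3]
    if not np.allclose(lin, np.diag(np.diag(lin)), atol=1e-4):
        raise AlignmentError("only axis-aligned (diagonal-affine) NIfTI grids are supported")
    spacing = np.abs(np.diag(lin))
    return ImageGrid(dims=tuple(shape), spacing=tuple(spacing), origin=tuple(affine[:3, 3]))


def load_volume(path: str | Path, meta: ScanMeta) -> SUVVolume | ActivityVolume:
    """Load a NIfTI scan; returns an SUV volume when ``meta.suv_precomputed``,
    otherwise an activity volume still requiring :func:`compute_suv`."""
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=np.float32)
    grid = _grid_from_affine(img.affine, data.shape)
    if meta.suv_precomputed:
        return SUVVolume(grid=grid, voxels=data, meta=meta)
    return ActivityVolume(grid=grid, voxels=data)


def load_mask(path: str | Path) -> OrganMask:
    img = nib.load(str(path))
    data = np.rint(np.asarray(img.get_fdata())).astype(np.int16)
    return OrganMask(grid=_grid_from_affine(img.affine, data.shape), labels=data)


SCAN_TABLE_COLUMNS = ["patient_id", "scan_day", "weight_g", "dose_Bq", "suv_precomputed"]


def read_scan_table(path: str | Path) -> pd.DataFrame:
    """Read the scan-metadata sidecar CSV and validate its columns."""
    df = pd.read_csv(path)
    missing = set(SCAN_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise InvalidMetadataError(f"scan table missing columns {sorted(missing)}")
    if (df["weight_g"] <= 0).any() or (df["dose_Bq"] <= 0).any():
        raise InvalidMetadataError("scan table contains nonpositive weight or dose")
    return df


def scan_meta_from_row(row) -> ScanMeta:
    return ScanMeta(
        patient_id=str(row["patient_id"]),
        scan_day=int(row["scan_day"]),
        weight_g=float(row["weight_g"]),
        dose_bq=float(row["dose_Bq"]),
        suv_precomputed=bool(int(row["suv_precomputed"])),
    )
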