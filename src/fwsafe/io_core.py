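"""Volume and gradient-table I/O with grid bookkeeping.

All spatial data in this package lives on a single shared voxel grid: the
upstream pipeline is expected to have registered and resampled every input
(DWI, tissue maps, brain mask, WMH mask) onto one grid before anything here
runs.  This module defines the grid-aware containers, reads/writes NIfTI-1
volumes and FSL-style bval/bvec gradient tables, and performs the
gradient-shell quality check applied before any subject enters the cohort
(a usable acquisition has all of its diffusion weighting on one shell with
a minimum number of directions).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence, Union

import nibabel as nib
import numpy as np

#: b-values below this (s/mm^2) are treated as unweighted (b=0) measurements.
B0_THRESHOLD = 50.0


class GridMismatchError(ValueError):
    """Raised when volumes expected to share a voxel grid do not."""


@dataclass(frozen=True)
class ImageGrid:
    """A 3-D voxel grid: shape, voxel size (mm) and voxel-to-world affine."""

    shape: tuple[int, int, int]
    voxel_size: tuple[float, float, float]
    affine: np.ndarray

    def __post_init__(self) -> None:
        shape = tuple(int(s) for s in self.shape)
        vs = tuple(float(v) for v in self.voxel_size)
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "voxel_size", vs)
        aff = np.asarray(self.affine, dtype=float)
        object.__setattr__(self, "affine", aff)
        if len(shape) != 3 or any(s < 1 for s in shape):
            raise ValueError(f"grid shape must be 3 positive integers, got {shape}")
        if len(vs) != 3 or any(v <= 0 for v in vs):
            raise ValueError(f"voxel size must be 3 positive lengths, got {vs}")
        if aff.shape != (4, 4):
            raise ValueError(f"affine must be 4x4, got {aff.shape}")
        if abs(np.linalg.det(aff[:3, :3])) < 1e-12:
            raise ValueError("affine rotation/scaling block is singular")

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(np.prod(self.voxel_size))

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    @classmethod
    def isotropic(cls, shape: Sequence[int], voxel_size: float = 1.0) -> "ImageGrid":
        """Grid with isotropic voxels and a diagonal affine (convenience)."""
        aff = np.diag([voxel_size, voxel_size, voxel_size, 1.0])
        return cls(tuple(shape), (voxel_size,) * 3, aff)

    def matches(self, other: "ImageGrid", atol: float = 1e-4) -> bool:
        return self.shape == other.shape and np.allclose(
            self.affine, other.affine, atol=atol
        )


@dataclass
class ScalarVolume:
    """A per-voxel scalar field (FW map, z-score map, ...) on a grid.

    ``values`` is a float array of the grid's shape; NaN marks missing
    voxels (e.g. unfittable voxels), which downstream metrics exclude.
    """

    grid: ImageGrid
    values: np.ndarray
    units: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"values shape {self.values.shape} != grid shape {self.grid.shape}"
            )


@dataclass
class BinaryMask:
    """A boolean voxel set on a grid."""

    grid: ImageGrid
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values).astype(bool)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"mask shape {self.values.shape} != grid shape {self.grid.shape}"
            )

    @property
    def n_true(self) -> int:
        return int(self.values.sum())

    @property
    def volume_mm3(self) -> float:
        return self.n_true * self.grid.voxel_volume


@dataclass
class GradientTable:
    """Diffusion gradient table: b-values (s/mm^2) and unit directions.

    Directions with b > 0 are unit-norm; b=0 entries may carry a zero
    vector.  The b=0 / b>0 split uses a single cutoff (``B0_THRESHOLD``)
    to absorb small scanner-reported b-values.
    """

    bvals: np.ndarray
    bvecs: np.ndarray

    def __post_init__(self) -> None:
        self.bvals = np.asarray(self.bvals, dtype=float).ravel()
        self.bvecs = np.asarray(self.bvecs, dtype=float)
        if self.bvecs.ndim != 2 or self.bvecs.shape[1] != 3:
            raise ValueError("bvecs must be an (N, 3) array")
        if len(self.bvals) != len(self.bvecs):
            raise ValueError(
                f"{len(self.bvals)} b-values but {len(self.bvecs)} directions"
            )
        if np.any(self.bvals < 0):
            raise ValueError("negative b-value")
        norms = np.linalg.norm(self.bvecs, axis=1)
        bad = (self.bvals > B0_THRESHOLD) & (np.abs(norms - 1.0) > 1e-3)
        if np.any(bad):
            raise ValueError(
                f"{int(bad.sum())} diffusion direction(s) with b > 0 are not unit norm"
            )

    def __len__(self) -> int:
        return len(self.bvals)

    @property
    def b0_mask(self) -> np.ndarray:
        """Boolean mask of unweighted (b ~ 0) measurements."""
        return self.bvals <= B0_THRESHOLD

    @property
    def dwi_mask(self) -> np.ndarray:
        return ~self.b0_mask


@dataclass
class DWISeries:
    """A 4-D diffusion-weighted series: one 3-D volume per gradient."""

    grid: ImageGrid
    signal: np.ndarray
    gtab: GradientTable

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 4:
            raise ValueError("DWI signal must be 4-D (x, y, z, gradient)")
        if self.signal.shape[:3] != self.grid.shape:
            raise ValueError(
                f"signal grid {self.signal.shape[:3]} != grid shape {self.grid.shape}"
            )
        if self.signal.shape[3] != len(self.gtab):
            raise ValueError(
                f"{self.signal.shape[3]} volumes but {len(self.gtab)} gradients"
            )
        if bool((self.signal < 0).any()):  # NaN compares False: finite check only
            raise ValueError("negative DWI signal values")


@dataclass
class ShellQAReport:
    """Result of the single-shell gradient check (report-only, never raises)."""

    passed: bool
    messages: list[str] = field(default_factory=list)
    n_directions: int = 0
    mean_b: float = float("nan")


# ---------------------------------------------------------------------------
# NIfTI reading / writing


def _grid_from_img(img: nib.Nifti1Image) -> ImageGrid:
    zooms = img.header.get_zooms()[:3]
    return ImageGrid(tuple(img.shape[:3]), tuple(float(z) for z in zooms),
                     np.asarray(img.affine, dtype=float))


def read_volume(path: Union[str, Path], as_mask: bool = False):
    """Read a 3-D NIfTI-1 volume as a :class:`ScalarVolume` or :class:`BinaryMask`.

    A mask is returned only when ``as_mask`` is requested and every stored
    value is 0 or 1.  NaN voxels are tolerated in scalar volumes but
    reported with a warning naming their count.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3-D volume, got {data.ndim}-D")
    grid = _grid_from_img(img)
    n_nan = int(np.isnan(data).sum())
    if n_nan:
        warnings.warn(f"{path}: {n_nan} NaN voxel(s)", stacklevel=2)
    if as_mask:
        finite = data[np.isfinite(data)]
        if not np.all(np.isin(finite, (0.0, 1.0))):
            raise ValueError(f"{path}: values outside {{0,1}}, not a binary mask")
        return BinaryMask(grid, np.nan_to_num(data) > 0.5)
    return ScalarVolume(grid, data)


def read_dwi(path: Union[str, Path], gtab: GradientTable) -> DWISeries:
    """Read a 4-D DWI series and attach its gradient table."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError(f"{path}: expected 4-D DWI, got {data.ndim}-D")
    return DWISeries(_grid_from_img(img), data, gtab)


def write_volume(vol: Union[ScalarVolume, BinaryMask], path: Union[str, Path]) -> Path:
    """Write a volume as NIfTI-1 (masks as uint8 0/1, scalars as float32)."""
    path = Path(path)
    if isinstance(vol, BinaryMask):
        data = vol.values.astype(np.uint8)
    else:
        data = vol.values.astype(np.float32)
    img = nib.Nifti1Image(data, vol.grid.affine)
    img.header.set_zooms(vol.grid.voxel_size)
    nib.save(img, str(path))
    return path


def write_4d(data: np.ndarray, grid: ImageGrid, path: Union[str, Path]) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), grid.affine)
    nib.save(img, str(path))
    return path


# ---------------------------------------------------------------------------
# Gradient tables (FSL bval/bvec dialect: whitespace-separated rows)


def _parse_rows(path: Path, n_rows: int) -> np.ndarray:
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line:
                try:
                    rows.append([float(tok) for tok in line.split()])
                except ValueError as exc:
                    raise ValueError(f"{path}: non-numeric token ({exc})") from None
    if len(rows) != n_rows:
        raise ValueError(f"{path}: expected {n_rows} row(s), found {len(rows)}")
    return np.asarray(rows, dtype=float)


def read_gradients(bval_path: Union[str, Path],
                   bvec_path: Union[str, Path]) -> GradientTable:
    """Read FSL-style bval (one row) and bvec (three rows: x, y, z) files.

    Directions with b > 0 are renormalized to unit length when within 1e-2
    of unit norm; larger deviations raise.
    """
    bvals = _parse_rows(Path(bval_path), 1).ravel()
    bvecs = _parse_rows(Path(bvec_path), 3).T  # (N, 3)
    if len(bvals) != len(bvecs):
        raise ValueError(
            f"gradient length mismatch: {len(bvals)} b-values, {len(bvecs)} directions"
        )
    norms = np.linalg.norm(bvecs, axis=1)
    weighted = bvals > B0_THRESHOLD
    off = np.abs(norms - 1.0)
    too_far = off > 1e-2 + 1e-9  # inclusive window, float-safe
    if np.any(weighted & too_far):
        idx = int(np.argmax(weighted & too_far))
        raise ValueError(
            f"direction {idx} has norm {norms[idx]:.4f}, too far from unit to renormalize"
        )
    out = bvecs.copy()
    fix = weighted & (norms > 0)
    out[fix] = bvecs[fix] / norms[fix, None]
    return GradientTable(bvals, out)


def write_gradients(gtab: GradientTable, bval_path: Union[str, Path],
                    bvec_path: Union[str, Path]) -> None:
    with open(bval_path, "w") as fh:
        fh.write(" ".join(f"{b:g}" for b in gtab.bvals) + "\n")
    with open(bvec_path, "w") as fh:
        for axis in range(3):
            fh.write(" ".join(f"{v:.8f}" for v in gtab.bvecs[:, axis]) + "\n")


def check_single_shell(gtab: GradientTable, b_tolerance: float = 50.0,
                       min_directions: int = 41) -> ShellQAReport:
    """QA check: all diffusion weighting on one shell, with enough directions.

    Passes iff every nonzero b-value lies within ``b_tolerance`` of the mean
    nonzero b-value and the number of weighted directions is at least
    ``min_directions``.  b=0 entries are ignored for the shell test.
    """
    if len(gtab) == 0:
        raise ValueError("empty gradient table")
    b = gtab.bvals[gtab.dwi_mask]
    messages: list[str] = []
    n_dir = int(len(b))
    mean_b = float(b.mean()) if n_dir else float("nan")
    if n_dir == 0:
        messages.append("no diffusion-weighted directions")
    else:
        if np.any(np.abs(b - mean_b) > b_tolerance):
            messages.append(
                f"multiple shells: b-values span [{b.min():g}, {b.max():g}] "
                f"around mean {mean_b:g}"
            )
        if n_dir < min_directions:
            messages.append(
                f"too few directions: {n_dir} < {min_directions}"
            )
    return ShellQAReport(passed=not messages, messages=messages,
                         n_directions=n_dir, mean_b=mean_b)


def assert_same_grid(volumes: Sequence, atol: float = 1e-4) -> None:
    """Check that ≥2 volumes/grids share shape and affine; raise naming the first mismatch."""
    grids = [v if isinstance(v, ImageGrid) else v.grid for v in volumes]
    if len(grids) < 2:
        raise ValueError("need at least two grids to compare")
    ref = grids[0]
    for i, g in enumerate(grids[1:], start=1):
        if g.shape != ref.shape:
            raise GridMismatchError(
                f"volume {i}: shape {g.shape} != reference shape {ref.shape}"
            )
        if not np.allclose(g.affine, ref.affine, atol=atol):
            raise GridMismatchError(
                f"volume {i}: affine differs from reference by more than {atol}"
            )
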