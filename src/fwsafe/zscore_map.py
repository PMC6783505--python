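"""Voxelwise z-score group comparison with cluster-size filtering.

Spatially aligned FW maps are compared across groups: a reference group
(normal controls) provides a per-voxel mean and sample standard deviation;
each comparison subject's map is z-scored against that reference; the
z-volumes are averaged within the comparison group; the average is
thresholded at z >= 2 (inclusive, positive tail by default — the interest
is *elevated* free water in patients) and connected components smaller
than 10 voxels are discarded.

All volumes must already be registered to one grid (template registration
is upstream).  Connectivity defaults to the 26-neighbourhood and is
configurable (6/18/26).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence, Union

import numpy as np
import pandas as pd
from scipy import ndimage

from .io_core import BinaryMask, ImageGrid, ScalarVolume, assert_same_grid, write_volume

_CONNECTIVITY_RANK = {6: 1, 18: 2, 26: 3}


@dataclass
class GroupReference:
    """Per-voxel mean/SD of a reference group's FW maps.

    ``valid`` marks voxels where every subject has a finite value and the
    SD is strictly positive; z-scores are defined only there.
    """

    mean: ScalarVolume
    sd: ScalarVolume
    n: int
    valid: BinaryMask


@dataclass
class ClusterMap:
    """Connected suprathreshold clusters: integer labels (0 = background)
    numbered contiguously from 1, plus per-label voxel counts."""

    grid: ImageGrid
    labels: np.ndarray
    sizes: dict[int, int]

    def cluster_table(self) -> pd.DataFrame:
        """(label, size, centroid voxel) rows, one per retained cluster."""
        rows = []
        for label, size in self.sizes.items():
            idx = np.nonzero(self.labels == label)
            rows.append({
                "label": label,
                "size": size,
                "centroid_x": float(np.mean(idx[0])),
                "centroid_y": float(np.mean(idx[1])),
                "centroid_z": float(np.mean(idx[2])),
            })
        return pd.DataFrame(rows, columns=["label", "size", "centroid_x",
                                           "centroid_y", "centroid_z"])

    def write(self, nifti_path: Union[str, Path],
              csv_path: Union[str, Path, None] = None) -> None:
        import nibabel as nib

        img = nib.Nifti1Image(self.labels.astype(np.int32), self.grid.affine)
        nib.save(img, str(nifti_path))
        if csv_path is not None:
            self.cluster_table().to_csv(csv_path, index=False)


def group_reference(fw_volumes: Sequence[ScalarVolume]) -> GroupReference:
    """Per-voxel mean and sample SD (divisor n−1) of >= 2 aligned volumes."""
    if len(fw_volumes) < 2:
        raise ValueError("need at least two volumes for a group reference")
    assert_same_grid(fw_volumes)
    stack = np.stack([v.values for v in fw_volumes], axis=0)
    finite = np.isfinite(stack).all(axis=0)
    mean = np.where(finite, stack.mean(axis=0), np.nan)
    sd = np.where(finite, stack.std(axis=0, ddof=1), np.nan)
    grid = fw_volumes[0].grid
    valid = finite & (sd > 0)
    return GroupReference(
        mean=ScalarVolume(grid, mean),
        sd=ScalarVolume(grid, sd),
        n=len(fw_volumes),
        valid=BinaryMask(grid, valid),
    )


def subject_zscore(fw: ScalarVolume, ref: GroupReference) -> ScalarVolume:
    """(x − mean)/sd inside the reference's valid voxels, NaN elsewhere."""
    assert_same_grid([fw, ref.mean])
    z = np.full(fw.grid.shape, np.nan)
    ok = ref.valid.values & np.isfinite(fw.values)
    z[ok] = (fw.values[ok] - ref.mean.values[ok]) / ref.sd.values[ok]
    return ScalarVolume(fw.grid, z, units="z")


def mean_zscore(z_volumes: Sequence[ScalarVolume]) -> ScalarVolume:
    """Voxelwise mean of z-volumes; valid only where all inputs are."""
    if len(z_volumes) == 0:
        raise ValueError("no z-score volumes to average")
    if len(z_volumes) > 1:
        assert_same_grid(z_volumes)
    stack = np.stack([v.values for v in z_volumes], axis=0)
    finite = np.isfinite(stack).all(axis=0)
    out = np.where(finite, stack.mean(axis=0), np.nan)
    return ScalarVolume(z_volumes[0].grid, out, units="z")


def threshold_clusters(z: ScalarVolume, z_min: float = 2.0, min_size: int = 10,
                       connectivity: int = 26,
                       two_tailed: bool = False) -> ClusterMap:
    """Threshold a z-map (inclusive, z >= z_min) and keep clusters of at
    least ``min_size`` voxels under the given connectivity.

    ``two_tailed`` thresholds |z| >= z_min instead of the positive tail.
    """
    if connectivity not in _CONNECTIVITY_RANK:
        raise ValueError("connectivity must be 6, 18 or 26")
    vals = z.values
    with np.errstate(invalid="ignore"):
        binary = np.abs(vals) >= z_min if two_tailed else vals >= z_min
    binary &= np.isfinite(vals)
    structure = ndimage.generate_binary_structure(3, _CONNECTIVITY_RANK[connectivity])
    raw_labels, n_raw = ndimage.label(binary, structure=structure)
    labels = np.zeros_like(raw_labels)
    sizes: dict[int, int] = {}
    if n_raw:
        counts = np.bincount(raw_labels.ravel())
        next_label = 1
        for lab in range(1, n_raw + 1):
            if counts[lab] >= min_size:
                labels[raw_labels == lab] = next_label
                sizes[next_label] = int(counts[lab])
                next_label += 1
    return ClusterMap(grid=z.grid, labels=labels, sizes=sizes)


def group_comparison(patient_maps: Sequence[ScalarVolume],
                     reference_maps: Sequence[ScalarVolume],
                     z_min: float = 2.0, min_size: int = 10,
                     connectivity: int = 26,
                     two_tailed: bool = False):
    """Full patient-vs-reference comparison: reference mean/SD, per-subject
    z-scores, group-average z-map, thresholded cluster map.

    Returns (mean z-map, ClusterMap).
    """
    ref = group_reference(reference_maps)
    zmaps = [subject_zscore(m, ref) for m in patient_maps]
    zbar = mean_zscore(zmaps)
    clusters = threshold_clusters(zbar, z_min=z_min, min_size=min_size,
                                  connectivity=connectivity,
                                  two_tailed=two_tailed)
    return zbar, clusters
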