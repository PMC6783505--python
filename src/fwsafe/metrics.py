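"""Free-water summary metrics over white-matter mask variants.

Two scalar summaries are computed per mask ``m``:

* ``rFW_m`` — relative free-water volume: the fraction of mask voxels
  whose FW value strictly exceeds a threshold (default 0.1).  Built to be
  insensitive to ventricle expansion and whole-brain atrophy; the strict
  inequality means a voxel at exactly the threshold does not count.
* ``muFW_m`` — mean FW value over all valid mask voxels (values below the
  threshold included).

Each subject is summarized over four masks: raw WM, the partial-volume-safe
WM_safe, the (undilated) WMH lesions themselves, and WM_safe minus the
dilated WMH mask.  Unfittable voxels (NaN in the FW map) are excluded from
every computation and their count is reported, so missing data never biases
the metrics toward zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .io_core import BinaryMask, ScalarVolume, assert_same_grid
from .masks import TissueMaps, subtract

DEFAULT_THRESHOLD = 0.1
MASK_NAMES = ("WM", "WM_safe", "WMHs", "WM_safe_minus_WMHs")


@dataclass
class FWMetricsRecord:
    """One (subject, mask) row of the per-subject metrics table.

    ``rFW``/``muFW`` are NaN when the mask has no valid voxels.
    """

    subject_id: str
    mask_name: str
    rFW: float
    muFW: float
    mask_volume: float
    wmh_volume: float
    n_voxels: int
    n_missing: int

    def __post_init__(self) -> None:
        if self.mask_name not in MASK_NAMES:
            raise ValueError(f"unknown mask name {self.mask_name!r}")
        for v in (self.rFW, self.muFW):
            if not math.isnan(v) and not (0.0 <= v <= 1.0):
                raise ValueError(f"metric {v} outside [0, 1]")
        if self.n_missing > self.n_voxels:
            raise ValueError("n_missing exceeds n_voxels")


def _valid_values(fw: ScalarVolume, mask: BinaryMask) -> np.ndarray:
    assert_same_grid([fw, mask])
    vals = fw.values[mask.values]
    return vals[np.isfinite(vals)]


def relative_fw(fw: ScalarVolume, mask: BinaryMask,
                threshold: float = DEFAULT_THRESHOLD) -> float:
    """Fraction of valid mask voxels with FW strictly above ``threshold``.

    Voxel-volume factors cancel on a shared grid, so this is a voxel-count
    ratio.  NaN when the mask has no valid voxels.
    """
    vals = _valid_values(fw, mask)
    if vals.size == 0:
        return float("nan")
    return float((vals > threshold).sum() / vals.size)


def mean_fw(fw: ScalarVolume, mask: BinaryMask) -> float:
    """Arithmetic mean FW over valid mask voxels; NaN on an empty mask."""
    vals = _valid_values(fw, mask)
    if vals.size == 0:
        return float("nan")
    return float(vals.mean())


def mask_volume_mm3(mask: BinaryMask) -> float:
    """True-voxel count times voxel volume."""
    return mask.volume_mm3


def threshold_sweep(fw: ScalarVolume, mask: BinaryMask,
                    thresholds: Sequence[float]) -> pd.DataFrame:
    """rFW at a grid of thresholds (rFW is non-increasing in the threshold)."""
    rows = [{"threshold": t, "rFW": relative_fw(fw, mask, t)}
            for t in thresholds]
    return pd.DataFrame(rows)


def subject_metrics(fw: ScalarVolume, tissues: TissueMaps,
                    wm_safe: BinaryMask, wmh_expanded: BinaryMask,
                    threshold: float = DEFAULT_THRESHOLD,
                    subject_id: str = "") -> list[FWMetricsRecord]:
    """The four per-subject metric records.

    Masks: raw tissue WM; WM_safe; the undilated WMH lesions; and
    WM_safe minus the *dilated* WMH mask (lesions plus penumbrae removed).
    Every record carries the volume of the undilated WMH mask.
    """
    assert_same_grid([fw, tissues.wm, wm_safe, wmh_expanded, tissues.wmh])
    wmh_vol = mask_volume_mm3(tissues.wmh)
    masks = {
        "WM": tissues.wm,
        "WM_safe": wm_safe,
        "WMHs": tissues.wmh,
        "WM_safe_minus_WMHs": subtract(wm_safe, wmh_expanded),
    }
    records = []
    for name, mask in masks.items():
        in_mask = fw.values[mask.values]
        n_vox = int(mask.n_true)
        n_missing = int(np.sum(~np.isfinite(in_mask)))
        records.append(FWMetricsRecord(
            subject_id=subject_id,
            mask_name=name,
            rFW=relative_fw(fw, mask, threshold),
            muFW=mean_fw(fw, mask),
            mask_volume=mask_volume_mm3(mask),
            wmh_volume=wmh_vol,
            n_voxels=n_vox,
            n_missing=n_missing,
        ))
    return records


METRIC_COLUMNS = [f.name for f in fields(FWMetricsRecord)]


def records_to_frame(records: Iterable[FWMetricsRecord]) -> pd.DataFrame:
    df = pd.DataFrame([vars(r) for r in records], columns=METRIC_COLUMNS)
    return df


def write_metrics_csv(records: Iterable[FWMetricsRecord],
                      path: Union[str, Path]) -> Path:
    """One CSV row per (subject, mask); missing metrics as empty fields."""
    path = Path(path)
    records_to_frame(records).to_csv(path, index=False, na_rep="")
    return path


def wide_metrics(df: pd.DataFrame) -> pd.DataFrame:
    """Long (subject, mask) table -> one row per subject with columns like
    ``rFW_WM_safe``, ``muFW_WM_safe_minus_WMHs`` and ``wmh_volume`` —
    the shape the cohort statistics consume."""
    out: Optional[pd.DataFrame] = None
    for mask_name, sub in df.groupby("mask_name"):
        piece = sub.set_index("subject_id")[["rFW", "muFW"]]
        piece = piece.rename(columns={
            "rFW": f"rFW_{mask_name}", "muFW": f"muFW_{mask_name}"})
        out = piece if out is None else out.join(piece)
    wmh = df.drop_duplicates("subject_id").set_index("subject_id")["wmh_volume"]
    out = out.join(wmh)
    return out.reset_index()
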