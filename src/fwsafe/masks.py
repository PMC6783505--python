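"""Binary 3-D morphology for partial-volume-safe white-matter masks.

Free water measured in the full white-matter (WM) mask is contaminated by
CSF and grey-matter (GM) partial-volume voxels at tissue borders and by
white-matter hyperintensities (WMHs) and their penumbrae.  The safe WM
mask removes all of these with plain set algebra and morphology::

    WM_safe = ((WM - (GM (+) R1)) - (CSF (+) R1))  ∩  (BM (-) R15)

where (+) / (-) are dilation / erosion by a 3-D structuring element of
radius n (a discrete Euclidean ball by default), BM is the brain mask, and
A - B is set subtraction.  The WMH penumbra is excluded by dilating the
lesion mask by 2 voxels before subtracting it from WM_safe.

All radii are in voxels of the shared grid; physical interpretation
(e.g. 15 voxels = 15 mm on a 1 mm isotropic grid) is the caller's.
Erosion treats out-of-grid voxels as background, so the brain-mask erosion
recedes from the field-of-view edge as well as from the brain surface.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy import ndimage

from .io_core import BinaryMask, assert_same_grid

ElementShape = Literal["ball", "cube"]


@dataclass(frozen=True)
class StructuringElement:
    """A symmetric set of integer voxel offsets around the origin."""

    radius: int
    offsets: frozenset[tuple[int, int, int]]

    def __post_init__(self) -> None:
        if (0, 0, 0) not in self.offsets:
            raise ValueError("structuring element must contain the origin")
        for v in self.offsets:
            if tuple(-c for c in v) not in self.offsets:
                raise ValueError("structuring element must be symmetric")

    @property
    def footprint(self) -> np.ndarray:
        """Dense (2r+1)^3 boolean footprint centred on the origin."""
        r = self.radius
        fp = np.zeros((2 * r + 1,) * 3, dtype=bool)
        for v in self.offsets:
            fp[v[0] + r, v[1] + r, v[2] + r] = True
        return fp

    def __len__(self) -> int:
        return len(self.offsets)


def make_ball(radius: int, shape: ElementShape = "ball") -> StructuringElement:
    """Structuring element of the given radius.

    ``ball`` (default): all integer offsets with Euclidean norm <= radius —
    the faithful reading of "radius".  ``cube``: Chebyshev norm <= radius,
    kept as an option for sensitivity checks.
    """
    radius = int(radius)
    if radius < 0:
        raise ValueError("radius must be non-negative")
    rng = range(-radius, radius + 1)
    if shape == "ball":
        offs = {(x, y, z) for x in rng for y in rng for z in rng
                if x * x + y * y + z * z <= radius * radius}
    elif shape == "cube":
        offs = {(x, y, z) for x in rng for y in rng for z in rng}
    else:
        raise ValueError(f"unknown element shape {shape!r}")
    return StructuringElement(radius, frozenset(offs))


def dilate(mask: BinaryMask, se: StructuringElement) -> BinaryMask:
    """Morphological dilation; out-of-grid neighbours are ignored."""
    out = ndimage.binary_dilation(mask.values, structure=se.footprint)
    return BinaryMask(mask.grid, out)


def erode(mask: BinaryMask, se: StructuringElement) -> BinaryMask:
    """Morphological erosion; out-of-grid voxels count as background,
    so the result recedes from the grid border."""
    out = ndimage.binary_erosion(mask.values, structure=se.footprint,
                                 border_value=0)
    return BinaryMask(mask.grid, out)


def subtract(a: BinaryMask, b: BinaryMask) -> BinaryMask:
    """Set subtraction a AND NOT b (same grid required)."""
    assert_same_grid([a, b])
    return BinaryMask(a.grid, a.values & ~b.values)


def intersect(a: BinaryMask, b: BinaryMask) -> BinaryMask:
    assert_same_grid([a, b])
    return BinaryMask(a.grid, a.values & b.values)


@dataclass
class TissueMaps:
    """WM/GM/CSF/brain/WMH binary maps on one shared grid.

    WM, GM and CSF are expected to be disjoint hard labels (probabilistic
    maps must be thresholded upstream); overlap is warned about, not
    rejected, and the overlap count is recorded.
    """

    wm: BinaryMask
    gm: BinaryMask
    csf: BinaryMask
    brain: BinaryMask
    wmh: BinaryMask
    overlap_count: int = field(init=False, default=0)

    def __post_init__(self) -> None:
        assert_same_grid([self.wm, self.gm, self.csf, self.brain, self.wmh])
        overlap = (
            (self.wm.values & self.gm.values)
            | (self.wm.values & self.csf.values)
            | (self.gm.values & self.csf.values)
        )
        self.overlap_count = int(overlap.sum())
        if self.overlap_count:
            warnings.warn(
                f"tissue maps overlap at {self.overlap_count} voxel(s)",
                stacklevel=2,
            )

    @property
    def grid(self):
        return self.wm.grid


def build_wm_safe(tissues: TissueMaps, r_small: int = 1, r_brain: int = 15,
                  element: ElementShape = "ball") -> BinaryMask:
    """The partial-volume-safe WM mask.

    Removes from WM every voxel within ``r_small`` of GM or CSF and every
    voxel within ``r_brain`` of the brain-mask boundary.  The result is a
    subset of WM by construction.
    """
    if tissues.wm.n_true == 0:
        warnings.warn("empty WM mask: WM_safe is empty", stacklevel=2)
    se_small = make_ball(r_small, element)
    se_brain = make_ball(r_brain, element)
    safe = subtract(tissues.wm, dilate(tissues.gm, se_small))
    safe = subtract(safe, dilate(tissues.csf, se_small))
    return intersect(safe, erode(tissues.brain, se_brain))


def expand_wmh(wmh: BinaryMask, radius: int = 2,
               element: ElementShape = "ball") -> BinaryMask:
    """Dilate the WMH lesion mask to cover the lesion penumbrae.

    A single dilation by a radius-``radius`` element (not iterated
    unit-radius dilations, which differ on the discrete grid).
    """
    return dilate(wmh, make_ball(radius, element))
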