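"""Synthetic phantoms and cohorts with known free-water ground truth.

The geometry is stylized, not anatomical: a brain ellipsoid holds a
cortical grey-matter shell, central CSF-filled ventricles, and white
matter in between, with optional spherical WMH lesions carved from the
white matter.  The true free-water field is elevated near the CSF border
(emulating partial-volume contamination), inside lesions, and — at cohort
level — by a per-group additive offset, so the pipeline's mask-algebraic
and statistical claims can be exercised end to end with no real data.

The DWI signal is generated voxelwise from the same bi-tensor forward
model the fit inverts (one b=0 volume plus 41 evenly distributed
directions at b = 1000 s/mm^2) and corrupted with Rician noise, the
magnitude-MRI noise model.  White-matter tensors are anisotropic with a
smoothly rotating principal direction; GM and CSF are isotropic.

Everything is deterministic given the seeds carried by the parameter
dataclasses.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .fw_fit import _design_matrix
from .io_core import (
    BinaryMask,
    DWISeries,
    GradientTable,
    ImageGrid,
    ScalarVolume,
    write_gradients,
    write_volume,
    write_4d,
)
from .masks import TissueMaps, build_wm_safe, expand_wmh
from .metrics import records_to_frame, subject_metrics, wide_metrics


def even_directions(n: int) -> np.ndarray:
    """n roughly evenly distributed unit vectors (Fibonacci sphere)."""
    i = np.arange(n, dtype=float)
    z = 1.0 - (2.0 * i + 1.0) / n
    phi = i * np.pi * (3.0 - np.sqrt(5.0))
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)


def make_gradient_table(n_directions: int = 41, bval: float = 1000.0,
                        n_b0: int = 1) -> GradientTable:
    """Single-shell table: ``n_b0`` unweighted volumes + evenly spread
    directions at one b-value (defaults mirror the target acquisition)."""
    bvals = np.concatenate([np.zeros(n_b0), np.full(n_directions, bval)])
    bvecs = np.vstack([np.zeros((n_b0, 3)), even_directions(n_directions)])
    return GradientTable(bvals, bvecs)


def add_rician_noise(signal: np.ndarray, sigma: float,
                     seed: Union[int, np.random.Generator] = 0) -> np.ndarray:
    """Rician-corrupt a noise-free magnitude signal.

    Returns sqrt((S + n1)^2 + n2^2) with n1, n2 independent zero-mean
    Gaussians of SD ``sigma``; always non-negative; identity when
    sigma == 0.
    """
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    signal = np.asarray(signal, dtype=float)
    if sigma == 0:
        return signal
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    n1 = rng.normal(0.0, sigma, size=signal.shape)
    n2 = rng.normal(0.0, sigma, size=signal.shape)
    return np.sqrt((signal + n1) ** 2 + n2 ** 2)


@dataclass
class PhantomSpec:
    """Geometry, tissue and acquisition parameters of one phantom.

    Radii and widths are in voxels; diffusivities in mm^2/s; ``f_*`` are
    free-water fractions in [0, 1].  ``rician_sigma`` defaults to s0/30,
    a moderate single-shell SNR.
    """

    shape: tuple[int, int, int] = (40, 40, 40)
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    brain_frac: float = 0.45          # brain ellipsoid semi-axes / grid shape
    gm_thickness: float = 2.0         # cortical shell, voxels
    ventricle_frac: float = 0.12      # ventricle semi-axes / grid shape
    f_wm: float = 0.15                # baseline FW in white matter
    f_gm: float = 0.25
    csf_gradient_width: float = 3.0   # near-CSF FW ramp extent, voxels
    csf_gradient_amplitude: float = 0.25
    n_wmh: int = 3
    wmh_radius_range: tuple[int, int] = (1, 2)
    f_wmh: float = 0.6
    wm_eigenvalues: tuple[float, float, float] = (1.5e-3, 0.4e-3, 0.4e-3)
    d_gm: float = 0.8e-3
    d_csf: float = 3.0e-3
    d_water: float = 3.0e-3
    n_directions: int = 41
    bval: float = 1000.0
    n_b0: int = 1
    s0: float = 1000.0
    rician_sigma: float = 1000.0 / 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        for f in (self.f_wm, self.f_gm, self.f_wmh):
            if not 0.0 <= f <= 1.0:
                raise ValueError("free-water fractions must be in [0, 1]")
        if self.rician_sigma < 0:
            raise ValueError("rician_sigma must be non-negative")


@dataclass
class Phantom:
    """One synthetic subject: tissue maps, the true FW field, the DWI
    series, and the true tissue tensor field (6 components per voxel)."""

    tissues: TissueMaps
    true_f: ScalarVolume
    dwi: DWISeries
    true_tensor: np.ndarray = field(repr=False, default=None)


def _ellipsoid(shape, center, radii) -> np.ndarray:
    coords = np.indices(shape, dtype=float)
    acc = np.zeros(shape, dtype=float)
    for ax in range(3):
        acc += ((coords[ax] - center[ax]) / radii[ax]) ** 2
    return acc <= 1.0


def make_phantom(spec: Optional[PhantomSpec] = None) -> Phantom:
    """Generate one phantom subject, deterministic given ``spec.seed``."""
    from scipy import ndimage

    spec = spec or PhantomSpec()
    shape = tuple(spec.shape)
    center = tuple((s - 1) / 2.0 for s in shape)
    brain_radii = tuple(max(spec.brain_frac * s, 3.0) for s in shape)
    inner_radii = tuple(max(r - spec.gm_thickness, 2.0) for r in brain_radii)
    vent_radii = tuple(max(spec.ventricle_frac * s, 1.0) for s in shape)
    if any(v >= i for v, i in zip(vent_radii, inner_radii)):
        raise ValueError("ventricles do not fit inside the white matter")

    brain = _ellipsoid(shape, center, brain_radii)
    interior = _ellipsoid(shape, center, inner_radii)
    vent = _ellipsoid(shape, center, vent_radii)
    gm = brain & ~interior
    csf = vent
    wm = interior & ~vent
    if not wm.any():
        raise ValueError("white matter region is empty on this grid")

    rng = np.random.default_rng(spec.seed)

    # WMH lesions: spheres fully inside WM, away from its borders
    wmh = np.zeros(shape, dtype=bool)
    if spec.n_wmh > 0:
        r_lo, r_hi = spec.wmh_radius_range
        dist_in_wm = ndimage.distance_transform_edt(wm)
        coords = np.indices(shape, dtype=float)
        for _ in range(spec.n_wmh):
            radius = int(rng.integers(r_lo, r_hi + 1))
            ok = np.argwhere(dist_in_wm > radius + 0.5)
            if len(ok) == 0:
                break
            c = ok[rng.integers(len(ok))]
            d2 = sum((coords[ax] - c[ax]) ** 2 for ax in range(3))
            wmh |= d2 <= radius ** 2
        wmh &= wm

    # true FW field
    true_f = np.zeros(shape, dtype=float)
    true_f[wm] = spec.f_wm
    if spec.csf_gradient_width > 0 and csf.any():
        d_csf_vox = ndimage.distance_transform_edt(~csf)
        ramp = spec.csf_gradient_amplitude * np.clip(
            1.0 - d_csf_vox / spec.csf_gradient_width, 0.0, None)
        true_f[wm] += ramp[wm]
    true_f[gm] = spec.f_gm
    true_f[wmh] = spec.f_wmh
    true_f[csf] = 1.0
    true_f = np.clip(true_f, 0.0, 1.0)

    # tissue tensors: anisotropic WM with smoothly rotating principal axis
    l1, l2, l3 = spec.wm_eigenvalues
    d6 = np.zeros(shape + (6,), dtype=float)
    x = np.indices(shape, dtype=float)[0]
    theta = np.pi * x / max(shape[0] - 1, 1)
    vx, vy = np.cos(theta), np.sin(theta)
    lam_t = (l2 + l3) / 2.0  # transverse (axially symmetric tensor)
    d6[..., 0] = lam_t + (l1 - lam_t) * vx * vx        # Dxx
    d6[..., 1] = (l1 - lam_t) * vx * vy                # Dxy
    d6[..., 3] = lam_t + (l1 - lam_t) * vy * vy        # Dyy
    d6[..., 5] = lam_t                                  # Dzz
    for iso_mask, d_iso in ((gm, spec.d_gm), (csf, spec.d_csf),
                            (~brain, spec.d_csf)):
        d6[iso_mask] = 0.0
        d6[iso_mask, 0] = d6[iso_mask, 3] = d6[iso_mask, 5] = d_iso

    gtab = make_gradient_table(spec.n_directions, spec.bval, spec.n_b0)
    design = _design_matrix(gtab)  # (n_grad, 6)
    water_att = np.exp(-gtab.bvals * spec.d_water)

    signal = np.zeros(shape + (len(gtab),), dtype=float)
    bidx = np.nonzero(brain)
    tissue_att = np.exp(d6[bidx] @ design.T)
    fb = true_f[bidx][:, None]
    signal[bidx] = spec.s0 * ((1.0 - fb) * tissue_att + fb * water_att[None, :])
    signal = add_rician_noise(signal, spec.rician_sigma, rng)

    grid = ImageGrid(shape, spec.voxel_size,
                     np.diag(list(spec.voxel_size) + [1.0]))
    as_mask = lambda v: BinaryMask(grid, v)
    tissues = TissueMaps(wm=as_mask(wm), gm=as_mask(gm), csf=as_mask(csf),
                         brain=as_mask(brain), wmh=as_mask(wmh))
    return Phantom(
        tissues=tissues,
        true_f=ScalarVolume(grid, true_f, units="fraction"),
        dwi=DWISeries(grid, signal, gtab),
        true_tensor=d6,
    )


# ---------------------------------------------------------------------------
# Cohorts


@dataclass
class CohortSpec:
    """Statistical structure of a synthetic cohort.

    Group sizes default to the target cohort (NC 81, MCI 103, AD 42);
    ``f_offsets`` shift the white-matter FW baseline per group (ordered
    NC < MCI < AD), with small per-subject Gaussian jitter.  WMH lesion
    counts are Poisson with a group-dependent mean, so lesion load grows
    along the disease spectrum.
    """

    n_per_group: dict[str, int] = field(
        default_factory=lambda: {"NC": 81, "MCI": 103, "AD": 42})
    f_offsets: dict[str, float] = field(
        default_factory=lambda: {"NC": 0.0, "MCI": 0.02, "AD": 0.04})
    offset_jitter_sd: float = 0.005
    age_mean_sd: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"NC": (73.0, 6.0), "MCI": (74.0, 7.0),
                                 "AD": (76.0, 8.0)})
    female_fraction: dict[str, float] = field(
        default_factory=lambda: {"NC": 0.5, "MCI": 0.5, "AD": 0.5})
    wmh_count_mean: dict[str, float] = field(
        default_factory=lambda: {"NC": 1.5, "MCI": 2.5, "AD": 3.5})
    seed: int = 0

    def __post_init__(self) -> None:
        for g, n in self.n_per_group.items():
            if n < 2:
                raise ValueError(f"group {g!r} needs at least 2 subjects")


@dataclass
class CohortSubject:
    subject_id: str
    group: str
    age: float
    gender: str
    phantom: Phantom


@dataclass
class CohortBundle:
    """All subjects plus the demographics table and a ground-truth metric
    table computed from the *true* FW fields (never from any fit)."""

    subjects: list[CohortSubject]
    demographics: pd.DataFrame
    ground_truth: pd.DataFrame


def make_cohort(pspec: Optional[PhantomSpec] = None,
                cspec: Optional[CohortSpec] = None,
                r_small: int = 1, r_brain: int = 3, wmh_dilation: int = 2,
                threshold: float = 0.1,
                out_dir: Optional[Union[str, Path]] = None) -> CohortBundle:
    """Generate a cohort of phantoms with group-level FW offsets.

    Morphology radii (voxels) are phantom-scale defaults — synthetic brains
    are tens of voxels across, so the brain-edge erosion defaults to 3
    rather than the full-size 15.  The ground-truth table applies the
    metrics layer to each subject's true FW field with these same radii.
    When ``out_dir`` is given the whole bundle is also written to disk
    (NIfTI volumes, bval/bvec, CSVs and a manifest).
    """
    pspec = pspec or PhantomSpec()
    cspec = cspec or CohortSpec()
    master = np.random.default_rng(cspec.seed)

    subjects: list[CohortSubject] = []
    demo_rows = []
    truth_records = []
    for group in [g for g in ("NC", "MCI", "AD") if g in cspec.n_per_group]:
        n = cspec.n_per_group[group]
        base_off = cspec.f_offsets.get(group, 0.0)
        a_mean, a_sd = cspec.age_mean_sd.get(group, (74.0, 7.0))
        f_frac = cspec.female_fraction.get(group, 0.5)
        wmh_mean = cspec.wmh_count_mean.get(group, pspec.n_wmh)
        for i in range(n):
            sid = f"{group}_{i:03d}"
            offset = base_off + master.normal(0.0, cspec.offset_jitter_sd)
            f_wm = float(np.clip(pspec.f_wm + offset, 0.0, 1.0))
            n_wmh = int(master.poisson(wmh_mean))
            sub_seed = int(master.integers(0, 2 ** 31 - 1))
            sub_spec = replace(pspec, f_wm=f_wm, n_wmh=n_wmh, seed=sub_seed)
            phantom = make_phantom(sub_spec)
            age = float(master.normal(a_mean, a_sd))
            gender = "F" if master.random() < f_frac else "M"
            subjects.append(CohortSubject(sid, group, age, gender, phantom))
            demo_rows.append({"subject_id": sid, "group": group,
                              "age": age, "gender": gender})

            wm_safe = build_wm_safe(phantom.tissues, r_small=r_small,
                                    r_brain=r_brain)
            wmh_exp = expand_wmh(phantom.tissues.wmh, radius=wmh_dilation)
            truth_records.extend(subject_metrics(
                phantom.true_f, phantom.tissues, wm_safe, wmh_exp,
                threshold=threshold, subject_id=sid))

    demographics = pd.DataFrame(demo_rows)
    ground_truth = wide_metrics(records_to_frame(truth_records))
    bundle = CohortBundle(subjects=subjects, demographics=demographics,
                          ground_truth=ground_truth)
    if out_dir is not None:
        write_cohort(bundle, out_dir)
    return bundle


def write_phantom(phantom: Phantom, subject_dir: Union[str, Path]) -> dict:
    """Write one subject's volumes and gradients; returns relative paths."""
    subject_dir = Path(subject_dir)
    subject_dir.mkdir(parents=True, exist_ok=True)
    t = phantom.tissues
    write_4d(phantom.dwi.signal, phantom.dwi.grid, subject_dir / "dwi.nii.gz")
    write_gradients(phantom.dwi.gtab, subject_dir / "dwi.bval",
                    subject_dir / "dwi.bvec")
    for name, mask in (("wm", t.wm), ("gm", t.gm), ("csf", t.csf),
                       ("brain", t.brain), ("wmh", t.wmh)):
        write_volume(mask, subject_dir / f"{name}_mask.nii.gz")
    write_volume(phantom.true_f, subject_dir / "true_fw.nii.gz")
    names = ["dwi.nii.gz", "dwi.bval", "dwi.bvec", "wm_mask.nii.gz",
             "gm_mask.nii.gz", "csf_mask.nii.gz", "brain_mask.nii.gz",
             "wmh_mask.nii.gz", "true_fw.nii.gz"]
    return {n: str(subject_dir / n) for n in names}


def write_cohort(bundle: CohortBundle, out_dir: Union[str, Path]) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {"subjects": {}}
    for sub in bundle.subjects:
        manifest["subjects"][sub.subject_id] = write_phantom(
            sub.phantom, out_dir / sub.subject_id)
    bundle.demographics.to_csv(out_dir / "demographics.csv", index=False)
    bundle.ground_truth.to_csv(out_dir / "ground_truth.csv", index=False)
    manifest["demographics"] = str(out_dir / "demographics.csv")
    manifest["ground_truth"] = str(out_dir / "ground_truth.csv")
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return out_dir / "manifest.json"
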