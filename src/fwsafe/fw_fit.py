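"""Bi-tensor free-water fitting for single-shell diffusion MRI.

The signal in a voxel is modelled as a mixture of two compartments: an
anisotropic tissue tensor ``D`` and an isotropic free-water compartment
with fixed diffusivity ``d_water`` (3.0e-3 mm^2/s, free water at body
temperature)::

    S_k = S0 * [ (1 - f) * exp(-b_k g_k^T D g_k) + f * exp(-b_k d_water) ]

``f`` is the free-water volume fraction; the 3-D image of ``f`` is the FW
map.  With a single shell this inverse problem is ill-posed without
constraints, so the fit is regularized three ways: tissue-tensor
eigenvalues are confined to a physiological band, ``f`` is confined to
[0, 1], and an optional spatial smoothness penalty ``lambda_reg *
sum ||grad f||^2`` couples neighbouring voxels.

The optimizer works on normalized signal (attenuation) space and exploits
the model's structure: for any fixed ``f`` the tissue compartment has a
closed-form fit (the standard log-linear tensor regression, with
eigenvalue clipping), so the objective can be *profiled* down to a 1-D
function of ``f``.  That profile is minimized per voxel by a deterministic
grid scan plus golden-section refinement — robust to the notoriously flat
valley of the single-shell problem, where plain alternating descent
stalls — followed by a short block-coordinate polish.  When the spatial
penalty is active, outer iterations alternate per-voxel updates with
Jacobi sweeps that solve the coupled quadratic ``f`` problem over the mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np

from .io_core import (
    BinaryMask,
    DWISeries,
    GradientTable,
    ImageGrid,
    ScalarVolume,
    write_4d,
    write_volume,
)

TENSOR_COMPONENTS = ("Dxx", "Dxy", "Dxz", "Dyy", "Dyz", "Dzz")


@dataclass
class FitConfig:
    """Parameters of the free-water fit.

    d_water : isotropic free-water diffusivity, mm^2/s.
    eig_min, eig_max : tissue-tensor eigenvalue bounds, mm^2/s.
    f_bounds : allowed free-water fraction interval, subset of [0, 1].
    max_iter : coordinate-descent polish iteration cap.
    tol : convergence threshold on the per-voxel objective decrease.
    lambda_reg : spatial smoothness weight on the f field (0 disables).
    n_outer : outer fit/smooth alternations when lambda_reg > 0.
    n_profile : grid points of the initial profile scan over f.
    n_golden : golden-section refinement iterations (each narrows the
        f bracket by the golden ratio).
    d_tissue_prior : mean-diffusivity prior used only for initialization.
    seed : reserved for randomized initialization; the default fit is
        fully deterministic and does not consume it.
    """

    d_water: float = 3.0e-3
    eig_min: float = 0.1e-3
    eig_max: float = 2.5e-3
    f_bounds: tuple[float, float] = (0.0, 1.0)
    max_iter: int = 10
    tol: float = 1e-10
    lambda_reg: float = 1.0
    n_outer: int = 10
    n_profile: int = 21
    n_golden: int = 12
    d_tissue_prior: float = 0.6e-3
    init_clip: tuple[float, float] = (0.05, 0.95)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.eig_min < self.eig_max):
            raise ValueError("require 0 < eig_min < eig_max")
        if self.d_water <= self.eig_max:
            raise ValueError("d_water must exceed eig_max")
        lo, hi = self.f_bounds
        if not (0.0 <= lo < hi <= 1.0):
            raise ValueError("f_bounds must be a sub-interval of [0, 1]")
        if self.lambda_reg < 0:
            raise ValueError("lambda_reg must be >= 0")


@dataclass
class FreeWaterFitResult:
    """Per-voxel output of :func:`fit_volume`.

    ``f_map`` holds NaN outside the mask and at unfittable voxels;
    ``tensor_map`` stores the 6 unique tensor components in the order
    (Dxx, Dxy, Dxz, Dyy, Dyz, Dzz).
    """

    f_map: ScalarVolume
    tensor_map: np.ndarray
    s0_map: ScalarVolume
    converged: np.ndarray
    n_iter: np.ndarray
    config: FitConfig = field(repr=False, default_factory=FitConfig)

    def write(self, out_dir: Union[str, Path], prefix: str = "") -> dict[str, Path]:
        """Write f/s0/tensor maps and convergence flags as NIfTI-1 files."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        grid = self.f_map.grid
        paths = {
            "f_map": write_volume(self.f_map, out_dir / f"{prefix}fw_map.nii.gz"),
            "s0_map": write_volume(self.s0_map, out_dir / f"{prefix}s0_map.nii.gz"),
            "tensor_map": write_4d(self.tensor_map, grid,
                                   out_dir / f"{prefix}tensor_map.nii.gz"),
            "converged": write_volume(
                BinaryMask(grid, self.converged), out_dir / f"{prefix}converged.nii.gz"
            ),
        }
        return paths


# ---------------------------------------------------------------------------
# Forward model


def _design_matrix(gtab: GradientTable) -> np.ndarray:
    """Rows -b * (gx^2, 2 gx gy, 2 gx gz, gy^2, 2 gy gz, gz^2), one per gradient,
    so that ``design @ d`` is the log-attenuation of tensor ``d``."""
    b = gtab.bvals
    g = gtab.bvecs
    gx, gy, gz = g[:, 0], g[:, 1], g[:, 2]
    cols = np.stack([gx * gx, 2 * gx * gy, 2 * gx * gz,
                     gy * gy, 2 * gy * gz, gz * gz], axis=1)
    return -b[:, None] * cols


def predict_signal(f: float, tensor: np.ndarray, s0: float,
                   gtab: GradientTable, d_water: float = 3.0e-3) -> np.ndarray:
    """Evaluate the bi-tensor forward model for one voxel.

    Returns one non-negative signal value per gradient; b=0 entries equal
    ``s0`` exactly regardless of ``f`` and the tensor.
    """
    if not 0.0 <= f <= 1.0:
        raise ValueError(f"free-water fraction {f} outside [0, 1]")
    tensor = np.asarray(tensor, dtype=float).ravel()
    if tensor.shape != (6,):
        raise ValueError("tensor must have 6 unique components")
    design = _design_matrix(gtab)
    tissue_att = np.exp(design @ tensor)
    water_att = np.exp(-gtab.bvals * d_water)
    return s0 * ((1.0 - f) * tissue_att + f * water_att)


def tensor_to_matrix(d6: np.ndarray) -> np.ndarray:
    """(..., 6) unique components -> (..., 3, 3) symmetric matrices."""
    d6 = np.asarray(d6, dtype=float)
    out = np.empty(d6.shape[:-1] + (3, 3), dtype=float)
    out[..., 0, 0] = d6[..., 0]
    out[..., 0, 1] = out[..., 1, 0] = d6[..., 1]
    out[..., 0, 2] = out[..., 2, 0] = d6[..., 2]
    out[..., 1, 1] = d6[..., 3]
    out[..., 1, 2] = out[..., 2, 1] = d6[..., 4]
    out[..., 2, 2] = d6[..., 5]
    return out


def matrix_to_tensor(m: np.ndarray) -> np.ndarray:
    m = np.asarray(m, dtype=float)
    return np.stack([m[..., 0, 0], m[..., 0, 1], m[..., 0, 2],
                     m[..., 1, 1], m[..., 1, 2], m[..., 2, 2]], axis=-1)


def _clip_eigenvalues(d6: np.ndarray, eig_min: float, eig_max: float) -> np.ndarray:
    """Project tensors onto the band of SPD matrices with eigenvalues in
    [eig_min, eig_max] (eigenvalue clipping, eigenvectors preserved)."""
    mats = tensor_to_matrix(d6)
    w, v = np.linalg.eigh(mats)
    w = np.clip(w, eig_min, eig_max)
    mats = np.einsum("...ij,...j,...kj->...ik", v, w, v)
    return matrix_to_tensor(mats)


# ---------------------------------------------------------------------------
# Initialization


def init_estimate(dwi_voxel: np.ndarray, gtab: GradientTable,
                  config: Optional[FitConfig] = None):
    """Initial (f0, tensor0, s0) for one voxel.

    s0 is the mean of the b=0 signals.  f0 places the voxel's geometric-mean
    attenuation on the log scale between a tissue prior
    ``exp(-b * d_tissue_prior)`` and the free-water value
    ``exp(-b * d_water)``, clipped to the configured window.  tensor0 is a
    log-linear tensor fit of the signal after removing the f0 water
    fraction, with eigenvalues clipped to bounds.

    Raises ``UnfittableVoxelError`` when s0 <= 0.
    """
    config = config or FitConfig()
    dwi_voxel = np.asarray(dwi_voxel, dtype=float)
    b0 = gtab.b0_mask
    if not b0.any() or b0.sum() == len(gtab):
        raise ValueError("need at least one b=0 and six weighted measurements")
    if (~b0).sum() < 6:
        raise ValueError("need at least six diffusion-weighted measurements")
    s0 = float(dwi_voxel[b0].mean())
    if not np.isfinite(s0) or s0 <= 0:
        raise UnfittableVoxelError("non-positive b=0 signal")
    att = np.clip(dwi_voxel[~b0] / s0, 1e-6, None)
    log_a = float(np.mean(np.log(att)))  # geometric mean, log domain
    b_mean = float(gtab.bvals[~b0].mean())
    log_tissue = -b_mean * config.d_tissue_prior
    log_water = -b_mean * config.d_water
    f0 = (log_a - log_tissue) / (log_water - log_tissue)
    f0 = float(np.clip(f0, *config.init_clip))
    tensor0 = _tensor_fit(att[None, :], np.full(1, f0),
                          _design_matrix(gtab)[~b0],
                          np.exp(-gtab.bvals[~b0] * config.d_water),
                          config)[0]
    return f0, tensor0, s0


class UnfittableVoxelError(ValueError):
    """Voxel cannot be fit (bad s0 or degenerate signal)."""


def _tensor_fit(att: np.ndarray, f: np.ndarray, design: np.ndarray,
                water_att: np.ndarray, config: FitConfig) -> np.ndarray:
    """Log-linear tensor fit of the tissue compartment, vectorized over voxels.

    ``att`` is (n_vox, n_dir) normalized signal at the weighted gradients.
    """
    f_eff = np.minimum(f, 1.0 - 1e-6)[:, None]
    tissue_att = (att - f_eff * water_att[None, :]) / (1.0 - f_eff)
    tissue_att = np.clip(tissue_att, 1e-6, 1.0)
    pinv = np.linalg.pinv(design)  # (6, n_dir)
    d6 = np.log(tissue_att) @ pinv.T
    return _clip_eigenvalues(d6, config.eig_min, config.eig_max)


def _f_closed_form(att: np.ndarray, tissue_att: np.ndarray,
                   water_att: np.ndarray, config: FitConfig):
    """Data-optimal f per voxel (quadratic in f) plus its curvature."""
    diff = water_att[None, :] - tissue_att
    num = ((att - tissue_att) * diff).sum(axis=1)
    den = (diff * diff).sum(axis=1)
    f_star = num / np.maximum(den, 1e-30)
    return np.clip(f_star, *config.f_bounds), den


def _objective(att, f, tissue_att, water_att):
    pred = (1.0 - f)[:, None] * tissue_att + f[:, None] * water_att[None, :]
    resid = att - pred
    return (resid * resid).sum(axis=1)


def _profile_objective(att, f, design, water_att, config):
    """Objective profiled over the tensor: best tensor given f, per voxel."""
    d6 = _tensor_fit(att, f, design, water_att, config)
    tissue_att = np.exp(d6 @ design.T)
    return _objective(att, f, tissue_att, water_att)


def _profile_search(att, design, water_att, config) -> np.ndarray:
    """Minimize the f-profiled objective per voxel: grid scan over
    ``n_profile`` points followed by ``n_golden`` golden-section steps.

    Deterministic and immune to the flat (f, tensor) valley that makes
    plain alternating descent stall on single-shell data.
    """
    lo, hi = config.f_bounds
    n = att.shape[0]
    grid = np.linspace(lo, hi, config.n_profile)
    best_f = np.full(n, lo)
    best_obj = np.full(n, np.inf)
    for fc in grid:
        obj = _profile_objective(att, np.full(n, fc), design, water_att, config)
        better = obj < best_obj
        best_f[better] = fc
        best_obj[better] = obj[better]
    step = (hi - lo) / (config.n_profile - 1)
    a = np.clip(best_f - step, lo, hi)
    b = np.clip(best_f + step, lo, hi)
    invphi = (np.sqrt(5.0) - 1.0) / 2.0
    for _ in range(config.n_golden):
        c = b - invphi * (b - a)
        d = a + invphi * (b - a)
        obj_c = _profile_objective(att, c, design, water_att, config)
        obj_d = _profile_objective(att, d, design, water_att, config)
        left = obj_c < obj_d
        b = np.where(left, d, b)
        a = np.where(left, a, c)
    return (a + b) / 2.0


def _descend(att, f, design, water_att, config, max_iter=None):
    """Block-coordinate (tensor, f) polish for a batch of voxels.

    Returns (f, tensor, tissue_att, objective, converged, n_iter).
    """
    max_iter = max_iter or config.max_iter
    n = att.shape[0]
    prev_obj = np.full(n, np.inf)
    converged = np.zeros(n, dtype=bool)
    n_iter = np.zeros(n, dtype=int)
    d6 = None
    tissue_att = None
    for it in range(max_iter):
        d6 = _tensor_fit(att, f, design, water_att, config)
        tissue_att = np.exp(d6 @ design.T)
        f, _ = _f_closed_form(att, tissue_att, water_att, config)
        obj = _objective(att, f, tissue_att, water_att)
        newly = ~converged & (prev_obj - obj < config.tol)
        converged |= newly
        n_iter[~converged] = it + 1
        prev_obj = obj
        if converged.all():
            break
    return f, d6, tissue_att, prev_obj, converged, n_iter


def _solve_batch(att, design, water_att, config):
    """Full per-voxel solve: profile search then descent polish."""
    f0 = _profile_search(att, design, water_att, config)
    return _descend(att, f0, design, water_att, config)


def fit_voxel(dwi_voxel: np.ndarray, gtab: GradientTable,
              config: Optional[FitConfig] = None):
    """Fit the bi-tensor model in a single voxel.

    Returns ``(f, tensor, s0, converged, n_iter)``.  Minimizes the sum of
    squared residuals between observed and predicted signal subject to
    ``f`` in ``f_bounds`` and tensor eigenvalues in [eig_min, eig_max]
    (enforced by eigenvalue clipping after each tensor update).
    """
    config = config or FitConfig()
    _, _, s0 = init_estimate(dwi_voxel, gtab, config)
    dwi_mask = gtab.dwi_mask
    att = np.clip(np.asarray(dwi_voxel, float)[dwi_mask] / s0, 0.0, None)[None, :]
    design = _design_matrix(gtab)[dwi_mask]
    water_att = np.exp(-gtab.bvals[dwi_mask] * config.d_water)
    f, d6, _, _, conv, n_iter = _solve_batch(att, design, water_att, config)
    return float(f[0]), d6[0], s0, bool(conv[0]), int(n_iter[0])


# ---------------------------------------------------------------------------
# Volume fit with optional spatial regularization


def _neighbor_sums(field3d: np.ndarray, valid: np.ndarray):
    """Sum of valid 6-neighbour values and the valid-neighbour count."""
    s = np.zeros_like(field3d)
    c = np.zeros(field3d.shape, dtype=float)
    vals = np.where(valid, field3d, 0.0)
    v = valid.astype(float)
    for axis in range(3):
        for shift in (1, -1):
            s += np.roll(vals, shift, axis=axis) * _roll_ok(valid, shift, axis)
            c += np.roll(v, shift, axis=axis) * _roll_ok(valid, shift, axis)
    return s, c


def _roll_ok(valid: np.ndarray, shift: int, axis: int) -> np.ndarray:
    """Mask of positions whose rolled neighbour is real (not wrapped) and valid."""
    ok = np.roll(valid, shift, axis=axis).astype(float)
    sl = [slice(None)] * 3
    sl[axis] = 0 if shift == 1 else -1
    ok[tuple(sl)] = 0.0
    return ok


def _smooth_f(f_flat, f_star, curvature, idx, shape, lambda_reg, n_sweeps=10):
    """Jacobi sweeps on a_v (f - f*_v)^2 + lambda * sum_edges (f_u - f_v)^2."""
    valid = np.zeros(shape, dtype=bool)
    valid[idx] = True
    f3 = np.zeros(shape, dtype=float)
    a3 = np.zeros(shape, dtype=float)
    fs3 = np.zeros(shape, dtype=float)
    f3[idx] = f_flat
    a3[idx] = curvature
    fs3[idx] = f_star
    for _ in range(n_sweeps):
        nb_sum, nb_cnt = _neighbor_sums(f3, valid)
        denom = a3 + 2.0 * lambda_reg * nb_cnt
        upd = (a3 * fs3 + 2.0 * lambda_reg * nb_sum) / np.maximum(denom, 1e-30)
        f3 = np.where(valid & (denom > 0), upd, f3)
    return f3[idx]


def fit_volume(dwi: DWISeries, mask: BinaryMask,
               config: Optional[FitConfig] = None) -> FreeWaterFitResult:
    """Fit the bi-tensor model at every voxel inside ``mask``.

    When ``config.lambda_reg > 0`` the per-voxel fits alternate with a
    spatial smoothing step on the f field (``n_outer`` outer iterations);
    with ``lambda_reg == 0`` a single coordinate-descent pass runs to
    convergence.  Voxels outside the mask, and unfittable voxels inside it
    (non-positive s0, all-zero signal), carry NaN in the output maps and
    are excluded downstream — never reported as 0.
    """
    config = config or FitConfig()
    if mask.n_true == 0:
        raise ValueError("empty fitting mask")
    if mask.grid.shape != dwi.grid.shape:
        raise ValueError("mask grid does not match DWI grid")
    gtab = dwi.gtab
    b0 = gtab.b0_mask
    if not b0.any() or (~b0).sum() < 6:
        raise ValueError("need >= 1 b=0 volume and >= 6 weighted directions")

    shape = dwi.grid.shape
    idx = np.nonzero(mask.values)
    sig = dwi.signal[idx]  # (n_vox, n_grad)
    s0 = sig[:, b0].mean(axis=1)
    fittable = np.isfinite(s0) & (s0 > 0) & np.isfinite(sig).all(axis=1) \
        & (sig[:, ~b0].max(axis=1) > 0)

    n = sig.shape[0]
    f = np.full(n, np.nan)
    d6 = np.full((n, 6), np.nan)
    conv = np.zeros(n, dtype=bool)
    n_iter = np.zeros(n, dtype=int)

    if fittable.any():
        sub = np.nonzero(fittable)[0]
        att = np.clip(sig[sub][:, ~b0] / s0[sub, None], 0.0, None)
        design = _design_matrix(gtab)[~b0]
        water_att = np.exp(-gtab.bvals[~b0] * config.d_water)

        f_cur, d6_s, tissue_att, _, c_s, it_s = _solve_batch(
            att, design, water_att, config)

        if config.lambda_reg > 0:
            sub_idx = tuple(ax[sub] for ax in idx)
            for _ in range(config.n_outer):
                f_star, curvature = _f_closed_form(att, tissue_att, water_att,
                                                   config)
                f_cur = _smooth_f(f_cur, f_star, curvature, sub_idx, shape,
                                  config.lambda_reg)
                f_cur = np.clip(f_cur, *config.f_bounds)
                d6_s = _tensor_fit(att, f_cur, design, water_att, config)
                tissue_att = np.exp(d6_s @ design.T)
        f[sub], d6[sub], conv[sub], n_iter[sub] = f_cur, d6_s, c_s, it_s

    def scatter(flat, fill=np.nan, dtype=float, extra=()):
        out = np.full(shape + tuple(extra), fill, dtype=dtype)
        out[idx] = flat
        return out

    grid = dwi.grid
    return FreeWaterFitResult(
        f_map=ScalarVolume(grid, scatter(f), units="fraction"),
        tensor_map=scatter(d6, extra=(6,)),
        s0_map=ScalarVolume(grid, scatter(np.where(fittable, s0, np.nan))),
        converged=scatter(conv, fill=False, dtype=bool),
        n_iter=scatter(n_iter, fill=0, dtype=int),
        config=config,
    )
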