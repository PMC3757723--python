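"""Intensity-driven nonlinear registration and template construction.

The nonlinear engine is a diffusion-regularized demons scheme: per
iteration an intensity-difference-driven update is computed from the
symmetrized image gradient, Gaussian-smoothed (fluid step), composed
additively into the displacement field, and the field itself smoothed
(diffusion step), coarse-to-fine over a multiresolution pyramid.  An
optional symmetric mode estimates the forward and backward fields jointly
and projects them towards mutual inverses, giving inverse-consistent
longitudinal transforms.

Displacement convention: the field ``u`` lives on the fixed-image grid in
voxel units, and the transform maps fixed-grid coordinate ``x`` to
moving-image coordinate ``x + u(x)``, so ``det(I + grad u)`` measures the
volume of moving-image tissue per unit fixed-grid volume.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates, zoom
from scipy.optimize import minimize

__all__ = [
    "DisplacementField",
    "RegistrationConfig",
    "AffineTransform",
    "register_affine",
    "register_nonlinear",
    "warp_volume",
    "invert_field",
    "build_mdt",
    "inverse_consistency_error",
    "RegistrationError",
]


class RegistrationError(RuntimeError):
    pass


@dataclass
class DisplacementField:
    """Per-voxel 3-vector displacement on the fixed-image grid (voxels)."""

    u: np.ndarray  # shape (3, nx, ny, nz)

    def __post_init__(self):
        u = np.asarray(self.u, dtype=np.float64)
        if u.ndim != 4 or u.shape[0] != 3:
            raise ValueError("field must have shape (3, nx, ny, nz)")
        if not np.isfinite(u).all():
            raise ValueError("field contains non-finite values")
        self.u = u

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return tuple(self.u.shape[1:])

    def magnitude(self) -> np.ndarray:
        return np.sqrt((self.u**2).sum(axis=0))


@dataclass(frozen=True)
class RegistrationConfig:
    n_levels: int = 3
    iters_per_level: tuple[int, ...] = (100, 80, 40)
    update_sigma: float = 1.0
    field_sigma: float = 0.8
    step_cap: float = 1.5  # voxels per iteration
    symmetric: bool = False
    tol: float = 1e-5

    def __post_init__(self):
        if self.n_levels < 1:
            raise ValueError("n_levels must be >= 1")
        if self.update_sigma < 0 or self.field_sigma < 0:
            raise ValueError("sigmas must be >= 0")
        if self.step_cap <= 0:
            raise ValueError("step_cap must be positive")
        if len(self.iters_per_level) < self.n_levels:
            raise ValueError("iters_per_level shorter than n_levels")


@dataclass
class AffineTransform:
    """x_moving = A @ x_fixed + t, voxel coordinates."""

    matrix: np.ndarray  # 3x3
    translation: np.ndarray  # 3
    final_ssd: float = np.nan

    def apply_to_coords(self, coords: np.ndarray) -> np.ndarray:
        flat = coords.reshape(3, -1)
        out = self.matrix @ flat + self.translation[:, None]
        return out.reshape(coords.shape)


def _grid_coords(shape):
    return np.indices(shape, dtype=np.float64)


def warp_volume(vol: np.ndarray, field: DisplacementField, order: int = 1) -> np.ndarray:
    """Resample ``vol`` at x + u(x); out-of-grid samples take background 0."""
    if tuple(vol.shape) != field.grid_shape:
        raise ValueError(
            f"shape mismatch: volume {vol.shape} vs field {field.grid_shape}"
        )
    coords = _grid_coords(vol.shape) + field.u
    return map_coordinates(vol, coords, order=order, mode="constant", cval=0.0)


def _sample_field(u: np.ndarray, coords: np.ndarray) -> np.ndarray:
    return np.stack(
        [
            map_coordinates(u[a], coords, order=1, mode="nearest")
            for a in range(3)
        ]
    )


def invert_field(field: DisplacementField, n_iter: int = 10) -> DisplacementField:
    """Fixed-point inversion: v(x) = -u(x + v(x))."""
    grid = _grid_coords(field.grid_shape)
    v = np.zeros_like(field.u)
    for _ in range(n_iter):
        v = -_sample_field(field.u, grid + v)
    return DisplacementField(v)


def inverse_consistency_error(
    fwd: DisplacementField, bwd: DisplacementField, margin: int = 2
) -> float:
    """Mean interior residual ||u_fwd(x + u_bwd(x)) + u_bwd(x)|| in voxels."""
    if fwd.grid_shape != bwd.grid_shape:
        raise ValueError("fields must share a grid")
    grid = _grid_coords(fwd.grid_shape)
    comp = _sample_field(fwd.u, grid + bwd.u) + bwd.u
    mag = np.sqrt((comp**2).sum(axis=0))
    sl = tuple(slice(margin, -margin) for _ in range(3))
    return float(mag[sl].mean())


# ---------------------------------------------------------------------------
# affine


def _affine_params_to_transform(params, dof):
    t = params[0:3]
    rot = params[3:6]
    scale = params[6:9]
    shear = params[9:12] if dof == 12 else np.zeros(3)
    cx, cy, cz = np.cos(rot)
    sx, sy, sz = np.sin(rot)
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    S = np.diag(scale)
    H = np.array([[1, shear[0], shear[1]], [0, 1, shear[2]], [0, 0, 1]])
    return Rx @ Ry @ Rz @ S @ H, np.asarray(t, float)


def register_affine(
    moving: np.ndarray,
    fixed: np.ndarray,
    dof: int = 12,
    smooth_sigma: float = 2.0,
) -> AffineTransform:
    """Affine (9 or 12 dof) alignment by minimizing the sum of squared
    intensity differences, optimized about the grid center.
    """
    if moving.shape != fixed.shape:
        raise ValueError("volumes must share a grid")
    if dof not in (9, 12):
        raise ValueError("dof must be 9 or 12")
    if fixed.std() == 0 or moving.std() == 0:
        raise RegistrationError("zero intensity variance")
    n_params = 12 if dof == 12 else 9
    x = np.concatenate([np.zeros(3), np.zeros(3), np.ones(3), np.zeros(3)])[:n_params]
    # centre-of-mass initialization keeps the optimizer local
    grids = _grid_coords(fixed.shape).reshape(3, -1)
    wf = np.clip(fixed, 0, None).ravel()
    wm = np.clip(moving, 0, None).ravel()
    com_f = grids @ wf / max(wf.sum(), 1e-12)
    com_m = grids @ wm / max(wm.sum(), 1e-12)
    x[0:3] = com_m - com_f
    baseline = final = None
    # coarse-to-fine: solve at half resolution, refine at full resolution
    for scale in (0.5, 1.0):
        fs = gaussian_filter(fixed, smooth_sigma)
        ms = gaussian_filter(moving, smooth_sigma)
        if scale < 1.0:
            fs, ms = zoom(fs, scale, order=1), zoom(ms, scale, order=1)
        center = (np.asarray(fs.shape, float) - 1) / 2.0
        grid = _grid_coords(fs.shape).reshape(3, -1) - center[:, None]

        def cost(params):
            A, t = _affine_params_to_transform(params, dof)
            coords = (A @ grid + t[:, None] + center[:, None]).reshape((3,) + fs.shape)
            warped = map_coordinates(ms, coords, order=1, mode="constant", cval=0.0)
            return float(((warped - fs) ** 2).mean())

        x[0:3] *= scale / (1.0 if baseline is None else 0.5)  # rescale translation
        if baseline is None:
            baseline = cost(x)
        res = minimize(
            cost, x, method="Powell",
            options={"xtol": 1e-3, "ftol": 1e-6, "maxfev": 4000},
        )
        x = res.x.copy()
        final = res.fun
    if final > cost(np.concatenate(
        [np.zeros(3), np.zeros(3), np.ones(3), np.zeros(3)])[:n_params]) * (1 + 1e-9):
        raise RegistrationError(
            f"affine registration diverged: SSD {final:.4g} did not improve"
        )
    center = (np.asarray(fixed.shape, float) - 1) / 2.0
    A, t = _affine_params_to_transform(x, dof)
    # cost parameterizes x -> A (x - c) + t + c; report the origin form
    t_origin = t + center - A @ center
    return AffineTransform(matrix=A, translation=t_origin, final_ssd=float(res.fun))


# ---------------------------------------------------------------------------
# demons


def _image_gradient(img):
    return np.stack(np.gradient(img))


def _demons_update(fixed, warped_moving, grad_fixed, step_cap):
    diff = fixed - warped_moving
    grad = 0.5 * (grad_fixed + _image_gradient(warped_moving))
    gnorm2 = (grad**2).sum(axis=0)
    denom = gnorm2 + diff**2
    with np.errstate(invalid="ignore", divide="ignore"):
        upd = np.where(denom > 1e-12, diff / denom, 0.0)[None] * grad
    mag = np.sqrt((upd**2).sum(axis=0))
    over = mag > step_cap
    if over.any():
        upd = np.where(over[None], upd * (step_cap / np.maximum(mag, 1e-12))[None], upd)
    return upd


def _zero_boundary(u):
    for ax in range(3):
        sl = [slice(None)] * 4
        for edge in (0, -1):
            sl[ax + 1] = edge
            u[tuple(sl)] = 0.0
    return u


def _demons_level(fixed, moving, u, cfg: RegistrationConfig, iters: int,
                  history: list | None = None):
    grid = _grid_coords(fixed.shape)
    grad_fixed = _image_gradient(fixed)
    prev = None
    for _ in range(iters):
        warped = map_coordinates(
            moving, grid + u, order=1, mode="constant", cval=0.0
        )
        ssd = float(((warped - fixed) ** 2).mean())
        if history is not None:
            history.append(ssd)
        if prev is not None and prev - ssd < cfg.tol * max(prev, 1e-30):
            break
        prev = ssd
        upd = _demons_update(fixed, warped, grad_fixed, cfg.step_cap)
        if cfg.update_sigma > 0:
            upd = gaussian_filter(upd, (0, cfg.update_sigma, cfg.update_sigma, cfg.update_sigma))
        u = u + upd
        if cfg.field_sigma > 0:
            u = gaussian_filter(u, (0, cfg.field_sigma, cfg.field_sigma, cfg.field_sigma))
        u = _zero_boundary(u)
    return u


def _resize_field(u, new_shape):
    factors = [ns / os for ns, os in zip(new_shape, u.shape[1:])]
    out = np.stack(
        [zoom(u[a], factors, order=1, mode="nearest") * factors[a] for a in range(3)]
    )
    return out


def _pyramid(img, n_levels):
    levels = [img]
    for _ in range(n_levels - 1):
        levels.append(zoom(gaussian_filter(levels[-1], 1.0), 0.5, order=1))
    return levels[::-1]  # coarse first


def _jacobian_positive_fraction(u):
    from .jacobian import jacobian_determinant_array

    j = jacobian_determinant_array(u)
    core = j[2:-2, 2:-2, 2:-2]
    return float((core > 0).mean())


def register_nonlinear(
    moving: np.ndarray,
    fixed: np.ndarray,
    config: RegistrationConfig | None = None,
) -> DisplacementField:
    """Demons registration of ``moving`` onto ``fixed``.

    Returns the forward field (fixed grid -> moving coordinates).  In
    symmetric mode the backward field is estimated jointly and the two are
    projected toward mutual inverses; the returned field carries the
    backward field in the ``backward`` attribute.
    """
    cfg = config or RegistrationConfig()
    if moving.shape != fixed.shape:
        raise ValueError("volumes must share a grid")

    f_pyr = _pyramid(fixed, cfg.n_levels)
    m_pyr = _pyramid(moving, cfg.n_levels)
    u = np.zeros((3,) + f_pyr[0].shape)
    ub = np.zeros_like(u) if cfg.symmetric else None
    ssd_history: list[list[float]] = []
    for lev, (f, m) in enumerate(zip(f_pyr, m_pyr)):
        if u.shape[1:] != f.shape:
            u = _resize_field(u, f.shape)
            if ub is not None:
                ub = _resize_field(ub, f.shape)
        iters = cfg.iters_per_level[lev]
        level_hist: list[float] = []
        ssd_history.append(level_hist)
        if not cfg.symmetric:
            u = _demons_level(f, m, u, cfg, iters, history=level_hist)
        else:
            # joint estimation with periodic inverse-consistency projection
            block = max(1, iters // 3)
            done = 0
            while done < iters:
                n = min(block, iters - done)
                u = _demons_level(f, m, u, cfg, n)
                ub = _demons_level(m, f, ub, cfg, n)
                u_inv = invert_field(DisplacementField(ub), n_iter=4).u
                ub_inv = invert_field(DisplacementField(u), n_iter=4).u
                u = _zero_boundary(0.5 * (u + u_inv))
                ub = _zero_boundary(0.5 * (ub + ub_inv))
                done += n
    frac = _jacobian_positive_fraction(u)
    if frac < 1.0:
        if frac < 0.99:
            raise RegistrationError(
                f"non-positive Jacobian on {100 * (1 - frac):.1f}% of interior "
                "voxels; increase field_sigma / reduce step_cap"
            )
    field = DisplacementField(u)
    field.ssd_history = ssd_history
    if ub is not None:
        field.backward = DisplacementField(ub)
    return field


def build_mdt(
    volumes: list[np.ndarray],
    n_iter: int = 2,
    config: RegistrationConfig | None = None,
) -> tuple[np.ndarray, list[DisplacementField]]:
    """Minimal deformation template: iteratively register the group to the
    evolving mean and re-center it so the average displacement shrinks
    towards zero.
    """
    if len(volumes) < 3:
        raise ValueError("need at least 3 volumes")
    shapes = {v.shape for v in volumes}
    if len(shapes) != 1:
        raise ValueError("all volumes must share a grid")
    cfg = config or RegistrationConfig()
    template = np.mean(volumes, axis=0)
    fields: list[DisplacementField] = []
    for _ in range(n_iter):
        fields = []
        for i, vol in enumerate(volumes):
            try:
                fields.append(register_nonlinear(vol, template, cfg))
            except RegistrationError as exc:
                raise RegistrationError(f"member {i} failed: {exc}") from exc
        warped = [warp_volume(v, f) for v, f in zip(volumes, fields)]
        mean_img = np.mean(warped, axis=0)
        mean_u = DisplacementField(np.mean([f.u for f in fields], axis=0))
        template = warp_volume(mean_img, invert_field(mean_u))
    return template, fields
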