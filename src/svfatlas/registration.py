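"""Pairwise diffeomorphic registration with a stationary velocity field.

Estimates the SVF ``v`` minimizing

    E(v) = Sim(moving ∘ exp(v), fixed) + reg_weight * ||grad v||^2

by multiresolution gradient descent. The similarity is either SSD (sum of
squared differences) or LNCC (local normalized cross-correlation, squared,
ANTs-style); the regularizer is first-order (diffusion). Velocity updates are
Gaussian-smoothed and step sizes are controlled by backtracking so the
recorded energy is non-increasing across accepted iterations. Initialization
is the zero field unless an initial SVF is supplied.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .fields import Image3D, InvalidInputError, VelocityField, check_same_grid
from .diffeo import exp_svf, warp

__all__ = ["RegistrationConfig", "register", "energy", "RegistrationResult"]

_EPS = 1e-8


@dataclass
class RegistrationConfig:
    """Registration hyperparameters.

    levels : depth of the multiresolution pyramid (coarsest is /2^(levels-1)).
    iters_per_level : maximum gradient iterations at each level.
    similarity : 'ssd' or 'lncc'; lncc_radius is the local window half-width.
    reg_weight : weight of the diffusion penalty ||grad v||^2.
    step_size : maximum voxel displacement added per update (the smoothed
        descent direction is rescaled to this length).
    smooth_update_sigma : Gaussian sigma (voxels) applied to each update.
    converge_tol : stop when the relative energy decrease falls below this.
    max_backtracks : step halvings allowed before the level terminates.
    """

    levels: int = 3
    iters_per_level: int = 100
    similarity: str = "lncc"
    lncc_radius: int = 2
    reg_weight: float = 0.01
    step_size: float = 0.4
    smooth_update_sigma: float = 1.5
    converge_tol: float = 1e-6
    max_backtracks: int = 10

    def __post_init__(self):
        if self.levels < 1:
            raise InvalidInputError("levels must be >= 1")
        if self.reg_weight < 0:
            raise InvalidInputError("reg_weight must be nonnegative")
        if self.step_size <= 0:
            raise InvalidInputError("step_size must be positive")
        if self.similarity not in ("ssd", "lncc"):
            raise InvalidInputError(f"unknown similarity {self.similarity!r}")


@dataclass
class RegistrationResult:
    """Estimated velocity plus one energy trace per pyramid level; each trace
    is non-increasing across accepted iterations."""

    velocity: VelocityField
    energies: list = field(default_factory=list)


def _check_inputs(moving: Image3D, fixed: Image3D) -> None:
    check_same_grid(moving, fixed, "register")
    if not (np.all(np.isfinite(moving.values)) and np.all(np.isfinite(fixed.values))):
        raise InvalidInputError("registration inputs must be finite")


def _gradient(vol: np.ndarray) -> np.ndarray:
    return np.stack(np.gradient(vol), axis=-1)


def _local_sums(x: np.ndarray, radius: int) -> np.ndarray:
    size = 2 * radius + 1
    return ndimage.uniform_filter(x, size=size, mode="constant") * size ** 3


def _lncc_terms(warped: np.ndarray, fixed: np.ndarray, radius: int):
    size = 2 * radius + 1
    n = size ** 3
    sw = _local_sums(warped, radius)
    sf = _local_sums(fixed, radius)
    wbar = warped - sw / n
    fbar = fixed - sf / n
    a = _local_sums(warped * fixed, radius) - sw * sf / n          # cov * n
    b = _local_sums(warped * warped, radius) - sw * sw / n          # var_w * n
    c = _local_sums(fixed * fixed, radius) - sf * sf / n            # var_f * n
    return wbar, fbar, a, b, c


def _lncc_delta(fixed: np.ndarray, radius: int, rel_floor: float = 1e-3) -> float:
    """Variance floor for the LNCC denominator: windows whose local variance
    is far below (rel_floor * dynamic range)^2 are effectively structureless
    and must not contribute unstable correlation values."""
    n = (2 * radius + 1) ** 3
    rng_ = float(np.ptp(fixed))
    return n * (rel_floor * max(rng_, _EPS)) ** 2


def _similarity_value(warped: np.ndarray, fixed: np.ndarray, cfg: RegistrationConfig) -> float:
    if cfg.similarity == "ssd":
        diff = warped - fixed
        return float((diff * diff).sum())
    _, _, a, b, c = _lncc_terms(warped, fixed, cfg.lncc_radius)
    delta = _lncc_delta(fixed, cfg.lncc_radius)
    cc2 = (a * a) / ((b + delta) * (c + delta))
    return float(-cc2.sum())


def _similarity_force(warped: np.ndarray, fixed: np.ndarray, cfg: RegistrationConfig) -> np.ndarray:
    """Approximate gradient of the similarity with respect to the velocity,
    using the first-order (demons-style) identification dW/dv ~= grad W."""
    grad_w = _gradient(warped)
    if cfg.similarity == "ssd":
        resid = 2.0 * (warped - fixed)
        return resid[..., None] * grad_w
    # exact derivative of -sum_windows cc^2: every voxel collects the
    # contributions of all windows containing it (box-filter sums)
    radius = cfg.lncc_radius
    size = 2 * radius + 1
    n = size ** 3
    sw = _local_sums(warped, radius)
    sf = _local_sums(fixed, radius)
    a = _local_sums(warped * fixed, radius) - sw * sf / n
    b = _local_sums(warped * warped, radius) - sw * sw / n
    c = _local_sums(fixed * fixed, radius) - sf * sf / n
    delta = _lncc_delta(fixed, radius)
    denom = (b + delta) * (c + delta)
    p = a / denom                         # weight of F-bar term per window
    q = a * a / (denom * (b + delta))     # weight of W-bar term per window
    mu_w = sw / n
    mu_f = sf / n
    sum_p = _local_sums(p, radius)
    sum_q = _local_sums(q, radius)
    sum_mix = _local_sums(p * mu_f - q * mu_w, radius)
    coeff = -2.0 * (fixed * sum_p - warped * sum_q - sum_mix)
    return coeff[..., None] * grad_w


def _reg_value(v: np.ndarray) -> float:
    total = 0.0
    for comp in range(3):
        for g in np.gradient(v[..., comp]):
            total += float((g * g).sum())
    return total


def _reg_gradient(v: np.ndarray) -> np.ndarray:
    """Gradient of ||grad v||^2 w.r.t. v: -2 * Laplacian(v)."""
    out = np.empty_like(v)
    for comp in range(3):
        out[..., comp] = -2.0 * ndimage.laplace(v[..., comp], mode="nearest")
    return out


def energy(moving: Image3D, fixed: Image3D, v: VelocityField,
           config: RegistrationConfig | None = None) -> float:
    """E(v) = Sim(moving ∘ exp(v), fixed) + reg_weight * ||grad v||^2.

    With v = 0, identical images and SSD similarity the energy is exactly 0.
    """
    config = config or RegistrationConfig()
    _check_inputs(moving, fixed)
    check_same_grid(moving, v, "energy")
    warped = warp(moving, exp_svf(v), mode="linear").values
    val = _similarity_value(warped, fixed.values, config)
    if config.reg_weight > 0:
        val += config.reg_weight * _reg_value(v.vectors)
    return val


def _downsample_image(img: np.ndarray, factor: int) -> np.ndarray:
    if factor == 1:
        return img
    sm = ndimage.gaussian_filter(img, sigma=0.5 * factor)
    return ndimage.zoom(sm, 1.0 / factor, order=1)


def _upsample_velocity(v: np.ndarray, target_shape: tuple) -> np.ndarray:
    zoom = [t / s for t, s in zip(target_shape, v.shape[:3])]
    out = np.stack([ndimage.zoom(v[..., c], zoom, order=1) for c in range(3)], axis=-1)
    for c in range(3):
        out[..., c] *= zoom[c]
    return out


def _descend_level(moving: np.ndarray, fixed: np.ndarray, v: np.ndarray,
                   cfg: RegistrationConfig, energies: list) -> np.ndarray:
    mov_img = Image3D(moving)
    fix_img = Image3D(fixed)

    def total_energy(vec: np.ndarray) -> float:
        warped = warp(mov_img, exp_svf(VelocityField(vec)), mode="linear").values
        val = _similarity_value(warped, fixed, cfg)
        if cfg.reg_weight > 0:
            val += cfg.reg_weight * _reg_value(vec)
        return val

    e_cur = total_energy(v)
    energies.append(e_cur)
    step = cfg.step_size
    for _ in range(cfg.iters_per_level):
        warped = warp(mov_img, exp_svf(VelocityField(v)), mode="linear").values
        g = _similarity_force(warped, fixed, cfg)
        if cfg.reg_weight > 0:
            g = g + cfg.reg_weight * _reg_gradient(v)
        for c in range(3):
            g[..., c] = ndimage.gaussian_filter(g[..., c], cfg.smooth_update_sigma)
        gmax = np.sqrt((g * g).sum(axis=-1)).max()
        if gmax < _EPS:
            break
        direction = g / gmax  # unit-capped descent direction, step = max voxels moved
        accepted = False
        for _bt in range(cfg.max_backtracks + 1):
            trial = v - step * direction
            e_trial = total_energy(trial)
            if e_trial <= e_cur:
                accepted = True
                break
            step *= 0.5
        if not accepted:
            break
        rel_drop = (e_cur - e_trial) / (abs(e_cur) + _EPS)
        v = trial
        e_cur = e_trial
        energies.append(e_cur)
        step = min(step * 1.2, cfg.step_size)
        if rel_drop < cfg.converge_tol:
            break
    return v


def register(moving: Image3D, fixed: Image3D, config: RegistrationConfig | None = None,
             init: VelocityField | None = None, return_result: bool = False):
    """Estimate the SVF mapping ``moving`` onto ``fixed``.

    Runs coarse-to-fine over a Gaussian pyramid; the velocity estimated at
    each level is upsampled (and rescaled to voxel units of the finer grid)
    to initialize the next. Returns the VelocityField, or a
    RegistrationResult carrying the per-iteration energy trace.
    """
    config = config or RegistrationConfig()
    _check_inputs(moving, fixed)
    if init is not None:
        check_same_grid(moving, init, "register init")
        v_full = init.vectors.copy()
    else:
        v_full = np.zeros(moving.shape + (3,))

    shape = np.asarray(moving.shape)
    factors = []
    for lev in range(config.levels - 1, -1, -1):
        f = 2 ** lev
        if np.all(shape // f >= 8):
            factors.append(f)
    if not factors:
        factors = [1]

    energies: list = []
    v = None
    for factor in factors:
        mov_l = _downsample_image(moving.values, factor)
        fix_l = _downsample_image(fixed.values, factor)
        if v is None:
            v = _upsample_velocity(v_full, mov_l.shape) if factor != 1 else v_full.copy()
        else:
            v = _upsample_velocity(v, mov_l.shape)
        level_trace: list = []
        v = _descend_level(mov_l, fix_l, v, config, level_trace)
        energies.append(level_trace)
    if v.shape[:3] != moving.shape:
        v = _upsample_velocity(v, moving.shape)
    result = VelocityField(v, moving.spacing.copy(), moving.origin.copy())
    if return_result:
        return RegistrationResult(velocity=result, energies=energies)
    return result
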