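"""Thin-plate-spline densification of sparse control-point displacements.

A TPS interpolant f(p) = a0 + a·p + Σ_i w_i U(‖p − c_i‖), U(r) = r² log r,
minimises bending energy subject to exact interpolation at the control
points.  With the control points and evaluation pixels fixed, the dense
field is a *linear* map of the control values, so we precompute the basis
matrix once and reuse it (this also makes the network head differentiable
through the densification for free).
"""

from __future__ import annotations

import numpy as np

from ischemap.errors import ValidationError


def make_control_grid(shape: tuple, grid: tuple) -> np.ndarray:
    """(G_r·G_c, 2) control-point coordinates spanning the image."""
    h, w = shape
    gr, gc = grid
    if gr < 2 or gc < 2:
        raise ValidationError("control grid must be at least 2x2")
    rows = np.linspace(0.0, h - 1.0, gr)
    cols = np.linspace(0.0, w - 1.0, gc)
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    return np.stack([rr.ravel(), cc.ravel()], axis=1)


def _kernel(r2: np.ndarray) -> np.ndarray:
    # U(r) = r^2 log r = 0.5 r^2 log r^2; define U(0) = 0
    with np.errstate(divide="ignore", invalid="ignore"):
        u = 0.5 * r2 * np.log(r2)
    u[r2 == 0.0] = 0.0
    return u


def tps_basis(shape: tuple, control_points: np.ndarray,
              reg: float = 0.0) -> np.ndarray:
    """(H·W, M) matrix B with dense_component = B @ control_values.

    ``reg`` adds Tikhonov smoothing on the kernel block (0 = exact
    interpolation at the control points).
    """
    h, w = shape
    c = np.asarray(control_points, dtype=np.float64)
    m = c.shape[0]
    d2 = ((c[:, None, :] - c[None, :, :]) ** 2).sum(axis=2)
    k = _kernel(d2) + reg * np.eye(m)
    p = np.concatenate([np.ones((m, 1)), c], axis=1)
    lmat = np.zeros((m + 3, m + 3))
    lmat[:m, :m] = k
    lmat[:m, m:] = p
    lmat[m:, :m] = p.T
    linv = np.linalg.solve(lmat, np.eye(m + 3))[:, :m]
    rr, cc = np.meshgrid(np.arange(h, dtype=np.float64),
                         np.arange(w, dtype=np.float64), indexing="ij")
    pts = np.stack([rr.ravel(), cc.ravel()], axis=1)      # (HW, 2)
    d2e = ((pts[:, None, :] - c[None, :, :]) ** 2).sum(axis=2)
    e = np.concatenate([_kernel(d2e), np.ones((pts.shape[0], 1)), pts], axis=1)
    return e @ linv                                        # (HW, M)


def densify(control_values: np.ndarray, basis: np.ndarray,
            shape: tuple) -> np.ndarray:
    """(2, M) or (2, G_r, G_c) control displacements -> (2, H, W) field."""
    v = np.asarray(control_values, dtype=np.float64).reshape(2, -1)
    dense = basis @ v.T                                    # (HW, 2)
    return dense.T.reshape(2, *shape)


def random_tps_field(shape: tuple, magnitude: float,
                     rng: np.random.Generator,
                     grid: tuple = (4, 4)) -> np.ndarray:
    """Smooth random (2, H, W) field with control offsets ≤ ``magnitude`` px."""
    if magnitude < 0:
        raise ValidationError("warp magnitude must be nonnegative")
    pts = make_control_grid(shape, grid)
    offsets = rng.uniform(-magnitude, magnitude, size=(2, pts.shape[0]))
    if magnitude == 0.0:
        return np.zeros((2, *shape))
    basis = tps_basis(shape, pts)
    return densify(offsets, basis, shape)


def sample_field(field: np.ndarray, points: np.ndarray) -> np.ndarray:
    """Bilinearly sample a (2, H, W) field at (N, 2) row/col points."""
    _, h, w = field.shape
    pts = np.asarray(points, dtype=np.float64)
    r = np.clip(pts[:, 0], 0, h - 1)
    c = np.clip(pts[:, 1], 0, w - 1)
    r0 = np.minimum(np.floor(r), h - 2).astype(int)
    c0 = np.minimum(np.floor(c), w - 2).astype(int)
    fr, fc = r - r0, c - c0
    out = ((1 - fr) * (1 - fc) * field[:, r0, c0]
           + (1 - fr) * fc * field[:, r0, c0 + 1]
           + fr * (1 - fc) * field[:, r0 + 1, c0]
           + fr * fc * field[:, r0 + 1, c0 + 1])
    return out.T                                           # (N, 2)


def invert_at_points(field: np.ndarray, targets: np.ndarray,
                     n_iter: int = 25) -> np.ndarray:
    """Solve p + φ(p) = q for p by fixed-point iteration (small smooth φ)."""
    p = np.asarray(targets, dtype=np.float64).copy()
    q = np.asarray(targets, dtype=np.float64)
    for _ in range(n_iter):
        p = q - sample_field(field, p)
    return p
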