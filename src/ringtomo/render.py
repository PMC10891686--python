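"""Volume rendering: parallel-projection ray casting and re-slicing.

Every voxel is assigned a color and an opacity through piecewise-linear
transfer functions of its gray value (optionally modulated by gradient
magnitude).  A ray is cast through the volume from each pixel of the
projection plane (viewpoint at infinity, i.e. parallel projection),
sampled at equidistant points by trilinear interpolation, and composited
front to back:

    C <- C + (1 - A) * alpha_i * color_i
    A <- A + (1 - A) * alpha_i

terminating early once A >= 0.99 (the ray is effectively absorbed;
exactly 1.0 is unreachable in floating point).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml
from scipy import ndimage

from .interp import VolumeGrid

__all__ = ["TransferFunction", "Camera", "CompositeState", "SectionImages",
           "trilinear_sample", "composite_front_to_back", "ray_cast",
           "render_orthogonal_sections"]

EARLY_TERMINATION = 0.99


def _check_points(pts):
    pts = np.asarray(pts, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("control points must be (n, 2)")
    if np.any(np.diff(pts[:, 0]) < 0):
        raise ValueError("control points must be sorted by gray value")
    return pts


@dataclass
class TransferFunction:
    """Piecewise-linear gray -> RGB, gray -> alpha, |grad| -> alpha maps.

    ``gray_to_color`` holds (gray, r, g, b) rows; ``gray_to_opacity``
    (gray, alpha) rows; the optional ``gradient_to_opacity`` (|grad|
    normalized to [0, 1], multiplier) rows.
    """

    gray_to_color: np.ndarray
    gray_to_opacity: np.ndarray
    gradient_to_opacity: np.ndarray | None = None

    def __post_init__(self):
        self.gray_to_color = np.asarray(self.gray_to_color, dtype=float)
        if self.gray_to_color.ndim != 2 or self.gray_to_color.shape[1] != 4:
            raise ValueError("gray_to_color must be (n, 4): gray, r, g, b")
        if np.any(np.diff(self.gray_to_color[:, 0]) < 0):
            raise ValueError("color control points must be sorted")
        self.gray_to_opacity = _check_points(self.gray_to_opacity)
        if np.any((self.gray_to_opacity[:, 1] < 0) |
                  (self.gray_to_opacity[:, 1] > 1)):
            raise ValueError("opacity must lie in [0, 1]")
        if self.gradient_to_opacity is not None:
            self.gradient_to_opacity = _check_points(self.gradient_to_opacity)

    def color(self, gray):
        g = self.gray_to_color[:, 0]
        return np.stack([np.interp(gray, g, self.gray_to_color[:, k])
                         for k in (1, 2, 3)], axis=-1)

    def opacity(self, gray, grad_norm=None):
        a = np.interp(gray, self.gray_to_opacity[:, 0],
                      self.gray_to_opacity[:, 1])
        if self.gradient_to_opacity is not None and grad_norm is not None:
            a = a * np.interp(grad_norm, self.gradient_to_opacity[:, 0],
                              self.gradient_to_opacity[:, 1])
        return np.clip(a, 0.0, 1.0)

    @classmethod
    def grayscale(cls, opacity_scale: float = 1.0) -> "TransferFunction":
        """Neutral preset: gray maps to itself, opacity ramps with gray."""
        return cls(
            gray_to_color=[[0, 0, 0, 0], [1, 1, 1, 1]],
            gray_to_opacity=[[0, 0], [1, opacity_scale]],
        )

    def to_yaml(self, path=None) -> str:
        d = {
            "gray_to_color": np.asarray(self.gray_to_color).tolist(),
            "gray_to_opacity": np.asarray(self.gray_to_opacity).tolist(),
        }
        if self.gradient_to_opacity is not None:
            d["gradient_to_opacity"] = np.asarray(
                self.gradient_to_opacity).tolist()
        text = yaml.safe_dump(d, sort_keys=False)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "TransferFunction":
        try:
            with open(source) as fh:
                d = yaml.safe_load(fh)
        except (OSError, TypeError, ValueError):
            d = yaml.safe_load(source)
        return cls(
            gray_to_color=d["gray_to_color"],
            gray_to_opacity=d["gray_to_opacity"],
            gradient_to_opacity=d.get("gradient_to_opacity"),
        )


@dataclass
class Camera:
    """Parallel-projection camera.

    ``view`` is the ray direction, ``up`` the image vertical; the two are
    orthonormalized.  The image plane is centered on the volume center.
    """

    view: tuple
    up: tuple = (0.0, 0.0, 1.0)
    image_size: tuple = (128, 128)  # (ny, nx) pixels
    pixel_pitch: float = 1.0  # mm

    def basis(self):
        v = np.asarray(self.view, dtype=float)
        nv = np.linalg.norm(v)
        if nv == 0:
            raise ValueError("view direction must be nonzero")
        v = v / nv
        u = np.asarray(self.up, dtype=float)
        u = u - np.dot(u, v) * v
        nu = np.linalg.norm(u)
        if nu < 1e-12:
            raise ValueError("up direction is parallel to the view direction")
        u = u / nu
        r = np.cross(v, u)
        return v, u, r

    @classmethod
    def from_angles(cls, azimuth_deg: float, elevation_deg: float,
                    **kwargs) -> "Camera":
        az = np.deg2rad(azimuth_deg)
        el = np.deg2rad(elevation_deg)
        view = (-np.cos(el) * np.cos(az), -np.cos(el) * np.sin(az),
                -np.sin(el))
        return cls(view=view, **kwargs)


@dataclass
class CompositeState:
    """Accumulated color and opacity along a ray."""

    color: np.ndarray = field(default_factory=lambda: np.zeros(3))
    alpha: float = 0.0


def trilinear_sample(volume: VolumeGrid, p) -> np.ndarray:
    """Sample the volume at physical points ``p`` (xyz mm, (..., 3)).

    Standard 8-corner trilinear blend; points outside the grid return 0.
    """
    p = np.asarray(p, dtype=float)
    scalar = p.ndim == 1
    pts = np.atleast_2d(p)
    x0, y0, z0 = volume.origin
    dx, dy, dz = volume.spacing
    fz = (pts[:, 2] - z0) / dz
    fy = (pts[:, 1] - y0) / dy
    fx = (pts[:, 0] - x0) / dx
    nz, ny, nx = volume.values.shape
    inside = ((fx >= 0) & (fx <= nx - 1) & (fy >= 0) & (fy <= ny - 1) &
              (fz >= 0) & (fz <= nz - 1))
    out = np.zeros(pts.shape[0])
    if np.any(inside):
        coords = np.vstack([fz[inside], fy[inside], fx[inside]])
        out[inside] = ndimage.map_coordinates(volume.values, coords, order=1,
                                              mode="nearest")
    return float(out[0]) if scalar else out


def composite_front_to_back(samples) -> tuple:
    """Composite an ordered (front first) list of (color, alpha) samples.

    Returns (C, A).  Stops early once A >= 0.99.
    """
    state = CompositeState()
    for color, alpha in samples:
        alpha = float(alpha)
        if not (0.0 <= alpha <= 1.0):
            raise ValueError(f"alpha {alpha} outside [0, 1]")
        color = np.asarray(color, dtype=float)
        trans = 1.0 - state.alpha
        state.color = state.color + trans * alpha * color
        state.alpha = state.alpha + trans * alpha
        if state.alpha >= EARLY_TERMINATION:
            break
    return state.color, state.alpha


def _bbox_entry_exit(origin, direction, lo, hi):
    """Slab-method ray/box intersection; returns (t_near, t_far)."""
    with np.errstate(divide="ignore", invalid="ignore"):
        inv = 1.0 / direction
        t1 = (lo - origin) * inv
        t2 = (hi - origin) * inv
    par = np.broadcast_to(direction == 0, t1.shape)
    t1 = np.where(par, -np.inf, t1)
    t2 = np.where(par, np.inf, t2)
    bad = par & ((origin < lo) | (origin > hi))
    tmin = np.minimum(t1, t2)
    tmax = np.maximum(t1, t2)
    tn = np.max(tmin, axis=-1)
    tf = np.min(tmax, axis=-1)
    tf = np.where(np.any(bad, axis=-1), -np.inf, tf)
    return tn, tf


def ray_cast(volume: VolumeGrid, tf: TransferFunction, cam: Camera,
             step: float = None, background=(0.0, 0.0, 0.0)) -> np.ndarray:
    """Render an RGBA image by front-to-back ray casting.

    One ray per pixel of the projection plane, sampled at equidistant
    points (``step`` mm, default half the smallest voxel step) with
    trilinear value and gradient-magnitude interpolation; the transfer
    function supplies color and opacity and samples are composited front
    to back over ``background``.

    The transfer-function opacity is interpreted per millimeter of ray
    travel: each sample contributes 1 - (1 - alpha)**step, which makes
    the rendered image converge as the sampling step is refined instead
    of depending on the sample count.
    """
    if step is None:
        step = 0.5 * min(volume.spacing)
    if step <= 0:
        raise ValueError("step must be positive")
    v, u, r = cam.basis()
    x, y, z = volume.axes()
    lo = np.array([x[0], y[0], z[0]])
    hi = np.array([x[-1], y[-1], z[-1]])
    center = 0.5 * (lo + hi)
    ny, nx = cam.image_size
    diag = np.linalg.norm(hi - lo)
    iu = (np.arange(ny) - (ny - 1) / 2.0) * cam.pixel_pitch
    ir = (np.arange(nx) - (nx - 1) / 2.0) * cam.pixel_pitch
    IU, IR = np.meshgrid(iu, ir, indexing="ij")
    origins = (center - v * diag + IU[..., None] * u + IR[..., None] * r)
    origins = origins.reshape(-1, 3)
    tn, tf_exit = _bbox_entry_exit(origins, v, lo, hi)
    hit = tf_exit > tn

    # gradient magnitude, normalized by its 99th percentile
    dx, dy, dz = volume.spacing
    gz, gy, gx = np.gradient(volume.values, dz, dy, dx)
    gmag = np.sqrt(gx**2 + gy**2 + gz**2)
    p99 = np.percentile(gmag, 99)
    if p99 > 0:
        gmag = np.clip(gmag / p99, 0.0, 1.0)
    grad_vol = VolumeGrid(gmag, volume.spacing, volume.origin)

    n_rays = origins.shape[0]
    C = np.zeros((n_rays, 3))
    A = np.zeros(n_rays)
    if np.any(hit):
        t0 = tn[hit]
        t1 = tf_exit[hit]
        o = origins[hit]
        n_steps = int(np.ceil((t1 - t0).max() / step)) + 1
        active = np.arange(o.shape[0])
        Ch = np.zeros((o.shape[0], 3))
        Ah = np.zeros(o.shape[0])
        for i in range(n_steps):
            if active.size == 0:
                break
            t = t0[active] + i * step
            live = t <= t1[active]
            active = active[live]
            if active.size == 0:
                break
            pts = o[active] + np.outer(t[live], v)
            gray = trilinear_sample(volume, pts)
            gn = trilinear_sample(grad_vol, pts)
            alpha = 1.0 - (1.0 - tf.opacity(gray, gn)) ** step
            color = tf.color(gray)
            trans = 1.0 - Ah[active]
            Ch[active] += (trans * alpha)[:, None] * color
            Ah[active] += trans * alpha
            active = active[Ah[active] < EARLY_TERMINATION]
        C[hit] = Ch
        A[hit] = Ah
    bg = np.asarray(background, dtype=float)
    C = C + (1.0 - A)[:, None] * bg
    img = np.concatenate([C, A[:, None]], axis=1).reshape(ny, nx, 4)
    return np.clip(img, 0.0, 1.0)


@dataclass
class SectionImages:
    """Transverse/coronal/sagittal re-slices resampled to square pixels."""

    transverse: np.ndarray  # (y, x) at fixed z
    coronal: np.ndarray  # (z, x) at fixed y
    sagittal: np.ndarray  # (z, y) at fixed x
    pixel_size: float  # mm of the resampled isotropic pixel
    point: tuple


def _resample_iso(img, d_row, d_col, target):
    zoom = (d_row / target, d_col / target)
    if np.allclose(zoom, 1.0):
        return np.asarray(img, dtype=float)
    return ndimage.zoom(np.asarray(img, dtype=float), zoom, order=1)


def render_orthogonal_sections(volume: VolumeGrid, point) -> SectionImages:
    """Extract the three orthogonal sections through ``point`` (xyz mm).

    Each section is resampled to isotropic pixels of the smallest grid
    step so anisotropic layer pitch does not distort physical aspect
    ratios.
    """
    point = tuple(float(c) for c in point)
    x, y, z = volume.axes()
    if not (x[0] <= point[0] <= x[-1] and y[0] <= point[1] <= y[-1]
            and z[0] <= point[2] <= z[-1]):
        raise ValueError(f"point {point} outside the volume")
    dx, dy, dz = volume.spacing
    ix = int(round((point[0] - x[0]) / dx))
    iy = int(round((point[1] - y[0]) / dy))
    iz = int(round((point[2] - z[0]) / dz))
    target = min(volume.spacing)
    transverse = _resample_iso(volume.values[iz, :, :], dy, dx, target)
    coronal = _resample_iso(volume.values[:, iy, :], dz, dx, target)
    sagittal = _resample_iso(volume.values[:, :, ix], dz, dy, target)
    return SectionImages(transverse, coronal, sagittal, target, point)
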