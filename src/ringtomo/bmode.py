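"""Reflected-signal extraction and per-layer B-mode reconstruction.

The imaging stage is classical full-matrix synthetic-aperture
delay-and-sum (DAS): every (tx, rx) trace contributes to each pixel at
the two-way travel time (|tx - p| + |p - rx|)/c_ref, with linear time
interpolation; the image is the magnitude of the beamformed analytic
signal (frequency-domain quadrature), normalized to [0, 1].

Before beamforming, the direct transmitter-to-receiver arrival -- which
carries no target information and would otherwise dominate -- is removed
by time gating: samples earlier than |tx - rx|/c_ref plus a guard are
zeroed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import hilbert

from . import _fast
from .acoustics import EchoDataset, MM, ScanSeries

__all__ = ["GatePolicy", "Tomogram", "extract_reflection",
           "das_reconstruct", "reconstruct_series"]

# an image whose max is below this per-trace level is an empty scene and
# is left unnormalized
EMPTY_SCENE_FLOOR = 1e-12


@dataclass(frozen=True)
class GatePolicy:
    """How to remove the direct arrival before imaging.

    ``mode`` is ``"direct_arrival_mask"`` (zero each trace before its own
    direct-arrival time plus ``guard``), ``"fixed_time"`` (zero before
    ``guard`` on every trace) or ``"none"``.
    """

    mode: str = "direct_arrival_mask"
    guard: float = 0.0  # s

    def __post_init__(self):
        if self.mode not in ("direct_arrival_mask", "fixed_time", "none"):
            raise ValueError(f"unknown gate mode {self.mode!r}")
        if self.guard < 0:
            raise ValueError("guard must be >= 0")


@dataclass
class Tomogram:
    """Reconstructed 2D reflectivity image with pixel geometry.

    ``pixels[iy, ix]`` maps to physical (x, y) =
    (origin[0] + ix*spacing, origin[1] + iy*spacing) in mm.
    """

    pixels: np.ndarray
    spacing: float
    origin: tuple
    layer_z: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError("tomogram pixels must be 2D")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("tomogram pixels must be finite")
        self.spacing = float(self.spacing)
        self.origin = tuple(float(o) for o in self.origin)

    def coords(self):
        ny, nx = self.pixels.shape
        x = self.origin[0] + self.spacing * np.arange(nx)
        y = self.origin[1] + self.spacing * np.arange(ny)
        return x, y

    def pixel_center(self, iy: int, ix: int):
        return (self.origin[0] + self.spacing * ix,
                self.origin[1] + self.spacing * iy)


def extract_reflection(ds: EchoDataset, policy: GatePolicy) -> EchoDataset:
    """Zero the pre-echo portion of every trace according to ``policy``."""
    if policy.mode == "none":
        return ds
    data = np.array(ds.data, copy=True)
    t = ds.times
    if policy.mode == "fixed_time":
        cut = np.full((ds.array.n_elements,) * 2, policy.guard)
    else:
        pos = ds.array.element_positions
        d_pair = np.sqrt(((pos[:, None, :] - pos[None, :, :]) ** 2).sum(-1))
        cut = d_pair * MM / ds.reference_speed + policy.guard
    # number of zeroed samples per pair
    n_zero = np.searchsorted(t, cut.ravel()).reshape(cut.shape)
    if np.all(n_zero >= ds.n_samples):
        warnings.warn("gating removed every sample of every trace",
                      stacklevel=2)
    for tx in range(data.shape[0]):
        for rx in range(data.shape[1]):
            data[tx, rx, : n_zero[tx, rx]] = 0.0
    return EchoDataset(data, ds.sampling_rate, ds.t0, ds.reference_speed,
                       ds.array, ds.layer_z,
                       meta={**ds.meta, "gated": policy.mode,
                             "guard_s": policy.guard})


def _pair_mask(array, aperture):
    n = array.n_elements
    if aperture is None:
        return np.ones((n, n), dtype=np.bool_)
    # keep pairs whose rx element lies within +-aperture (radians) of the
    # direction opposite the tx element, i.e. a receive sub-aperture facing
    # the insonified region
    ang = 2.0 * np.pi * np.arange(n) / n
    diff = np.abs((ang[None, :] - ang[:, None] + np.pi) %
                  (2.0 * np.pi) - np.pi)
    return diff <= aperture


def das_reconstruct(ds: EchoDataset, grid_spacing: float, roi,
                    c_ref: float | None = None,
                    aperture: float | None = None,
                    coherence_weighting: bool = False) -> Tomogram:
    """Full-matrix delay-and-sum with envelope detection.

    ``roi`` is the image box ((xmin, xmax), (ymin, ymax)) in mm and must
    lie inside the ring; ``grid_spacing`` the pixel size in mm.  The
    beamforming speed defaults to the dataset's reference speed (water).
    ``aperture`` optionally restricts receive elements to those within
    that angle (radians) of the element opposite the transmitter.
    ``coherence_weighting`` multiplies each pixel by the coherence
    factor |Σs|² / (N·Σ|s|²) — a clutter suppressant, off by default.
    """
    if c_ref is None:
        c_ref = ds.reference_speed
    if c_ref <= 0:
        raise ValueError("c_ref must be positive")
    (xmin, xmax), (ymin, ymax) = [tuple(map(float, r)) for r in roi]
    cx, cy = ds.array.center
    r_ring = ds.array.radius
    corners = np.array([[xmin, ymin], [xmin, ymax], [xmax, ymin],
                        [xmax, ymax]])
    if np.any(np.hypot(corners[:, 0] - cx, corners[:, 1] - cy) >= r_ring):
        raise ValueError("roi must lie strictly inside the ring")
    h = float(grid_spacing)
    if h <= 0:
        raise ValueError("grid_spacing must be positive")
    x = np.arange(xmin, xmax + h / 2.0, h)
    y = np.arange(ymin, ymax + h / 2.0, h)
    X, Y = np.meshgrid(x, y, indexing="xy")
    px = np.column_stack([X.ravel(), Y.ravel()])

    pos = ds.array.element_positions
    d_px = np.sqrt(((pos[:, None, :] - px[None, :, :]) ** 2).sum(-1))
    t_px = d_px * MM / c_ref

    # analytic signal per tx row to bound peak memory on large arrays
    rf = np.asarray(ds.data, dtype=np.float32)
    rf_re = rf
    rf_im = np.empty_like(rf)
    for tx in range(rf.shape[0]):
        rf_im[tx] = hilbert(rf[tx], axis=-1).imag

    out_re = np.zeros(px.shape[0], dtype=np.float64)
    out_im = np.zeros(px.shape[0], dtype=np.float64)
    out_pow = np.zeros(px.shape[0], dtype=np.float64)
    use = _pair_mask(ds.array, aperture)
    _fast.das_sum(rf_re, rf_im, t_px, ds.sampling_rate, ds.t0, use,
                  out_re, out_im, out_pow)
    env = np.hypot(out_re, out_im)
    if coherence_weighting:
        with np.errstate(divide="ignore", invalid="ignore"):
            cf = env**2 / (use.sum() * out_pow)
        env = env * np.nan_to_num(cf, nan=0.0)
    env = env.reshape(X.shape)

    n_pairs = int(use.sum())
    peak = env.max()
    normalized = peak >= EMPTY_SCENE_FLOOR * n_pairs
    if normalized:
        env = env / peak
    return Tomogram(env, h, (x[0], y[0]), ds.layer_z, meta={
        "c_ref": c_ref, "normalized": bool(normalized),
        "raw_peak": float(peak), "n_pairs": n_pairs,
    })


def reconstruct_layers(layer_iter, grid_spacing: float, roi,
                       c_ref: float | None = None,
                       gate: GatePolicy | None = None,
                       aperture: float | None = None) -> list:
    """Gate + beamform an iterable of echo datasets one layer at a time.

    Accepts the lazy generator from ``acoustics.iter_scan_3d`` so each
    layer's echo tensor is released as soon as its tomogram exists --
    the memory-friendly path for large element counts.
    """
    out = []
    for ds in layer_iter:
        if gate is not None:
            ds = extract_reflection(ds, gate)
        out.append(das_reconstruct(ds, grid_spacing, roi, c_ref, aperture))
    if not out:
        raise ValueError("empty scan series")
    shapes = {t.pixels.shape for t in out}
    if len(shapes) != 1:
        raise ValueError("inconsistent layer geometry")
    return out


def reconstruct_series(series: ScanSeries, grid_spacing: float, roi,
                       c_ref: float | None = None,
                       gate: GatePolicy | None = None,
                       aperture: float | None = None) -> list:
    """One tomogram per scan layer on an identical pixel grid."""
    return reconstruct_layers(series, grid_spacing, roi, c_ref, gate,
                              aperture)
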