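"""Tomogram preprocessing: Gaussian smoothing and threshold segmentation.

Smoothing is linear scale-space filtering: convolution with the sampled
2D Gaussian G_sigma, which advances the image to diffusion time
t = 0.5*sigma^2.  Segmentation is global thresholding, f >= T ->
foreground, with T picked at the trough of the gray-level histogram
between its two dominant modes; when the histogram has no interior
trough the between-class-variance maximizer (Otsu) is used instead and
the result says so.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

__all__ = ["GaussianParams", "SegmentationResult", "ThresholdChoice",
           "gaussian_smooth", "select_threshold", "threshold_segment"]

N_BINS = 256
TROUGH_SMOOTH = 5  # moving-average window (bins) before trough search


@dataclass(frozen=True)
class GaussianParams:
    """Smoothing scale: sigma in pixels, diffusion time t = 0.5*sigma^2."""

    sigma: float

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")

    @property
    def t(self) -> float:
        return 0.5 * self.sigma**2


@dataclass(frozen=True)
class ThresholdChoice:
    """Selected threshold plus which rule produced it.

    ``rule`` is ``"trough"`` (deepest interior histogram minimum between
    the two dominant modes) or ``"otsu"`` (fallback for histograms
    without an interior trough).
    """

    threshold: float
    rule: str
    histogram: np.ndarray
    bin_centers: np.ndarray


@dataclass
class SegmentationResult:
    """Binary mask g (1 = object), threshold T and the gray histogram."""

    mask: np.ndarray
    threshold: float
    histogram: np.ndarray = field(default=None)

    def __post_init__(self):
        self.mask = np.asarray(self.mask)
        vals = np.unique(self.mask)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError("mask must be binary")


def gaussian_smooth(image: np.ndarray, sigma: float) -> np.ndarray:
    """Convolve with the normalized sampled Gaussian kernel.

    Truncation radius ceil(4*sigma), reflective borders; a constant image
    comes back unchanged (the kernel is normalized).
    """
    params = GaussianParams(float(sigma))  # validates sigma > 0
    image = np.asarray(image, dtype=float)
    return ndimage.gaussian_filter(image, params.sigma, mode="reflect",
                                   truncate=4.0)


def _moving_average(h: np.ndarray, w: int) -> np.ndarray:
    kernel = np.ones(w) / w
    pad = w // 2
    hp = np.pad(h, pad, mode="edge")
    return np.convolve(hp, kernel, mode="valid")[: h.size]


def select_threshold(image: np.ndarray) -> ThresholdChoice:
    """Histogram-trough threshold with an Otsu fallback.

    The two dominant gray modes are located as the class means on either
    side of the between-class-variance maximizer (Otsu); T is the center
    of the deepest interior local minimum of the 5-bin-smoothed 256-bin
    histogram between those two modes.  When no interior trough exists
    between the modes (effectively unimodal histograms) the Otsu value
    itself is returned, flagged ``"otsu"``.  Anchoring the trough search
    between the Otsu class means keeps it from latching onto incidental
    dips inside the background mode of multi-modal histograms.
    """
    image = np.asarray(image, dtype=float)
    lo, hi = float(image.min()), float(image.max())
    if hi <= lo:
        raise ValueError("cannot threshold a constant image")
    hist, edges = np.histogram(image, bins=N_BINS, range=(lo, hi))
    centers = 0.5 * (edges[:-1] + edges[1:])
    smooth = _moving_average(hist.astype(float), TROUGH_SMOOTH)

    t_otsu = float(threshold_otsu(image, nbins=N_BINS))
    below = image[image < t_otsu]
    above = image[image >= t_otsu]
    if below.size and above.size:
        mode_lo, mode_hi = float(below.mean()), float(above.mean())
        sel = (centers > mode_lo) & (centers < mode_hi)
        idx = np.nonzero(sel)[0]
        # interior local minima of the smoothed histogram
        idx = idx[(idx > 0) & (idx < N_BINS - 1)]
        if idx.size:
            is_min = (smooth[idx] <= smooth[idx - 1]) & \
                (smooth[idx] <= smooth[idx + 1])
            idx = idx[is_min]
        if idx.size:
            trough = idx[np.argmin(smooth[idx])]
            # a genuine trough must dip well below both mode bins;
            # sampling jitter inside a single mode does not qualify
            b_lo = int(np.clip(np.searchsorted(centers, mode_lo), 0,
                               N_BINS - 1))
            b_hi = int(np.clip(np.searchsorted(centers, mode_hi), 0,
                               N_BINS - 1))
            if smooth[trough] <= 0.9 * min(smooth[b_lo], smooth[b_hi]):
                return ThresholdChoice(float(centers[trough]), "trough",
                                       hist, centers)
    return ThresholdChoice(t_otsu, "otsu", hist, centers)


def threshold_segment(image: np.ndarray, T: float) -> SegmentationResult:
    """g = 1 where f >= T, else 0 (boundary pixels are foreground)."""
    if not np.isfinite(T):
        raise ValueError("threshold must be finite")
    image = np.asarray(image, dtype=float)
    mask = (image >= T).astype(np.uint8)
    lo, hi = float(image.min()), float(image.max())
    if hi > lo:
        hist, _ = np.histogram(image, bins=N_BINS, range=(lo, hi))
    else:
        hist = None
    return SegmentationResult(mask, float(T), hist)
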