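"""Reproduction studies: the simulation-side resolution experiments.

Each function runs one complete study from phantom construction through
acquisition, beamforming and analysis, and returns the headline number
plus a per-condition report:

* ``two_lesion_resolution`` -- sweep the separation of two 1 mm lesions
  and report the smallest separation the dip criterion resolves.
* ``smallest_detectable_lesion`` -- image the 0.3/0.5/1 mm multi-size
  phantom and report the smallest lesion reconstructed as a local
  envelope maximum at least 6 dB above its local background.
* ``model2_smallest_3d`` -- run the layered 3D pipeline over the small
  spheres of breast model 2 and report the smallest sphere that survives
  segmentation + interlayer interpolation as a connected component at
  its true position.
* ``model1_min_separated_gap`` -- sweep the surface gap between the 5
  and 10 mm spheres of breast model 1 and report the smallest gap whose
  lesions stay fully separated in the reconstructed sections through
  both centers.

Desk-scale settings (element counts, regions of interest, layer windows)
are fixed here so every study runs in minutes on one core; the physics
settings (3 MHz, 5-cycle pulse, 200 mm ring, 0.3 mm medium grid, 1.5 mm
layer pitch) are the acquisition protocol of the target system.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .acoustics import iter_scan_3d, make_pulse, make_ring, \
    simulate_echoes_born
from .bmode import GatePolicy, das_reconstruct, extract_reflection, \
    reconstruct_layers
from .interp import SliceStack, densify
from .metrics import TwoLesionSweepConfig, lesion_detection_db, \
    resolution_sweep
from .phantoms import make_breast_phantom_3d, make_section_phantom, \
    rasterize, to_scatterers
from .preprocess import gaussian_smooth, select_threshold, threshold_segment
from .render import render_orthogonal_sections

__all__ = ["two_lesion_resolution", "smallest_detectable_lesion",
           "model2_smallest_3d", "model1_min_separated_gap"]

FC = 3.0e6
FS = 24.0e6
C_REF = 1500.0
RING_DIAMETER = 200.0
RASTER = 0.3  # mm, the medium grid step
PIXEL = 0.15  # mm, reconstruction pixel
GUARD = 2.0e-6  # s, gate guard (covers the 5-cycle pulse)
PITCH = 1.5  # mm, layer pitch
SIGMA = 2.0  # px, tomogram smoothing
DETECT_DB = 6.0
DETECT_RADIUS = 0.5  # mm


def _window(ring, pulse, r_roi):
    """Record window covering two-way paths through radius ``r_roi``."""
    t0 = max(0.0, 2.0 * (ring.radius - r_roi) * 1e-3 / C_REF
             - pulse.duration)
    t_hi = 2.0 * (ring.radius + r_roi) * 1e-3 / C_REF + 2.0 * pulse.duration
    return t0, t_hi - t0


def two_lesion_resolution(n_elements: int = 128,
                          distances=(6.0, 5.0, 4.0, 3.0, 2.0, 1.0)):
    """Smallest resolved two-lesion separation (mm) with its report."""
    cfg = TwoLesionSweepConfig(n_elements=n_elements)
    return resolution_sweep(cfg, list(distances))


def smallest_detectable_lesion(n_elements: int = 128):
    """Smallest multi-size lesion diameter reconstructed at >= 6 dB."""
    spec = make_section_phantom("multi_size")
    roi = ((-14.0, 14.0), (-6.0, 6.0))
    amap = rasterize(spec, RASTER, roi, clip=True)
    cloud = to_scatterers(amap)
    ring = make_ring(n_elements, RING_DIAMETER, FC)
    pulse = make_pulse(FC, 5, FS)
    t0, rec = _window(ring, pulse, 16.0)
    ds = simulate_echoes_born(cloud, ring, pulse, C_REF, record_time=rec,
                              t0=t0, include_direct=True, eps_mm=RASTER)
    ds = extract_reflection(ds, GatePolicy("direct_arrival_mask", GUARD))
    tomo = das_reconstruct(ds, PIXEL, roi, C_REF)
    report = []
    detected = []
    for les in spec.lesions:
        db, pos = lesion_detection_db(tomo, les.center, DETECT_RADIUS)
        ok = db >= DETECT_DB
        report.append({"diameter_mm": les.diameter, "contrast_db": float(db),
                       "detected": bool(ok)})
        if ok:
            detected.append(les.diameter)
    smallest = min(detected) if detected else float("nan")
    return smallest, {"entries": report, "smallest_detected_mm": smallest}


def _segment_stack(tomos, roi, z0):
    masks = []
    for t in tomos:
        sm = gaussian_smooth(t.pixels, SIGMA)
        if sm.max() > sm.min():
            masks.append(threshold_segment(
                sm, select_threshold(sm).threshold).mask)
        else:
            masks.append(np.zeros(sm.shape, dtype=np.uint8))
    return SliceStack(np.asarray(masks, dtype=float), PITCH, PIXEL,
                      origin=(roi[0][0], roi[1][0], z0))


def model2_smallest_3d(n_elements: int = 128, interp_factor: int = 5):
    """Smallest model-2 sphere surviving the layered 3D pipeline (mm).

    The scan is restricted to the layers around the small spheres (the
    1 mm and the two 0.3 mm lesions); a sphere counts as reconstructed
    when the densified, segmented volume has foreground within 0.5 mm of
    its true center.
    """
    spec = make_breast_phantom_3d("model2")
    roi = ((-4.0, 10.0), (-12.0, 10.0))
    z0, n_layers = 16.5, 5
    ring = make_ring(n_elements, RING_DIAMETER, FC)
    pulse = make_pulse(FC, 5, FS)
    t0, rec = _window(ring, pulse, 17.0)
    layers = iter_scan_3d(spec, ring, n_layers, PITCH, z0, pulse=pulse,
                          c_ref=C_REF, raster_spacing=RASTER,
                          raster_extent=roi, record_time=rec, t0=t0,
                          include_direct=True)
    tomos = reconstruct_layers(layers, PIXEL, roi, C_REF,
                               gate=GatePolicy("direct_arrival_mask", GUARD))
    vol = densify(_segment_stack(tomos, roi, z0), interp_factor)
    lab, _ = ndimage.label(vol.values > 0.5)
    x, y, z = vol.axes()
    Z, Y, X = np.meshgrid(z, y, x, indexing="ij")
    fg = lab > 0
    report = []
    present = []
    for les in spec.lesions:
        cx, cy, cz = les.center
        in_roi = (roi[0][0] <= cx <= roi[0][1]
                  and roi[1][0] <= cy <= roi[1][1]
                  and z[0] <= cz <= z[-1])
        if not in_roi:
            report.append({"diameter_mm": les.diameter, "in_roi": False})
            continue
        d = np.sqrt((X - cx) ** 2 + (Y - cy) ** 2 + (Z - cz) ** 2)
        dmin = float(d[fg].min()) if fg.any() else float("inf")
        ok = dmin <= DETECT_RADIUS
        report.append({"diameter_mm": les.diameter, "in_roi": True,
                       "component_distance_mm": dmin, "present": bool(ok)})
        if ok:
            present.append(les.diameter)
    smallest = min(present) if present else float("nan")
    return smallest, {"entries": report, "smallest_present_mm": smallest}


def _nearest_label(lab, i, j):
    ys, xs = np.nonzero(lab)
    if len(ys) == 0:
        return 0
    d2 = (ys - i) ** 2 + (xs - j) ** 2
    k = int(np.argmin(d2))
    return int(lab[ys[k], xs[k]])


def model1_min_separated_gap(n_elements: int = 256,
                             gaps=(4.0, 3.0, 2.0, 1.0),
                             interp_factor: int = 5):
    """Smallest 5 mm / 10 mm sphere surface gap with full separation (mm).

    For each gap the layered scan around the sphere pair is reconstructed,
    segmented and densified; the lesions count as fully separated when
    the foreground components nearest the two sphere centers are distinct
    in *both* reconstructed sections through the centers (the transverse
    and coronal planes -- the two planes that contain both centers).
    """
    ring = make_ring(n_elements, RING_DIAMETER, FC)
    pulse = make_pulse(FC, 5, FS)
    roi = ((-17.0, 7.0), (-7.0, 7.0))
    z0, n_layers = 16.5, 7
    t0, rec = _window(ring, pulse, 19.0)
    entries = []
    separated_gaps = []
    for gap in gaps:
        spec = make_breast_phantom_3d("model1", gap=gap)
        c10 = spec.lesions[1].center
        c5 = spec.lesions[2].center
        layers = iter_scan_3d(spec, ring, n_layers, PITCH, z0, pulse=pulse,
                              c_ref=C_REF, raster_spacing=RASTER,
                              raster_extent=roi, record_time=rec, t0=t0,
                              include_direct=True)
        tomos = reconstruct_layers(layers, PIXEL, roi, C_REF,
                                   gate=GatePolicy("direct_arrival_mask",
                                                   GUARD))
        vol = densify(_segment_stack(tomos, roi, z0), interp_factor)
        sec = render_orthogonal_sections(vol, (c10[0], c10[1], c10[2]))
        pix = sec.pixel_size
        verdicts = {}
        for name in ("transverse", "coronal"):
            img = getattr(sec, name) > 0.5
            lab, _ = ndimage.label(img)
            if name == "transverse":  # (y, x) plane at the centers' z
                def idx(c):
                    return (int(round((c[1] - roi[1][0]) / pix)),
                            int(round((c[0] - roi[0][0]) / pix)))
            else:  # coronal: (z, x) plane at the centers' y
                def idx(c):
                    return (int(round((c[2] - z0) / pix)),
                            int(round((c[0] - roi[0][0]) / pix)))
            l1 = _nearest_label(lab, *idx(c10))
            l2 = _nearest_label(lab, *idx(c5))
            verdicts[name] = bool(l1 != 0 and l2 != 0 and l1 != l2)
        separated = all(verdicts.values())
        entries.append({"gap_mm": gap, **verdicts,
                        "separated": bool(separated)})
        if separated:
            separated_gaps.append(gap)
    min_gap = min(separated_gaps) if separated_gaps else float("nan")
    return min_gap, {"entries": entries, "min_separated_gap_mm": min_gap}
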