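"""File formats, DICOM series export, configuration and the pipeline runner.

Containers
----------
* Echo data and volumes travel as HDF5 (``rf`` / ``volume`` datasets with
  geometry attributes, ``schema = 1``).
* Tomograms are written as 16-bit TIFF/PNG with a JSON sidecar carrying
  pixel spacing, origin and layer height.
* Slice series export as a DICOM secondary-capture ultrasound series
  (grayscale 16-bit, explicit little endian) with the slice thickness /
  spacing-between-slices geometry tags; UIDs are derived
  deterministically from the series content so reruns are reproducible.

``run_pipeline`` chains the whole method -- simulate, beamform,
preprocess, densify, extract the isosurface, render -- and writes a
manifest (inputs, seeds, outputs with SHA-256 checksums, per-stage
timings) for provenance.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import tifffile
import yaml
from PIL import Image

import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid

from .acoustics import EchoDataset, RingArray, ScanSeries, add_noise, \
    make_pulse, make_ring, scan_3d
from .bmode import GatePolicy, Tomogram, reconstruct_series
from .interp import SliceStack, VolumeGrid, densify
from .phantoms import AcousticMap, make_breast_phantom_3d
from .preprocess import gaussian_smooth, select_threshold, threshold_segment
from .render import Camera, TransferFunction, ray_cast
from .surface import export_mesh, mesh_from_mask

__all__ = ["DicomSeriesSpec", "PipelineConfig", "logger",
           "save_echo", "load_echo", "save_scan", "load_scan",
           "save_volume", "load_volume", "save_volume_tiff_stack",
           "save_acoustic_map",
           "load_acoustic_map", "save_tomogram", "load_tomogram",
           "export_dicom_series", "run_pipeline"]

logger = logging.getLogger("ringtomo")

SCHEMA = 1
UID_ROOT = "1.2.826.0.1.3680043.10.1457."


# ---------------------------------------------------------------------------
# HDF5 containers
# ---------------------------------------------------------------------------

def _write_echo_group(g, ds: EchoDataset):
    g.create_dataset("rf", data=ds.data, compression="gzip",
                     compression_opts=1, track_times=False)
    g.attrs["schema"] = SCHEMA
    g.attrs["fs_hz"] = ds.sampling_rate
    g.attrs["t0_s"] = ds.t0
    g.attrs["c_ref_mps"] = ds.reference_speed
    g.attrs["layer_z_mm"] = ds.layer_z
    g.attrs["n_elements"] = ds.array.n_elements
    g.attrs["diameter_mm"] = ds.array.diameter
    g.attrs["fc_hz"] = ds.array.center_frequency
    g.attrs["center_mm"] = ds.array.center
    g.attrs["meta_json"] = json.dumps(ds.meta, default=str)


def _read_echo_group(g) -> EchoDataset:
    array = RingArray(int(g.attrs["n_elements"]), float(g.attrs["diameter_mm"]),
                      tuple(g.attrs["center_mm"]), float(g.attrs["fc_hz"]))
    meta = json.loads(g.attrs.get("meta_json", "{}"))
    return EchoDataset(g["rf"][()], float(g.attrs["fs_hz"]),
                       float(g.attrs["t0_s"]), float(g.attrs["c_ref_mps"]),
                       array, float(g.attrs["layer_z_mm"]), meta)


def save_echo(ds: EchoDataset, path):
    with h5py.File(path, "w") as f:
        _write_echo_group(f, ds)


def load_echo(path) -> EchoDataset:
    with h5py.File(path, "r") as f:
        return _read_echo_group(f)


def save_scan(series: ScanSeries, path):
    with h5py.File(path, "w") as f:
        f.attrs["schema"] = SCHEMA
        f.attrs["layer_pitch_mm"] = series.layer_pitch
        f.attrs["n_layers"] = len(series)
        for i, ds in enumerate(series):
            _write_echo_group(f.create_group(f"layer_{i:03d}"), ds)


def load_scan(path) -> ScanSeries:
    with h5py.File(path, "r") as f:
        n = int(f.attrs["n_layers"])
        layers = [_read_echo_group(f[f"layer_{i:03d}"]) for i in range(n)]
        return ScanSeries(layers, float(f.attrs["layer_pitch_mm"]))


def save_volume(vol: VolumeGrid, path):
    with h5py.File(path, "w") as f:
        f.create_dataset("volume", data=vol.values, compression="gzip",
                         compression_opts=1, track_times=False)
        f.attrs["schema"] = SCHEMA
        f.attrs["spacing_mm"] = vol.spacing
        f.attrs["origin_mm"] = vol.origin


def load_volume(path) -> VolumeGrid:
    with h5py.File(path, "r") as f:
        return VolumeGrid(f["volume"][()], tuple(f.attrs["spacing_mm"]),
                          tuple(f.attrs["origin_mm"]))


def save_acoustic_map(amap: AcousticMap, path):
    with h5py.File(path, "w") as f:
        f.create_dataset("sound_speed", data=amap.sound_speed,
                         track_times=False)
        f.create_dataset("density", data=amap.density,
                         track_times=False)
        f.attrs["schema"] = SCHEMA
        f.attrs["spacing_mm"] = amap.spacing
        f.attrs["origin_mm"] = amap.origin


def save_volume_tiff_stack(vol: VolumeGrid, directory) -> list:
    """Export a volume as a numbered 16-bit TIFF stack plus geometry JSON."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    lo, hi = float(vol.values.min()), float(vol.values.max())
    paths = []
    for i, sl in enumerate(vol.values):
        p = directory / f"layer_{i:04d}.tiff"
        tifffile.imwrite(p, _to_uint16(sl, lo, hi))
        paths.append(p)
    (directory / "stack.json").write_text(json.dumps({
        "spacing_mm": list(vol.spacing), "origin_mm": list(vol.origin),
        "value_range": [lo, hi], "n_layers": len(paths)}, indent=2))
    return paths


def load_acoustic_map(path) -> AcousticMap:
    with h5py.File(path, "r") as f:
        return AcousticMap(f["sound_speed"][()], f["density"][()],
                           tuple(f.attrs["spacing_mm"]),
                           tuple(f.attrs["origin_mm"]))


# ---------------------------------------------------------------------------
# Tomogram images
# ---------------------------------------------------------------------------

def _to_uint16(pixels: np.ndarray, lo: float, hi: float) -> np.ndarray:
    if hi <= lo:
        return np.zeros(pixels.shape, dtype=np.uint16)
    scaled = (pixels - lo) / (hi - lo)
    return np.round(np.clip(scaled, 0.0, 1.0) * 65535).astype(np.uint16)


def save_tomogram(tomo: Tomogram, path):
    """16-bit TIFF/PNG plus a JSON sidecar with the pixel geometry."""
    path = Path(path)
    lo, hi = float(tomo.pixels.min()), float(tomo.pixels.max())
    img = _to_uint16(tomo.pixels, lo, hi)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, img)
    elif path.suffix.lower() == ".png":
        Image.fromarray(img).save(path)
    else:
        raise ValueError(f"unsupported image suffix {path.suffix!r}")
    sidecar = {"spacing_mm": tomo.spacing, "origin_mm": list(tomo.origin),
               "layer_z_mm": tomo.layer_z, "value_range": [lo, hi]}
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar, indent=2))


def load_tomogram(path) -> Tomogram:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        img = tifffile.imread(path).astype(float)
    else:
        img = np.asarray(Image.open(path), dtype=float)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    lo, hi = meta["value_range"]
    pixels = img / 65535.0 * (hi - lo) + lo
    return Tomogram(pixels, meta["spacing_mm"], tuple(meta["origin_mm"]),
                    meta["layer_z_mm"])


# ---------------------------------------------------------------------------
# DICOM secondary-capture series
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DicomSeriesSpec:
    """Geometry and identity of an exported DICOM slice series.

    ``slice_thickness`` and ``spacing_between_slices`` (mm) fill the
    standard geometry tags; ``pixel_spacing`` is the in-plane step (mm).
    ``entropy`` seeds the deterministic UID derivation.
    """

    slice_thickness: float = 1.0
    spacing_between_slices: float = 0.5
    pixel_spacing: float = 0.3
    entropy: str = "ringtomo-series"

    def __post_init__(self):
        if min(self.slice_thickness, self.spacing_between_slices,
               self.pixel_spacing) <= 0:
            raise ValueError("DICOM geometry must be positive")


def _slice_arrays(slices):
    if isinstance(slices, SliceStack):
        return [np.asarray(s, dtype=float) for s in slices.slices]
    out = []
    for s in slices:
        out.append(np.asarray(s.pixels if isinstance(s, Tomogram) else s,
                              dtype=float))
    return out


def export_dicom_series(slices, spec: DicomSeriesSpec, directory) -> list:
    """Write one secondary-capture US file per slice; returns the paths.

    Pixels are rescaled to the full 16-bit range over the series (the
    linear map is recorded in RescaleSlope/Intercept); a reader therefore
    recovers the stored 16-bit data bit-exactly.
    """
    arrays = _slice_arrays(slices)
    if len(arrays) == 0:
        raise ValueError("empty slice stack")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    lo = min(float(a.min()) for a in arrays)
    hi = max(float(a.max()) for a in arrays)
    series_uid = generate_uid(UID_ROOT, entropy_srcs=[spec.entropy, "series"])
    study_uid = generate_uid(UID_ROOT, entropy_srcs=[spec.entropy, "study"])
    paths = []
    for i, arr in enumerate(arrays):
        pix = _to_uint16(arr, lo, hi)
        file_meta = FileMetaDataset()
        file_meta.MediaStorageSOPClassUID = \
            pydicom.uid.SecondaryCaptureImageStorage
        file_meta.MediaStorageSOPInstanceUID = generate_uid(
            UID_ROOT, entropy_srcs=[spec.entropy, f"instance{i}"])
        file_meta.TransferSyntaxUID = ExplicitVRLittleEndian

        ds = Dataset()
        ds.file_meta = file_meta
        ds.SOPClassUID = file_meta.MediaStorageSOPClassUID
        ds.SOPInstanceUID = file_meta.MediaStorageSOPInstanceUID
        ds.Modality = "US"
        ds.ConversionType = "SYN"
        ds.SeriesInstanceUID = series_uid
        ds.StudyInstanceUID = study_uid
        ds.PatientName = "PHANTOM^BREAST"
        ds.PatientID = "RINGTOMO"
        ds.StudyDate = "20240130"
        ds.ContentDate = "20240130"
        ds.ContentTime = "000000"
        ds.SeriesNumber = 1
        ds.InstanceNumber = i + 1
        ds.SliceThickness = spec.slice_thickness
        ds.SpacingBetweenSlices = spec.spacing_between_slices
        ds.PixelSpacing = [spec.pixel_spacing, spec.pixel_spacing]
        ds.ImagePositionPatient = [0.0, 0.0,
                                   i * spec.spacing_between_slices]
        ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.Rows, ds.Columns = pix.shape
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 0
        ds.RescaleSlope = (hi - lo) / 65535.0 if hi > lo else 1.0
        ds.RescaleIntercept = lo
        ds.PixelData = pix.tobytes()
        path = directory / f"slice_{i + 1:04d}.dcm"
        ds.save_as(path, enforce_file_format=True)
        paths.append(path)
    return paths


# ---------------------------------------------------------------------------
# Pipeline configuration and runner
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """End-to-end pipeline settings (units: mm, Hz, s).

    ``phantom`` selects a built-in 3D model (``model1``/``model2``);
    ``gap`` overrides the model-1 sphere surface gap.  The region of
    interest is the square of half-width ``roi_half`` centered on
    ``roi_center``.  ``noise_std`` > 0 adds seeded Gaussian noise to the
    echo tensors.
    """

    phantom: str = "model2"
    gap: float | None = None
    n_elements: int = 64
    ring_diameter: float = 200.0
    fc: float = 3.0e6
    n_cycles: int = 5
    fs: float = 24.0e6
    c_ref: float = 1500.0
    n_layers: int = 32
    pitch: float = 1.5
    z0: float = 0.0
    raster_spacing: float = 0.3
    roi_center: tuple = (0.0, 0.0)
    roi_half: float = 20.0
    recon_spacing: float = 0.3
    guard: float = 2.0e-6
    sigma: float = 2.0
    interp_factor: int = 4
    kernel_a: float = -0.5
    iso: float = 0.5
    transfer_function: str | None = None
    seed: int = 0
    noise_std: float = 0.0
    outdir: str = "pipeline_out"

    @classmethod
    def from_yaml(cls, source) -> "PipelineConfig":
        try:
            with open(source) as fh:
                d = yaml.safe_load(fh)
        except (OSError, TypeError, ValueError):
            d = yaml.safe_load(source)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "roi_center" in d:
            d["roi_center"] = tuple(d["roi_center"])
        return cls(**d)

    def to_yaml(self, path=None) -> str:
        d = dataclasses.asdict(self)
        d["roi_center"] = list(d["roi_center"])
        text = yaml.safe_dump(d, sort_keys=False)
        if path is not None:
            Path(path).write_text(text)
        return text

    def roi(self):
        cx, cy = self.roi_center
        h = self.roi_half
        return ((cx - h, cx + h), (cy - h, cy + h))


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


class StageError(RuntimeError):
    """A pipeline stage failed; the message is tagged with the stage."""

    def __init__(self, stage, exc):
        super().__init__(f"[{stage}] {exc}")
        self.stage = stage


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute simulate -> reconstruct -> preprocess -> densify -> mesh ->
    render, writing every artifact plus a provenance manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {"config": json.loads(json.dumps(dataclasses.asdict(config))),
                "seed": config.seed, "schema": SCHEMA,
                "stages": {}, "outputs": {}}
    timings = {}

    def stage(name):
        logger.info("stage %s starting", name)

        class _Ctx:
            def __enter__(self):
                self.start = time.perf_counter()
                return self

            def __exit__(self, exc_type, exc, tb):
                timings[name] = time.perf_counter() - self.start
                if exc is not None:
                    raise StageError(name, exc) from exc
                logger.info("stage %s done in %.2fs", name, timings[name])
        return _Ctx()

    with stage("simulate"):
        kwargs = {}
        if config.gap is not None:
            kwargs["gap"] = config.gap
        spec = make_breast_phantom_3d(config.phantom, **kwargs)
        ring = make_ring(config.n_elements, config.ring_diameter, config.fc)
        pulse = make_pulse(config.fc, config.n_cycles, config.fs)
        r_roi = (config.roi_half * np.sqrt(2.0)
                 + float(np.hypot(*config.roi_center)) + 2.0)
        t0 = max(0.0, 2.0 * (ring.radius - r_roi) * 1e-3 / config.c_ref
                 - pulse.duration)
        rec = (2.0 * (ring.radius + r_roi) * 1e-3 / config.c_ref
               + 2.0 * pulse.duration - t0)
        series = scan_3d(spec, ring, config.n_layers, config.pitch,
                         config.z0, pulse=pulse, c_ref=config.c_ref,
                         raster_spacing=config.raster_spacing,
                         raster_extent=config.roi(), record_time=rec,
                         t0=t0, include_direct=True)
        if config.noise_std > 0:
            series = ScanSeries(
                [add_noise(ds, config.noise_std, config.seed + i)
                 for i, ds in enumerate(series)], series.layer_pitch)
        scan_path = outdir / "scan.h5"
        save_scan(series, scan_path)
        manifest["outputs"]["scan"] = {"path": scan_path.name,
                                       "sha256": _sha256(scan_path),
                                       "n_layers": len(series)}

    with stage("reconstruct"):
        gate = GatePolicy("direct_arrival_mask", config.guard)
        tomos = reconstruct_series(series, config.recon_spacing,
                                   config.roi(), config.c_ref, gate)
        slices_dir = outdir / "slices"
        slices_dir.mkdir(exist_ok=True)
        tomo_entries = []
        for i, t in enumerate(tomos):
            p = slices_dir / f"slice_{i:03d}.tiff"
            save_tomogram(t, p)
            tomo_entries.append({"path": f"slices/{p.name}",
                                 "sha256": _sha256(p),
                                 "layer_z_mm": t.layer_z})
        manifest["outputs"]["tomograms"] = tomo_entries

    with stage("preprocess"):
        masks = []
        thresholds = []
        for t in tomos:
            sm = gaussian_smooth(t.pixels, config.sigma)
            if sm.max() > sm.min():
                choice = select_threshold(sm)
                seg = threshold_segment(sm, choice.threshold)
                thresholds.append({"T": choice.threshold,
                                   "rule": choice.rule})
            else:
                seg = None
                thresholds.append({"T": None, "rule": "empty"})
            masks.append(seg.mask if seg is not None
                         else np.zeros(sm.shape, dtype=np.uint8))
        manifest["outputs"]["thresholds"] = thresholds

    with stage("densify"):
        roi = config.roi()
        stack = SliceStack(np.asarray(masks, dtype=float), config.pitch,
                           config.recon_spacing,
                           origin=(roi[0][0], roi[1][0],
                                   series.layers[0].layer_z))
        vol = densify(stack, config.interp_factor, config.kernel_a)
        vol_path = outdir / "volume.h5"
        save_volume(vol, vol_path)
        manifest["outputs"]["volume"] = {"path": vol_path.name,
                                         "sha256": _sha256(vol_path),
                                         "shape": list(vol.shape)}

    with stage("mesh"):
        mesh = mesh_from_mask(vol, sigma=1.0, c=config.iso)
        mesh_path = outdir / "surface.ply"
        export_mesh(mesh, mesh_path)
        manifest["outputs"]["mesh"] = {"path": mesh_path.name,
                                       "sha256": _sha256(mesh_path),
                                       "n_vertices": mesh.n_vertices,
                                       "n_faces": mesh.n_faces}

    with stage("render"):
        if config.transfer_function:
            tf = TransferFunction.from_yaml(config.transfer_function)
        else:
            tf = TransferFunction.grayscale(opacity_scale=0.8)
        cam = Camera.from_angles(30.0, 45.0, image_size=(96, 96),
                                 pixel_pitch=max(
                                     vol.spacing[0] * vol.shape[2],
                                     vol.spacing[2] * vol.shape[0]) / 90.0)
        img = ray_cast(vol, tf, cam)
        render_path = outdir / "render.png"
        Image.fromarray(
            np.round(img * 255).astype(np.uint8), mode="RGBA"
        ).save(render_path)
        manifest["outputs"]["renders"] = [{"path": render_path.name,
                                           "sha256": _sha256(render_path)}]

    manifest["stages"] = {k: round(v, 3) for k, v in timings.items()}
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest
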