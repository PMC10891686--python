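"""Digital breast phantoms: geometric specs, acoustic-map rasterization,
and scatterer-cloud extraction.

A phantom is described geometrically (a background solid containing
spherical/circular lesions immersed in water) and rasterized on demand to
gridded sound-speed and density fields.  For the single-scattering echo
synthesizer the acoustic map is further reduced to a cloud of interface
scatterers whose reflectivity follows the local impedance contrast.

Built-in models
---------------
``table1_section``
    2D breast-tissue section: a 180 mm adipose disk (1515 m/s,
    1040 kg/m^3) holding five circular targets of 5-15 mm with the two
    tissue types (1479 m/s / 950 kg/m^3 and 1518 m/s / 1060 kg/m^3).
``multi_size``
    Three small lesions of 0.3, 0.5 and 1.0 mm diameter used for the
    minimum-detectable-size study.
``two_lesion``
    Two 1 mm lesions separated by a configurable gap, used for the
    two-point resolution sweep.
``model1`` / ``model2``
    3D breast phantoms (160 mm upper-surface diameter) with spherical
    lesions of 15/10/5 mm and 5/1/0.3/0.3 mm respectively; water, tissue
    and lesion speeds 1500/1510/1560 m/s, densities 1000/1040/1060 kg/m^3.

Lesion center coordinates are package choices (the source models are
specified only pictorially); they are fixed here so every downstream test
is deterministic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import yaml

__all__ = [
    "LesionSpec",
    "BackgroundSpec",
    "PhantomSpec",
    "AcousticMap",
    "ScattererCloud",
    "WATER_SPEED",
    "WATER_DENSITY",
    "make_section_phantom",
    "make_breast_phantom_3d",
    "slice_phantom",
    "rasterize",
    "to_scatterers",
]

# ambient water properties shared by every built-in model
WATER_SPEED = 1500.0  # m/s
WATER_DENSITY = 1000.0  # kg/m^3

# breast-tissue section model (2D): background + five circular targets
_TABLE1_BACKGROUND = (180.0, 1515.0, 1040.0)  # diameter, speed, density
_TABLE1_TARGETS = [
    # (center_x, center_y, diameter, speed, density) -- centers are package
    # defaults; all inter-target gaps >= 5 mm
    (-45.0, 25.0, 10.0, 1479.0, 950.0),
    (35.0, 35.0, 10.0, 1518.0, 1060.0),
    (0.0, 0.0, 5.0, 1518.0, 1060.0),
    (-30.0, -40.0, 15.0, 1479.0, 950.0),
    (40.0, -30.0, 10.0, 1518.0, 1060.0),
]

# small-lesion tissue properties used by the resolution models
_LESION_SPEED = 1518.0
_LESION_DENSITY = 1060.0

# 3D models: speeds/densities of water, mammary tissue and lesions
_TISSUE_SPEED, _TISSUE_DENSITY = 1510.0, 1040.0
_SPHERE_SPEED, _SPHERE_DENSITY = 1560.0, 1060.0
BREAST_UPPER_DIAMETER = 160.0  # mm
BREAST_HEIGHT = 48.0  # mm; spans the 32-layer x 1.5 mm scan range


@dataclass(frozen=True)
class LesionSpec:
    """A circular (2D) or spherical (3D) lesion.

    ``center`` is in mm (2 or 3 components), ``diameter`` in mm,
    ``sound_speed`` in m/s and ``density`` in kg/m^3.
    """

    center: tuple
    diameter: float
    sound_speed: float
    density: float

    def __post_init__(self):
        if self.diameter <= 0:
            raise ValueError(f"diameter must be > 0, got {self.diameter}")
        if self.sound_speed <= 0 or self.density <= 0:
            raise ValueError("sound_speed and density must be > 0")
        object.__setattr__(self, "center", tuple(float(c) for c in self.center))

    @property
    def radius(self) -> float:
        return self.diameter / 2.0


@dataclass(frozen=True)
class BackgroundSpec:
    """The background solid: a disk (2D), sphere, or breast hemispheroid.

    The hemispheroid models the pendant breast: a half ellipsoid with the
    flat (chest-wall) face at z = 0, equatorial diameter ``diameter`` and
    apex at z = ``height``.
    """

    shape: str  # "disk" | "sphere" | "hemispheroid"
    center: tuple
    diameter: float
    sound_speed: float
    density: float
    height: float | None = None  # hemispheroid only

    def __post_init__(self):
        if self.shape not in ("disk", "sphere", "hemispheroid"):
            raise ValueError(f"unknown background shape {self.shape!r}")
        if self.shape == "hemispheroid" and (self.height is None or self.height <= 0):
            raise ValueError("hemispheroid background needs a positive height")
        if self.diameter <= 0 or self.sound_speed <= 0 or self.density <= 0:
            raise ValueError("diameter, sound_speed and density must be > 0")
        object.__setattr__(self, "center", tuple(float(c) for c in self.center))

    def contains(self, pts: np.ndarray) -> np.ndarray:
        """Vectorized membership test for an (n, ndim) array of points (mm)."""
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        c = np.asarray(self.center)
        if self.shape in ("disk", "sphere"):
            return np.sum((pts - c) ** 2, axis=-1) <= (self.diameter / 2.0) ** 2
        # hemispheroid: (r_xy/a)^2 + (z/h)^2 <= 1 with z in [0, h]
        a = self.diameter / 2.0
        dx = pts[:, 0] - c[0]
        dy = pts[:, 1] - c[1]
        z = pts[:, 2] - c[2]
        inside = (dx**2 + dy**2) / a**2 + (z / self.height) ** 2 <= 1.0
        return inside & (z >= 0.0)


@dataclass(frozen=True)
class PhantomSpec:
    """Background solid + ordered lesion list + ambient water properties."""

    background: BackgroundSpec
    lesions: tuple
    ambient_speed: float = WATER_SPEED
    ambient_density: float = WATER_DENSITY
    name: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(self, "lesions", tuple(self.lesions))

    @property
    def ndim(self) -> int:
        return len(self.background.center)

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["background"]["center"] = list(d["background"]["center"])
        d["lesions"] = [
            {**l, "center": list(l["center"])} for l in d["lesions"]
        ]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomSpec":
        bg = BackgroundSpec(**d["background"])
        lesions = tuple(LesionSpec(**l) for l in d["lesions"])
        return cls(
            background=bg,
            lesions=lesions,
            ambient_speed=d.get("ambient_speed", WATER_SPEED),
            ambient_density=d.get("ambient_density", WATER_DENSITY),
            name=d.get("name", ""),
            meta=d.get("meta", {}),
        )

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=False)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "PhantomSpec":
        if hasattr(source, "read"):
            d = yaml.safe_load(source.read())
        else:
            try:
                with open(source) as fh:
                    d = yaml.safe_load(fh)
            except (OSError, ValueError):
                d = yaml.safe_load(source)
        return cls.from_dict(d)

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_json(cls, text: str) -> "PhantomSpec":
        return cls.from_dict(json.loads(text))


@dataclass
class AcousticMap:
    """Gridded sound-speed (m/s) and density (kg/m^3) fields.

    ``spacing`` is the per-axis grid step in mm and ``origin`` the physical
    coordinate of grid index (0, ..., 0).  2D grids are indexed [iy, ix]
    with origin (x0, y0); 3D grids [iz, iy, ix] with origin (x0, y0, z0).
    """

    sound_speed: np.ndarray
    density: np.ndarray
    spacing: tuple
    origin: tuple

    def __post_init__(self):
        self.sound_speed = np.asarray(self.sound_speed, dtype=float)
        self.density = np.asarray(self.density, dtype=float)
        if self.sound_speed.shape != self.density.shape:
            raise ValueError("sound_speed and density grids must share shape")
        if np.any(self.sound_speed <= 0) or np.any(self.density <= 0):
            raise ValueError("acoustic properties must be positive")
        self.spacing = tuple(float(s) for s in np.broadcast_to(
            np.asarray(self.spacing, dtype=float), (self.sound_speed.ndim,)))
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def impedance(self) -> np.ndarray:
        """Acoustic impedance Z = rho * c (SI units with mm-free scaling)."""
        return self.sound_speed * self.density

    def coords(self) -> tuple:
        """Physical coordinates along each axis, ordered (x, y[, z])."""
        shape = self.sound_speed.shape  # (ny, nx) or (nz, ny, nx)
        axes = []
        for ax in range(len(shape)):
            n = shape[len(shape) - 1 - ax]  # x fastest
            axes.append(self.origin[ax] + self.spacing[ax] * np.arange(n))
        return tuple(axes)


@dataclass
class ScattererCloud:
    """Point scatterers with dimensionless reflectivities.

    Positions are physical (mm).  This is the single-scattering medium
    description consumed by the Born echo synthesizer.
    """

    positions: np.ndarray  # (n, ndim) mm
    reflectivities: np.ndarray  # (n,)

    def __post_init__(self):
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        self.reflectivities = np.atleast_1d(
            np.asarray(self.reflectivities, dtype=float))
        if self.positions.shape[0] != self.reflectivities.shape[0]:
            raise ValueError("positions and reflectivities length mismatch")
        if not np.all(np.isfinite(self.reflectivities)):
            raise ValueError("reflectivities must be finite")

    def __len__(self) -> int:
        return self.positions.shape[0]

    def __add__(self, other: "ScattererCloud") -> "ScattererCloud":
        if len(self) == 0:
            return other
        if len(other) == 0:
            return self
        return ScattererCloud(
            np.vstack([self.positions, other.positions]),
            np.concatenate([self.reflectivities, other.reflectivities]),
        )


# ---------------------------------------------------------------------------
# Built-in model constructors
# ---------------------------------------------------------------------------

def make_section_phantom(model_id: str, **params) -> PhantomSpec:
    """Build one of the 2D section models.

    Parameters
    ----------
    model_id:
        ``"table1_section"``, ``"multi_size"`` or ``"two_lesion"``.
    params:
        ``two_lesion`` accepts ``d`` (separation, mm), ``orientation``
        (``"horizontal"`` or ``"vertical"``) and ``center_mode``
        (``"edge"`` for edge-to-edge gap -- the default -- or
        ``"center"`` for center-to-center distance), plus ``diameter``.
    """
    if model_id == "table1_section":
        bgd, bgc, bgr = _TABLE1_BACKGROUND
        bg = BackgroundSpec("disk", (0.0, 0.0), bgd, bgc, bgr)
        lesions = tuple(
            LesionSpec((x, y), d, c, rho) for x, y, d, c, rho in _TABLE1_TARGETS
        )
        return PhantomSpec(bg, lesions, name="table1_section")

    if model_id == "multi_size":
        # acoustically transparent background disk: the small targets sit
        # directly in water so their echoes are not masked by a strong
        # container-wall reflection
        bg = BackgroundSpec("disk", (0.0, 0.0), 60.0, WATER_SPEED, WATER_DENSITY)
        diameters = params.get("diameters", (0.3, 0.5, 1.0))
        xs = (-8.0, 0.0, 8.0)
        lesions = tuple(
            LesionSpec((x, 0.0), d, _LESION_SPEED, _LESION_DENSITY)
            for x, d in zip(xs, diameters)
        )
        return PhantomSpec(bg, lesions, name="multi_size")

    if model_id == "two_lesion":
        d = float(params.get("d", 2.0))
        if d <= 0:
            raise ValueError(f"two_lesion separation d must be > 0, got {d}")
        diameter = float(params.get("diameter", 1.0))
        orientation = params.get("orientation", "horizontal")
        center_mode = params.get("center_mode", "edge")
        if center_mode == "edge":
            cc = d + diameter  # center-to-center from edge gap
        elif center_mode == "center":
            cc = d
            if cc <= 0:
                raise ValueError("center-to-center distance must be > 0")
        else:
            raise ValueError(f"unknown center_mode {center_mode!r}")
        if orientation == "horizontal":
            c1, c2 = (-cc / 2.0, 0.0), (cc / 2.0, 0.0)
        elif orientation == "vertical":
            c1, c2 = (0.0, -cc / 2.0), (0.0, cc / 2.0)
        else:
            raise ValueError(f"unknown orientation {orientation!r}")
        bg = BackgroundSpec("disk", (0.0, 0.0), 60.0, WATER_SPEED, WATER_DENSITY)
        lesions = (
            LesionSpec(c1, diameter, _LESION_SPEED, _LESION_DENSITY),
            LesionSpec(c2, diameter, _LESION_SPEED, _LESION_DENSITY),
        )
        return PhantomSpec(
            bg,
            lesions,
            name="two_lesion",
            meta={"d": d, "orientation": orientation, "center_mode": center_mode,
                  "center_distance": cc},
        )

    raise ValueError(f"unknown section model {model_id!r}")


def make_breast_phantom_3d(model_id: str, **params) -> PhantomSpec:
    """Build one of the 3D breast phantoms (``model1`` or ``model2``).

    ``model1`` holds spheres of 15, 10 and 5 mm with a 2 mm surface gap
    between the 5 mm and 10 mm spheres (``gap`` overrides it, e.g. for a
    separation sweep).  ``model2`` holds spheres of 5, 1, 0.3 and 0.3 mm.
    Sphere centers lie on scan-layer planes (multiples of the 1.5 mm layer
    pitch) so a layered acquisition intersects every lesion.
    """
    bg = BackgroundSpec(
        "hemispheroid", (0.0, 0.0, 0.0), BREAST_UPPER_DIAMETER,
        _TISSUE_SPEED, _TISSUE_DENSITY, height=BREAST_HEIGHT,
    )
    if model_id == "model1":
        gap = float(params.get("gap", 2.0))
        if gap <= 0:
            raise ValueError(f"surface gap must be > 0, got {gap}")
        z = 21.0  # layer 14 of a 1.5 mm scan
        c10 = (-10.0, 0.0, z)
        # center distance = gap + r10 + r5
        c5 = (-10.0 + gap + 5.0 + 2.5, 0.0, z)
        c15 = (20.0, 25.0, z)
        lesions = (
            LesionSpec(c15, 15.0, _SPHERE_SPEED, _SPHERE_DENSITY),
            LesionSpec(c10, 10.0, _SPHERE_SPEED, _SPHERE_DENSITY),
            LesionSpec(c5, 5.0, _SPHERE_SPEED, _SPHERE_DENSITY),
        )
        return PhantomSpec(bg, lesions, name="model1",
                           meta={"gap": gap, "pair": ["10mm", "5mm"]})

    if model_id == "model2":
        z = 19.5  # layer 13
        lesions = (
            LesionSpec((-12.0, 0.0, z), 5.0, _SPHERE_SPEED, _SPHERE_DENSITY),
            LesionSpec((0.0, -8.0, z), 1.0, _SPHERE_SPEED, _SPHERE_DENSITY),
            LesionSpec((5.0, 0.0, z), 0.3, _SPHERE_SPEED, _SPHERE_DENSITY),
            LesionSpec((5.0, 6.0, z), 0.3, _SPHERE_SPEED, _SPHERE_DENSITY),
        )
        return PhantomSpec(bg, lesions, name="model2")

    raise ValueError(f"unknown 3D model {model_id!r}")


def slice_phantom(spec: PhantomSpec, z: float) -> PhantomSpec:
    """Intersect a 3D phantom with the plane at height ``z`` (mm).

    Spheres become circles of chord radius sqrt(r^2 - dz^2); lesions the
    plane misses are dropped.  The hemispheroid background becomes the
    disk of its cross-section (empty cross-section -> water-only disk of
    zero practical extent is rejected).
    """
    if spec.ndim != 3:
        raise ValueError("slice_phantom expects a 3D phantom")
    bg = spec.background
    if bg.shape == "hemispheroid":
        zrel = z - bg.center[2]
        if not (0.0 <= zrel <= bg.height):
            raise ValueError(f"plane z={z} mm misses the breast solid")
        a = bg.diameter / 2.0
        r = a * np.sqrt(max(0.0, 1.0 - (zrel / bg.height) ** 2))
    elif bg.shape == "sphere":
        dz = z - bg.center[2]
        r2 = (bg.diameter / 2.0) ** 2 - dz**2
        if r2 <= 0:
            raise ValueError(f"plane z={z} mm misses the background sphere")
        r = float(np.sqrt(r2))
    else:
        raise ValueError(f"cannot slice background shape {bg.shape!r}")
    if r <= 0:
        raise ValueError(f"plane z={z} mm gives an empty cross-section")
    bg2 = BackgroundSpec("disk", bg.center[:2], 2.0 * r,
                         bg.sound_speed, bg.density)
    lesions = []
    for les in spec.lesions:
        dz = z - les.center[2]
        r2 = les.radius**2 - dz**2
        if r2 > 0:
            lesions.append(LesionSpec(les.center[:2], 2.0 * float(np.sqrt(r2)),
                                      les.sound_speed, les.density))
    return PhantomSpec(bg2, tuple(lesions), spec.ambient_speed,
                       spec.ambient_density, name=f"{spec.name}@z={z:g}",
                       meta={**spec.meta, "layer_z": float(z)})


# ---------------------------------------------------------------------------
# Rasterization and scatterer extraction
# ---------------------------------------------------------------------------

def _axis(extent, spacing):
    lo, hi = float(extent[0]), float(extent[1])
    n = int(np.floor((hi - lo) / spacing + 0.5)) + 1
    return lo + spacing * np.arange(n)


def rasterize(spec: PhantomSpec, spacing: float, extent, *,
              clip: bool = False) -> AcousticMap:
    """Rasterize a phantom spec to an acoustic map.

    ``extent`` gives per-axis (lo, hi) bounds in mm, e.g.
    ``((-30, 30), (-30, 30))``.  Voxel membership is decided by
    voxel-center inclusion; lesions override background override ambient.
    By default the extent must cover the full background solid; pass
    ``clip=True`` to rasterize a sub-window (the clipped boundary emits no
    interface, which is exactly what a region-of-interest simulation
    wants).
    """
    spacing = float(spacing)
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    extent = [tuple(map(float, e)) for e in np.atleast_2d(extent)]
    if len(extent) == 1:
        extent = extent * spec.ndim
    if len(extent) != spec.ndim:
        raise ValueError("extent dimensionality does not match the phantom")
    bg = spec.background
    if not clip:
        c = bg.center
        r = bg.diameter / 2.0
        for ax in range(spec.ndim):
            lo_need = c[ax] - r
            hi_need = c[ax] + r
            if bg.shape == "hemispheroid" and ax == 2:
                lo_need, hi_need = c[2], c[2] + bg.height
            if extent[ax][0] > lo_need + 1e-9 or extent[ax][1] < hi_need - 1e-9:
                raise ValueError(
                    "extent does not cover the background region "
                    "(pass clip=True for a windowed raster)")

    axes = [_axis(e, spacing) for e in extent]  # x, y[, z]
    if spec.ndim == 2:
        X, Y = np.meshgrid(axes[0], axes[1], indexing="xy")
        pts = np.column_stack([X.ravel(), Y.ravel()])
        shape = X.shape  # (ny, nx)
    else:
        Z, Y, X = np.meshgrid(axes[2], axes[1], axes[0], indexing="ij")
        pts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
        shape = Z.shape  # (nz, ny, nx)

    speed = np.full(pts.shape[0], spec.ambient_speed)
    dens = np.full(pts.shape[0], spec.ambient_density)
    inside_bg = bg.contains(pts)
    speed[inside_bg] = bg.sound_speed
    dens[inside_bg] = bg.density
    for les in spec.lesions:
        c = np.asarray(les.center)
        inside = np.sum((pts - c) ** 2, axis=-1) <= les.radius**2
        speed[inside] = les.sound_speed
        dens[inside] = les.density

    origin = tuple(a[0] for a in axes)
    return AcousticMap(speed.reshape(shape), dens.reshape(shape),
                       (spacing,) * spec.ndim, origin)


def to_scatterers(amap: AcousticMap, ambient_impedance: float | None = None,
                  rtol: float = 1e-9) -> ScattererCloud:
    """Reduce an acoustic map to its interface scatterers.

    A voxel emits a scatterer when its impedance Z = rho*c differs from at
    least one face neighbor *and* from the ambient impedance (so a
    homogeneous water map emits nothing and a single-voxel inclusion emits
    exactly one point).  The reflectivity is the impedance contrast
    against the face-neighbor mean,

        R = (Z - mean(Z_neighbors)) / (Z + mean(Z_neighbors)),

    whose sign matches the contrast sign.
    """
    Z = amap.impedance
    if ambient_impedance is None:
        ambient_impedance = WATER_SPEED * WATER_DENSITY
    ndim = Z.ndim
    nbr_sum = np.zeros_like(Z)
    nbr_cnt = np.zeros_like(Z)
    differs = np.zeros(Z.shape, dtype=bool)
    for ax in range(ndim):
        for shift in (1, -1):
            rolled = np.roll(Z, shift, axis=ax)
            # edge-replicate instead of wrap
            sl = [slice(None)] * ndim
            sl[ax] = 0 if shift == 1 else -1
            src = [slice(None)] * ndim
            src[ax] = 0 if shift == 1 else -1
            rolled[tuple(sl)] = Z[tuple(src)]
            nbr_sum += rolled
            nbr_cnt += 1.0
            differs |= ~np.isclose(rolled, Z, rtol=rtol)
    nbr_mean = nbr_sum / nbr_cnt
    emit = differs & ~np.isclose(Z, ambient_impedance, rtol=rtol)
    if not np.any(emit):
        return ScattererCloud(np.zeros((0, ndim)), np.zeros(0))
    idx = np.argwhere(emit)  # (n, ndim) index order (y,x) or (z,y,x)
    # convert index order to physical (x, y[, z])
    cols = idx[:, ::-1].astype(float)  # now (x_idx, y_idx[, z_idx])
    pos = np.empty_like(cols)
    for ax in range(ndim):
        pos[:, ax] = amap.origin[ax] + amap.spacing[ax] * cols[:, ax]
    refl = (Z[emit] - nbr_mean[emit]) / (Z[emit] + nbr_mean[emit])
    return ScattererCloud(pos, refl)
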