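"""Isosurface extraction and mesh export.

The segmented, densified volume is turned into a triangle mesh with the
standard marching-cubes procedure: each cell's 8 corner values are
compared against the iso value c to form an 8-bit case index into the
256-entry triangulation table, edge vertices are placed by linear
interpolation between the bracketing corner values, and per-vertex
normals come from central-difference gradients interpolated to the
vertices.  The cell-table walk itself is delegated to
``skimage.measure.marching_cubes``; the gradient-based normal field and
the physical-coordinate bookkeeping are handled here.

Normals point from high values toward low values -- outward for solids
defined by "inside >= c".  Binary masks should be lightly smoothed
(sigma = 1 voxel) before extraction at c = 0.5 to avoid staircase
artifacts; ``mesh_from_mask`` does exactly that.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import trimesh
from scipy import ndimage
from skimage import measure

from .interp import VolumeGrid
from .preprocess import gaussian_smooth

__all__ = ["IsoSurfaceSpec", "TriangleMesh", "marching_cubes",
           "corner_normals", "mesh_from_mask", "export_mesh", "load_mesh"]


@dataclass(frozen=True)
class IsoSurfaceSpec:
    """Iso value c defining the surface {(x,y,z) : f(x,y,z) = c}."""

    c: float


@dataclass
class TriangleMesh:
    """Vertices (mm, xyz), face index triples and unit vertex normals."""

    vertices: np.ndarray
    faces: np.ndarray
    normals: np.ndarray

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        self.normals = np.asarray(self.normals, dtype=float).reshape(-1, 3)
        if self.faces.size and (self.faces.min() < 0 or
                                self.faces.max() >= len(self.vertices)):
            raise ValueError("face indices out of range")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def as_trimesh(self) -> trimesh.Trimesh:
        if self.n_vertices == 0:
            return trimesh.Trimesh(vertices=np.zeros((0, 3)),
                                   faces=np.zeros((0, 3), dtype=np.int64),
                                   process=False)
        return trimesh.Trimesh(vertices=self.vertices, faces=self.faces,
                               vertex_normals=self.normals, process=False)


def _empty_mesh() -> TriangleMesh:
    return TriangleMesh(np.zeros((0, 3)), np.zeros((0, 3), dtype=np.int64),
                        np.zeros((0, 3)))


def corner_normals(volume: VolumeGrid) -> np.ndarray:
    """Central-difference normal field, shape (nz, ny, nx, 3) in xyz order.

    The gradient is taken with respect to physical coordinates (mm),
    negated (normals run from high values toward low) and normalized;
    zero-gradient points get a zero vector, flagging the normal as
    undefined there.
    """
    dx, dy, dz = volume.spacing
    gz, gy, gx = np.gradient(volume.values, dz, dy, dx)
    n = np.stack([-gx, -gy, -gz], axis=-1)
    mag = np.linalg.norm(n, axis=-1)
    ok = mag > 0
    n[ok] = n[ok] / mag[ok][..., None]
    n[~ok] = 0.0
    return n


def _drop_degenerate(verts, faces):
    if faces.size == 0:
        return faces
    a = verts[faces[:, 1]] - verts[faces[:, 0]]
    b = verts[faces[:, 2]] - verts[faces[:, 0]]
    area2 = np.linalg.norm(np.cross(a, b), axis=1)
    return faces[area2 > 0]


def marching_cubes(volume: VolumeGrid, c: float) -> TriangleMesh:
    """Extract the iso-c triangle mesh in physical coordinates (mm).

    An iso value outside the volume's range yields an empty mesh rather
    than an error.  Zero-area faces are dropped.
    """
    vals = volume.values
    if any(s < 2 for s in vals.shape):
        raise ValueError("marching cubes needs at least 2 cells per axis")
    if not (vals.min() < c < vals.max()):
        return _empty_mesh()
    level = c
    if np.any(vals == c):
        # nudge the level off exact corner values: a corner-exact surface
        # would emit zero-area faces and open the mesh
        # (1e-6 of the range: visible only at the 7th digit, but large
        # enough to survive the extractor's float32 arithmetic)
        level = c + 1e-6 * (vals.max() - vals.min())
    dx, dy, dz = volume.spacing
    verts_zyx, faces, _, _ = measure.marching_cubes(
        vals, level=level, spacing=(dz, dy, dx))
    verts = verts_zyx[:, ::-1] + np.asarray(volume.origin)  # -> (x, y, z)
    faces = _drop_degenerate(verts, faces)
    if faces.size == 0:
        return _empty_mesh()
    used = np.unique(faces)
    remap = -np.ones(len(verts), dtype=np.int64)
    remap[used] = np.arange(used.size)
    verts = verts[used]
    faces = remap[faces]

    # vertex normals: central-difference field sampled at the vertices
    field = corner_normals(volume)
    x0, y0, z0 = volume.origin
    iz = (verts[:, 2] - z0) / dz
    iy = (verts[:, 1] - y0) / dy
    ix = (verts[:, 0] - x0) / dx
    coords = np.vstack([iz, iy, ix])
    normals = np.column_stack([
        ndimage.map_coordinates(field[..., k], coords, order=1,
                                mode="nearest")
        for k in range(3)
    ])
    mag = np.linalg.norm(normals, axis=1)
    ok = mag > 1e-12
    normals[ok] = normals[ok] / mag[ok][:, None]
    normals[~ok] = np.array([0.0, 0.0, 1.0])  # arbitrary unit for flats
    return TriangleMesh(verts, faces, normals)


def mesh_from_mask(mask_volume: VolumeGrid, sigma: float = 1.0,
                   c: float = 0.5) -> TriangleMesh:
    """Marching cubes on a binary mask, pre-smoothed to avoid staircasing."""
    smoothed = gaussian_smooth(mask_volume.values.astype(float), sigma)
    return marching_cubes(VolumeGrid(smoothed, mask_volume.spacing,
                                     mask_volume.origin), c)


def export_mesh(mesh: TriangleMesh, path, file_format: str | None = None):
    """Write PLY/STL/OBJ; the format defaults to the path suffix."""
    path = str(path)
    if file_format is None:
        file_format = path.rsplit(".", 1)[-1].lower()
    if file_format not in ("ply", "stl", "obj"):
        raise ValueError(f"unsupported mesh format {file_format!r}")
    if mesh.n_vertices == 0:
        # valid zero-face files (trimesh refuses empty geometry)
        if file_format == "ply":
            text = ("ply\nformat ascii 1.0\nelement vertex 0\n"
                    "property float x\nproperty float y\nproperty float z\n"
                    "element face 0\n"
                    "property list uchar int vertex_indices\nend_header\n")
        elif file_format == "obj":
            text = "# empty mesh\n"
        else:
            text = "solid empty\nendsolid empty\n"
        with open(path, "w") as fh:
            fh.write(text)
        return text
    tm = mesh.as_trimesh()
    kwargs = {"encoding": "ascii"} if file_format == "ply" else {}
    data = trimesh.exchange.export.export_mesh(
        tm, path, file_type=file_format, **kwargs)
    return data


def load_mesh(path) -> TriangleMesh:
    """Read a mesh back (PLY/STL/OBJ) as a TriangleMesh."""
    tm = trimesh.load(str(path), process=False)
    verts = np.asarray(getattr(tm, "vertices", np.zeros((0, 3))),
                       dtype=float).reshape(-1, 3)
    faces = np.asarray(getattr(tm, "faces", np.zeros((0, 3))),
                       dtype=np.int64).reshape(-1, 3)
    if len(verts) == 0:
        return _empty_mesh()
    if len(verts):
        normals = np.asarray(tm.vertex_normals, dtype=float)
    else:
        normals = np.zeros((0, 3))
    return TriangleMesh(verts, faces, normals)
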