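"""Image-stack I/O for FIB/SEM slice-and-view data.

A slice-and-view acquisition produces an ordered stack of 2D secondary-electron
images, one per milling step.  This module reads and writes such stacks
(multi-page TIFF or a directory of numbered single-page TIFFs), carries the
acquisition geometry (pixel size, slice thickness, viewing angle) alongside the
raster data, and exports segmented label volumes as triangulated surface
meshes in physical (nm) coordinates.

Axis convention used throughout the package: volumes are indexed
``(slice, row, column)``, 0-based.  The slice index runs along the milling
axis (the depth consumed by the ion beam); within a slice, row 0 is the image
top and the substrate lies toward high row indices.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import tifffile
import trimesh
from skimage import measure

__all__ = [
    "VoxelGeometry",
    "ImageStack",
    "read_stack",
    "write_stack",
    "export_surface_mesh",
    "geometry_from_config",
]


@dataclass(frozen=True)
class VoxelGeometry:
    """Physical size of one voxel and the SEM viewing angle.

    Parameters
    ----------
    pixel_size_x, pixel_size_y : float
        In-plane sampling, nm per pixel.
    slice_thickness : float
        Depth of material removed per milling step, nm.
    view_angle : float
        Angle in degrees between the SEM optical axis and the normal of the
        cut face.  Because the ion and electron columns are not collinear,
        images are recorded under a tilt (52 degrees in a typical dual-beam
        system) and appear vertically foreshortened until corrected.
    """

    pixel_size_x: float
    pixel_size_y: float
    slice_thickness: float
    view_angle: float = 0.0

    def __post_init__(self) -> None:
        for name in ("pixel_size_x", "pixel_size_y", "slice_thickness"):
            if not np.isfinite(getattr(self, name)) or getattr(self, name) <= 0:
                raise ValueError(f"{name} must be a positive finite length in nm")
        if not (0.0 <= self.view_angle < 90.0):
            raise ValueError("view_angle must satisfy 0 <= angle < 90 degrees")

    @property
    def pixel_area(self) -> float:
        """In-plane pixel area in nm^2."""
        return self.pixel_size_x * self.pixel_size_y

    @property
    def voxel_volume(self) -> float:
        """Voxel volume in nm^3."""
        return self.pixel_area * self.slice_thickness

    def replace(self, **changes) -> "VoxelGeometry":
        return replace(self, **changes)


@dataclass
class ImageStack:
    """An ordered stack of same-shaped 2D intensity rasters plus geometry.

    ``data`` has shape ``(n_slices, n_rows, n_cols)``.  Rasters are kept in
    their native dtype on read; processing steps convert to float internally.
    """

    data: np.ndarray
    geometry: VoxelGeometry
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("stack data must be 3D (slice, row, column)")
        if self.data.shape[0] < 1:
            raise ValueError("stack must contain at least one slice")
        if not np.all(np.isfinite(np.asarray(self.data, dtype=float))):
            raise ValueError("stack intensities must be finite")

    @property
    def n_slices(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple:
        return self.data.shape

    def as_float(self) -> np.ndarray:
        return np.asarray(self.data, dtype=np.float64)

    def with_data(self, data: np.ndarray, **provenance) -> "ImageStack":
        prov = dict(self.provenance)
        prov.update(provenance)
        return ImageStack(data=data, geometry=self.geometry, provenance=prov)


_NUM_RE = re.compile(r"(\d+)")


def _numeric_key(path: Path):
    """Sort key that orders s2.tif before s10.tif (numeric-aware)."""
    parts = _NUM_RE.split(path.name)
    return tuple(int(p) if p.isdigit() else p for p in parts)


def read_stack(path, geometry: VoxelGeometry) -> ImageStack:
    """Read a multi-page TIFF or a directory of numbered TIFFs as a stack.

    Slices are ordered by page index (multi-page) or by numeric-aware
    filename sort (directory).  The supplied geometry is attached unchanged.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such stack: {path}")
    if path.is_dir():
        files = sorted(
            (p for p in path.iterdir() if p.suffix.lower() in (".tif", ".tiff")),
            key=_numeric_key,
        )
        if not files:
            raise FileNotFoundError(f"no TIFF files in directory {path}")
        slices = [tifffile.imread(f) for f in files]
        shapes = {s.shape for s in slices}
        if len(shapes) != 1:
            raise ValueError(f"inconsistent slice shapes in {path}: {sorted(shapes)}")
        data = np.stack(slices, axis=0)
        source = [f.name for f in files]
    else:
        data = tifffile.imread(path)
        if data.ndim == 2:
            data = data[None]
        if data.ndim != 3:
            raise ValueError(f"{path} does not contain a stack of 2D images")
        source = str(path)
    return ImageStack(data=data, geometry=geometry, provenance={"source": source})


def write_stack(stack: ImageStack, path) -> Path:
    """Write a stack as a multi-page TIFF, preserving dtype exactly."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, stack.data)
    return path


def export_surface_mesh(
    labels: np.ndarray,
    geometry: VoxelGeometry,
    path,
    which: Iterable[int] | None = None,
) -> Path:
    """Export triangulated isosurfaces of a 3D label volume, scaled to nm.

    One marching-cubes surface per label is computed (on the zero-padded
    binary volume so surfaces close at the volume border) and all surfaces
    are concatenated into a single PLY or STL file.  Vertex coordinates are
    ``(z, y, x)`` in nm using slice thickness and pixel sizes.

    Raises ``ValueError`` when the volume holds no labelled voxel.
    """
    labels = np.asarray(labels)
    if labels.ndim != 3:
        raise ValueError("label volume must be 3D")
    ids = [int(v) for v in np.unique(labels) if v != 0]
    if which is not None:
        which = set(int(v) for v in which)
        ids = [v for v in ids if v in which]
    if not ids:
        raise ValueError("label volume contains no non-background voxels to export")

    spacing = (
        geometry.slice_thickness,
        geometry.pixel_size_y,
        geometry.pixel_size_x,
    )
    meshes = []
    for lab in ids:
        vol = np.pad((labels == lab).astype(np.float32), 1)
        verts, faces, _, _ = measure.marching_cubes(vol, level=0.5, spacing=spacing)
        # undo the one-voxel pad offset
        verts = verts - np.asarray(spacing)
        meshes.append(trimesh.Trimesh(vertices=verts, faces=faces, process=False))
    mesh = trimesh.util.concatenate(meshes) if len(meshes) > 1 else meshes[0]
    if mesh.volume < 0:  # enforce outward-facing normals
        mesh.invert()
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    mesh.export(path)
    return path


def geometry_from_config(cfg: Mapping) -> VoxelGeometry:
    """Build a :class:`VoxelGeometry` from config keys.

    Recognised keys: ``pixel_size_x_nm``, ``pixel_size_y_nm``,
    ``slice_thickness_nm``, ``view_angle_deg``.
    """
    return VoxelGeometry(
        pixel_size_x=float(cfg["pixel_size_x_nm"]),
        pixel_size_y=float(cfg["pixel_size_y_nm"]),
        slice_thickness=float(cfg["slice_thickness_nm"]),
        view_angle=float(cfg.get("view_angle_deg", 0.0)),
    )
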