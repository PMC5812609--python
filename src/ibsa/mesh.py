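"""Iso-surface meshing of body masks and surface-area measurement (iBSA).

A binary body mask is smoothed with a physically isotropic Gaussian and
triangulated with marching cubes at the 0.5 iso-level; the image-derived
body surface area (iBSA) is the sum of triangle face areas, reported in
cm² and m².

Marching cubes run directly on a raw binary mask systematically
overestimates the area of smooth bodies (staircase metrication).  The
Gaussian pre-smoothing (default sigma = 1 voxel on the finest axis)
removes that bias and makes the measured area converge to the analytic
truth on phantoms; ``smoothing_sigma_vox=0`` reproduces the raw
behaviour for study.  No decimation or Taubin smoothing is applied:
both silently alter area.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, asdict

import numpy as np
from scipy import ndimage
from skimage.measure import marching_cubes

from .ct_io import CTVolume
from .errors import EmptyMaskError, InvalidExtentError
from .segmentation import BodyMask, SegmentationConfig, segment_body


@dataclass
class MeshConfig:
    """Meshing parameters: Gaussian sigma (voxels on the finest axis) and iso-level."""

    smoothing_sigma_vox: float = 1.0
    iso_level: float = 0.5


@dataclass
class TriangleMesh:
    """Triangulated surface; vertices in millimetres."""

    vertices: np.ndarray  # (n, 3) float, mm, (z, y, x)
    faces: np.ndarray     # (m, 3) int

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64)
        self.faces = np.asarray(self.faces, dtype=np.int64)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def euler_characteristic(self) -> int:
        """V - E + F; 2 for a watertight genus-0 surface."""
        edges = np.sort(
            self.faces[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2), axis=1
        )
        n_edges = len(np.unique(edges, axis=0))
        return self.n_vertices - n_edges + self.n_faces

    def export(self, path: str) -> None:
        """Write PLY (binary little-endian) or STL for inspection."""
        import trimesh

        trimesh.Trimesh(vertices=self.vertices, faces=self.faces,
                        process=False).export(path)


@dataclass
class SurfaceMeasurement:
    """An iBSA measurement with mesh statistics and provenance."""

    area_cm2: float
    area_m2: float
    n_vertices: int
    n_faces: int
    z_extent_mm: float
    area_per_length_cm2_per_cm: float | None = None
    config_fingerprint: str = ""

    def to_dict(self) -> dict:
        return asdict(self)


def _face_areas(vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    v0, v1, v2 = (vertices[faces[:, i]] for i in range(3))
    return 0.5 * np.linalg.norm(np.cross(v1 - v0, v2 - v0), axis=1)


def mesh_area(mesh: TriangleMesh) -> float:
    """Total surface area in mm²: sum over faces of ½‖(v1−v0)×(v2−v0)‖."""
    if mesh.n_faces == 0:
        return 0.0
    return float(_face_areas(mesh.vertices, mesh.faces).sum())


def mask_to_mesh(mask: BodyMask, smoothing_sigma_vox: float = 1.0,
                 iso_level: float = 0.5) -> TriangleMesh:
    """Triangulate the mask's iso-surface at physical scale.

    The mask is converted to a float field, smoothed with a Gaussian that
    is isotropic in physical space (sigma = ``smoothing_sigma_vox`` voxels
    on the finest-spacing axis, rescaled per axis), padded with one layer
    of background so the surface closes, and passed to marching cubes
    with the voxel spacing applied.  Degenerate (zero-area) faces are
    dropped.
    """
    m = mask.voxels
    if not m.any():
        raise EmptyMaskError("empty mask")
    touches = (
        m[[0, -1], :, :].any() or m[:, [0, -1], :].any() or m[:, :, [0, -1]].any()
    )
    if touches:
        warnings.warn(
            "open surface: mask touches the volume border; "
            "the iso-surface is closed by clipping at the field of view",
            stacklevel=2,
        )
    spacing = np.asarray(mask.spacing, dtype=float)
    field = np.pad(m.astype(np.float32), 1)
    if smoothing_sigma_vox > 0:
        sigma_mm = smoothing_sigma_vox * spacing.min()
        ndimage.gaussian_filter(field, sigma=sigma_mm / spacing, output=field)
    try:
        verts, faces, _, _ = marching_cubes(field, level=iso_level,
                                            spacing=tuple(spacing))
    except ValueError as exc:
        raise EmptyMaskError(f"empty mask: no iso-surface ({exc})") from exc
    verts -= spacing  # undo the 1-voxel pad
    areas = _face_areas(verts, faces)
    faces = faces[areas > 0]
    return TriangleMesh(vertices=verts, faces=faces)


def measure_mask(mask: BodyMask, mesh_config: MeshConfig | None = None,
                 fingerprint: str = "") -> SurfaceMeasurement:
    """Mesh a mask and measure its surface."""
    mesh_config = mesh_config or MeshConfig()
    mesh = mask_to_mesh(mask, mesh_config.smoothing_sigma_vox,
                        mesh_config.iso_level)
    area_mm2 = mesh_area(mesh)
    nz = mask.shape[0]
    return SurfaceMeasurement(
        area_cm2=area_mm2 / 100.0,
        area_m2=area_mm2 / 1e6,
        n_vertices=mesh.n_vertices,
        n_faces=mesh.n_faces,
        z_extent_mm=(nz - 1) * mask.spacing[0],
        config_fingerprint=fingerprint,
    )


def measure_ibsa(ct: CTVolume, seg_config: SegmentationConfig | None = None,
                 mesh_config: MeshConfig | None = None) -> SurfaceMeasurement:
    """Full pipeline: segment_body -> mask_to_mesh -> mesh_area.

    Deterministic for a fixed configuration; the configuration fingerprint
    is embedded in the measurement for provenance.
    """
    seg_config = seg_config or SegmentationConfig()
    mesh_config = mesh_config or MeshConfig()
    mask = segment_body(ct, seg_config)
    blob = json.dumps({"seg": asdict(seg_config), "mesh": asdict(mesh_config)},
                      sort_keys=True).encode()
    fp = hashlib.sha256(blob).hexdigest()[:16]
    return measure_mask(mask, mesh_config, fingerprint=fp)


def normalize_partial(m: SurfaceMeasurement) -> SurfaceMeasurement:
    """Per-length normalisation of a partial-scan measurement (cm² per cm of z).

    A partial acquisition (thoracic, abdominal) yields an iBSA that depends
    on scan coverage; dividing by the z-extent gives a length-normalised
    surface usable for longitudinal (e.g. nutritional) follow-up.
    """
    if m.z_extent_mm <= 0:
        raise InvalidExtentError("invalid extent: z_extent_mm must be > 0")
    return SurfaceMeasurement(
        area_cm2=m.area_cm2,
        area_m2=m.area_m2,
        n_vertices=m.n_vertices,
        n_faces=m.n_faces,
        z_extent_mm=m.z_extent_mm,
        area_per_length_cm2_per_cm=m.area_cm2 / (m.z_extent_mm / 10.0),
        config_fingerprint=m.config_fingerprint,
    )
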