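"""Reading and writing CT volumes, masks and QC overlays.

All volumes are held in a canonical ``(z, y, x)`` axis order with per-axis
physical spacing in millimetres and voxel values calibrated to Hounsfield
units (HU).  DICOM series are sorted by spatial position (never by file
name) and rescaled with the per-slice slope/intercept; slice spacing is
derived from inter-slice position deltas, falling back to the declared
SliceThickness.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import (
    FormatError,
    GeometryMismatchError,
    InconsistentSeriesError,
    MultipleSeriesError,
    SliceOutOfRangeError,
)

HU_MIN = -1024.0
HU_MAX = 3071.0


@dataclass
class CTVolume:
    """A calibrated CT volume.

    Attributes
    ----------
    voxels : ndarray, shape (nz, ny, nx)
        Hounsfield units, clipped to [-1024, 3071].
    spacing : tuple of float
        Physical voxel size per axis (z, y, x), millimetres.
    origin : tuple of float
        Physical position of voxel (0, 0, 0), millimetres, (z, y, x).
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float32)
        if self.voxels.ndim != 3:
            raise FormatError("CT volume must be 3-D")
        if any(n < 2 for n in self.voxels.shape):
            raise FormatError("CT volume needs at least 2 voxels per axis")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise FormatError("voxel spacing must be positive")
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))


@dataclass
class QcBundle:
    """Per-slice QC overlays plus a 3-plane MIP snapshot.

    ``overlays`` maps slice index -> dict with uint8 image arrays
    ``ct`` (grayscale), ``contour`` (RGB, mask outline over CT) and
    ``panel`` (RGB side-by-side of the two).
    """

    overlays: dict[int, dict[str, np.ndarray]]
    snapshot: np.ndarray = field(repr=False, default=None)

    def save(self, directory: str) -> list[str]:
        """Write all images as PNG; returns the file paths."""
        from PIL import Image

        os.makedirs(directory, exist_ok=True)
        paths = []
        for idx, imgs in self.overlays.items():
            p = os.path.join(directory, f"slice_{idx:04d}_panel.png")
            Image.fromarray(imgs["panel"]).save(p)
            paths.append(p)
        if self.snapshot is not None:
            p = os.path.join(directory, "mip_3plane.png")
            Image.fromarray(self.snapshot).save(p)
            paths.append(p)
        return paths


def _clip_hu(arr: np.ndarray) -> np.ndarray:
    return np.clip(arr, HU_MIN, HU_MAX)


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def read_ct(path: str, format: str = "auto") -> CTVolume:
    """Read a CT volume from DICOM series dir, NIfTI or MetaImage.

    Parameters
    ----------
    path : str
        File (NIfTI/MetaImage) or directory (DICOM series).
    format : {"auto", "dicom_dir", "nifti", "metaimage"}
    """
    if not os.path.exists(path):
        raise FormatError(f"no such path: {path}")
    if format == "auto":
        if os.path.isdir(path):
            format = "dicom_dir"
        elif path.endswith((".nii", ".nii.gz")):
            format = "nifti"
        elif path.endswith((".mha", ".mhd")):
            format = "metaimage"
        else:
            raise FormatError(f"cannot infer format of {path}")
    if format == "dicom_dir":
        return _read_dicom_dir(path)
    if format == "nifti":
        return _read_nifti(path)
    if format == "metaimage":
        return _read_metaimage(path)
    raise FormatError(f"unknown format {format!r}")


def _read_nifti(path: str) -> CTVolume:
    import nibabel as nib

    try:
        img = nib.load(path)
    except Exception as exc:  # nibabel raises various types
        raise FormatError(f"format error reading {path}: {exc}") from exc
    img = nib.as_closest_canonical(img)
    data = np.asanyarray(img.dataobj, dtype=np.float32)  # (x, y, z)
    if data.ndim != 3:
        raise FormatError("NIfTI volume must be 3-D")
    zooms = img.header.get_zooms()[:3]
    origin_xyz = img.affine[:3, 3]
    return CTVolume(
        voxels=_clip_hu(data.T),  # -> (z, y, x)
        spacing=(float(zooms[2]), float(zooms[1]), float(zooms[0])),
        origin=(float(origin_xyz[2]), float(origin_xyz[1]), float(origin_xyz[0])),
    )


def _read_metaimage(path: str) -> CTVolume:
    import SimpleITK as sitk

    try:
        img = sitk.ReadImage(path)
    except Exception as exc:
        raise FormatError(f"format error reading {path}: {exc}") from exc
    # Reorient non-axial acquisitions to a canonical axial frame.
    try:
        img = sitk.DICOMOrient(img, "LPS")
    except Exception:
        pass
    arr = sitk.GetArrayFromImage(img).astype(np.float32)  # (z, y, x)
    if arr.ndim != 3:
        raise FormatError("MetaImage volume must be 3-D")
    sp = img.GetSpacing()  # (x, y, z)
    og = img.GetOrigin()
    return CTVolume(
        voxels=_clip_hu(arr),
        spacing=(float(sp[2]), float(sp[1]), float(sp[0])),
        origin=(float(og[2]), float(og[1]), float(og[0])),
    )


def _read_dicom_dir(path: str) -> CTVolume:
    import pydicom

    files = sorted(
        os.path.join(path, f)
        for f in os.listdir(path)
        if not f.startswith(".") and os.path.isfile(os.path.join(path, f))
    )
    if not files:
        raise FormatError(f"no files in DICOM directory {path}")
    slices = []
    for f in files:
        try:
            ds = pydicom.dcmread(f)
        except Exception as exc:
            raise FormatError(f"format error reading {f}: {exc}") from exc
        slices.append(ds)

    uids = {getattr(ds, "SeriesInstanceUID", None) for ds in slices}
    if len(uids) > 1:
        raise MultipleSeriesError("multiple series in directory")

    # Sort by position along the slice normal, never by file name.
    first = slices[0]
    iop = [float(v) for v in getattr(first, "ImageOrientationPatient",
                                     [1, 0, 0, 0, 1, 0])]
    row, col = np.array(iop[:3]), np.array(iop[3:])
    normal = np.cross(row, col)
    positions = []
    for ds in slices:
        ipp = getattr(ds, "ImagePositionPatient", None)
        if ipp is None:
            raise InconsistentSeriesError("inconsistent series: slice lacks position")
        positions.append(float(np.dot(normal, [float(v) for v in ipp])))
    order = np.argsort(positions)
    slices = [slices[i] for i in order]
    positions = np.asarray(positions)[order]

    deltas = np.diff(positions)
    if len(deltas) == 0:
        raise InconsistentSeriesError("inconsistent series: single slice")
    if np.any(np.abs(deltas) < 1e-6):
        raise InconsistentSeriesError("inconsistent series: duplicated slice positions")
    if np.max(deltas) - np.min(deltas) > 0.05 * np.median(deltas):
        raise InconsistentSeriesError("inconsistent series: missing or irregular slices")
    z_spacing = float(np.median(deltas))

    declared = getattr(first, "SliceThickness", None)
    if declared is not None and float(declared) > 0:
        if abs(z_spacing - float(declared)) > 0.10 * float(declared):
            warnings.warn(
                f"slice spacing from positions ({z_spacing:.3f} mm) disagrees with "
                f"declared SliceThickness ({float(declared):.3f} mm) by >10%; "
                "using position deltas",
                stacklevel=2,
            )

    ps = [float(v) for v in getattr(first, "PixelSpacing", [1.0, 1.0])]
    vol = np.empty((len(slices), first.Rows, first.Columns), dtype=np.float32)
    for i, ds in enumerate(slices):
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        vol[i] = ds.pixel_array.astype(np.float32) * slope + intercept

    ipp0 = [float(v) for v in slices[0].ImagePositionPatient]
    return CTVolume(
        voxels=_clip_hu(vol),
        spacing=(z_spacing, ps[0], ps[1]),
        origin=(float(positions[0]), float(ipp0[1]), float(ipp0[0])),
    )


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def _affine_from_geometry(ref: CTVolume) -> np.ndarray:
    sz, sy, sx = ref.spacing
    oz, oy, ox = ref.origin
    aff = np.diag([sx, sy, sz, 1.0])
    aff[:3, 3] = [ox, oy, oz]
    return aff


def write_mask(mask, ref: CTVolume, path: str) -> None:
    """Persist a binary mask as NIfTI uint8 with geometry copied from ``ref``."""
    import nibabel as nib

    voxels = np.asarray(getattr(mask, "voxels", mask))
    if voxels.shape != ref.shape:
        raise GeometryMismatchError(
            f"geometry mismatch: mask {voxels.shape} vs reference {ref.shape}"
        )
    data = (voxels > 0).astype(np.uint8).T  # (z,y,x) -> (x,y,z)
    img = nib.Nifti1Image(data, _affine_from_geometry(ref))
    img.header.set_zooms(tuple(reversed(ref.spacing)))
    nib.save(img, path)


def read_mask(path: str) -> np.ndarray:
    """Read a binary NIfTI mask back to a (z, y, x) boolean array."""
    import nibabel as nib

    img = nib.load(path)
    return (np.asanyarray(img.dataobj) > 0).T


def write_ct(ct: CTVolume, path: str) -> None:
    """Persist a CT volume as NIfTI (float32 HU)."""
    import nibabel as nib

    img = nib.Nifti1Image(ct.voxels.T.astype(np.float32),
                          _affine_from_geometry(ct))
    img.header.set_zooms(tuple(reversed(ct.spacing)))
    nib.save(img, path)


# ---------------------------------------------------------------------------
# QC overlays
# ---------------------------------------------------------------------------

def _window(slice_hu: np.ndarray, lo: float = -1000.0, hi: float = 1000.0) -> np.ndarray:
    g = np.clip((slice_hu - lo) / (hi - lo), 0.0, 1.0)
    return (g * 255).astype(np.uint8)


def _contour2d(mask2d: np.ndarray) -> np.ndarray:
    from scipy import ndimage

    m = mask2d.astype(bool)
    return m & ~ndimage.binary_erosion(m, border_value=0)


def qc_overlay(ct: CTVolume, mask, slices: list[int]) -> QcBundle:
    """Build deterministic QC images: CT slice, contour overlay, side-by-side panel.

    Mirrors a reviewer workflow of comparing the original acquisition with
    its segmentation mask slice by slice, plus a 3-plane MIP snapshot.
    """
    voxels = np.asarray(getattr(mask, "voxels", mask)).astype(bool)
    if voxels.shape != ct.shape:
        raise GeometryMismatchError("geometry mismatch between CT and mask")
    nz = ct.shape[0]
    overlays: dict[int, dict[str, np.ndarray]] = {}
    for idx in slices:
        if not (0 <= idx < nz):
            raise SliceOutOfRangeError(f"slice out of range: {idx} (nz={nz})")
        g = _window(ct.voxels[idx])
        rgb = np.stack([g, g, g], axis=-1)
        contour = _contour2d(voxels[idx])
        rgb[contour] = (255, 40, 40)
        panel = np.concatenate([np.stack([g, g, g], axis=-1), rgb], axis=1)
        overlays[idx] = {"ct": g, "contour": rgb, "panel": panel}

    mips = [_window(ct.voxels.max(axis=a)) for a in range(3)]
    h = max(m.shape[0] for m in mips)
    padded = [np.pad(m, ((0, h - m.shape[0]), (0, 2))) for m in mips]
    snapshot = np.concatenate(padded, axis=1)
    snapshot = np.stack([snapshot] * 3, axis=-1)
    return QcBundle(overlays=overlays, snapshot=snapshot)
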