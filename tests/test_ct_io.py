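"""I/O contracts: format round-trips, DICOM calibration/sorting, QC overlays."""

import os

import numpy as np
import pydicom
import pytest
from pydicom.dataset import FileDataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid

import ibsa
from ibsa.errors import (
    GeometryMismatchError,
    InconsistentSeriesError,
    MultipleSeriesError,
    SliceOutOfRangeError,
)


def _make_dicom_slice(path, z_pos, stored_value, series_uid, *,
                      slope=1.0, intercept=-1024.0, thickness=3.0, shape=(16, 16)):
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = pydicom.uid.CTImageStorage
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = FileDataset(path, {}, file_meta=meta, preamble=b"\0" * 128)
    ds.SOPClassUID = meta.MediaStorageSOPClassUID
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.SeriesInstanceUID = series_uid
    ds.Modality = "CT"
    ds.Rows, ds.Columns = shape
    ds.PixelSpacing = [0.8, 0.8]
    ds.SliceThickness = thickness
    ds.ImagePositionPatient = [0.0, 0.0, z_pos]
    ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
    ds.RescaleSlope = slope
    ds.RescaleIntercept = intercept
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 0
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    arr = np.full(shape, stored_value, dtype=np.uint16)
    ds.PixelData = arr.tobytes()
    ds.save_as(path, enforce_file_format=True)


def _write_series(directory, z_positions, stored=1024, names=None, uid=None):
    uid = uid or generate_uid()
    names = names or [f"slice_{i:03d}.dcm" for i in range(len(z_positions))]
    for name, z in zip(names, z_positions):
        _make_dicom_slice(os.path.join(directory, name), z, stored, uid)
    return uid


class TestDicom:
    def test_hu_rescale(self, tmp_path):
        """stored 1024 with slope 1 / intercept -1024 reads back as 0 HU."""
        _write_series(tmp_path, [0.0, 3.0, 6.0])
        ct = ibsa.read_ct(str(tmp_path))
        assert ct.shape == (3, 16, 16)
        assert np.all(ct.voxels == 0.0)
        assert ct.spacing == (3.0, 0.8, 0.8)

    def test_slice_order_from_position_not_filename(self, tmp_path):
        uid = generate_uid()
        # file names in reverse order of position; per-slice stored value
        for i, (name, z) in enumerate(zip(["z.dcm", "m.dcm", "a.dcm"],
                                          [0.0, 3.0, 6.0])):
            _make_dicom_slice(os.path.join(tmp_path, name), z, 1024 + i, uid)
        ct = ibsa.read_ct(str(tmp_path))
        assert list(np.unique(ct.voxels[0])) == [0.0]
        assert list(np.unique(ct.voxels[2])) == [2.0]

    def test_missing_middle_slice_rejected(self, tmp_path):
        _write_series(tmp_path, [0.0, 3.0, 9.0, 12.0])
        with pytest.raises(InconsistentSeriesError):
            ibsa.read_ct(str(tmp_path))

    def test_duplicate_position_rejected(self, tmp_path):
        _write_series(tmp_path, [0.0, 3.0, 3.0])
        with pytest.raises(InconsistentSeriesError):
            ibsa.read_ct(str(tmp_path))

    def test_mixed_series_rejected(self, tmp_path):
        _write_series(tmp_path, [0.0, 3.0], names=["a.dcm", "b.dcm"])
        _write_series(tmp_path, [6.0], names=["c.dcm"])
        with pytest.raises(MultipleSeriesError):
            ibsa.read_ct(str(tmp_path))

    def test_spacing_thickness_disagreement_warns(self, tmp_path):
        uid = generate_uid()
        for i, z in enumerate([0.0, 1.5, 3.0]):  # 50% overlap: spacing 1.5, thickness 3
            _make_dicom_slice(os.path.join(tmp_path, f"s{i}.dcm"), z, 1024, uid,
                              thickness=3.0)
        with pytest.warns(UserWarning, match="SliceThickness"):
            ct = ibsa.read_ct(str(tmp_path))
        assert ct.spacing[0] == pytest.approx(1.5)


class TestNiftiMetaimage:
    def test_nifti_roundtrip_identity(self, tmp_path, sphere50):
        path = str(tmp_path / "sphere.nii.gz")
        ibsa.write_ct(sphere50.ct, path)
        ct = ibsa.read_ct(path)
        assert ct.shape == sphere50.ct.shape
        assert ct.spacing == pytest.approx(sphere50.ct.spacing)
        np.testing.assert_allclose(ct.voxels, sphere50.ct.voxels, atol=1e-3)

    def test_metaimage_read(self, tmp_path, sphere50):
        import SimpleITK as sitk

        img = sitk.GetImageFromArray(sphere50.ct.voxels)
        img.SetSpacing((1.0, 1.0, 1.0))
        path = str(tmp_path / "sphere.mha")
        sitk.WriteImage(img, path)
        ct = ibsa.read_ct(path)
        assert ct.shape == sphere50.ct.shape
        np.testing.assert_allclose(ct.voxels, sphere50.ct.voxels, atol=1e-3)

    def test_unreadable_file(self, tmp_path):
        bad = tmp_path / "bad.nii"
        bad.write_bytes(b"not a nifti")
        with pytest.raises(ibsa.errors.FormatError):
            ibsa.read_ct(str(bad))


class TestMaskIO:
    def test_mask_roundtrip_bitwise(self, tmp_path, sphere50, sphere50_mask):
        path = str(tmp_path / "mask.nii.gz")
        ibsa.write_mask(sphere50_mask, sphere50.ct, path)
        back = ibsa.read_mask(path)
        assert np.array_equal(back, sphere50_mask.voxels)

    def test_all_ones_mask_sum(self, tmp_path, sphere50):
        ones = np.ones(sphere50.ct.shape, dtype=bool)
        path = str(tmp_path / "ones.nii")
        ibsa.write_mask(ibsa.BodyMask(ones, sphere50.ct.spacing), sphere50.ct, path)
        assert ibsa.read_mask(path).sum() == np.prod(sphere50.ct.shape)

    def test_geometry_mismatch(self, tmp_path, sphere50):
        wrong = np.ones((4,) + sphere50.ct.shape[1:], dtype=bool)
        with pytest.raises(GeometryMismatchError):
            ibsa.write_mask(ibsa.BodyMask(wrong, sphere50.ct.spacing),
                            sphere50.ct, str(tmp_path / "m.nii"))


class TestQcOverlay:
    def test_contour_present_on_equatorial_slice(self, sphere50, sphere50_mask):
        mid = sphere50.ct.shape[0] // 2
        bundle = ibsa.qc_overlay(sphere50.ct, sphere50_mask, [mid])
        rgb = bundle.overlays[mid]["contour"]
        n_red = int(((rgb[..., 0] == 255) & (rgb[..., 1] == 40)).sum())
        assert n_red > 0

    def test_empty_mask_zero_contour(self, sphere50):
        empty = np.zeros(sphere50.ct.shape, dtype=bool)
        bundle = ibsa.qc_overlay(sphere50.ct, empty, [5])
        rgb = bundle.overlays[5]["contour"]
        assert int(((rgb[..., 0] == 255) & (rgb[..., 1] == 40)).sum()) == 0

    def test_three_slices_three_overlays(self, tmp_path, sphere50, sphere50_mask):
        nz = sphere50.ct.shape[0]
        bundle = ibsa.qc_overlay(sphere50.ct, sphere50_mask, [0, nz // 2, nz - 1])
        assert len(bundle.overlays) == 3
        paths = bundle.save(str(tmp_path / "qc"))
        assert all(os.path.exists(p) for p in paths)

    def test_out_of_range_slice(self, sphere50, sphere50_mask):
        with pytest.raises(SliceOutOfRangeError):
            ibsa.qc_overlay(sphere50.ct, sphere50_mask, [10_000])
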