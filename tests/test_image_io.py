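"""I/O: HU conversion, ordering, round trips, and the dataset split rule."""

import numpy as np
import pytest

import eatquant as eq
from eatquant.image_io import ImageIOError


def _slice(z, value=0.0, shape=(16, 16), sx=0.7, sy=0.7):
    return eq.CTSlice(pixels=np.full(shape, value, dtype=np.float32), sx=sx, sy=sy, z=z)


class TestSeries:
    def test_slices_sorted_by_z(self):
        series = eq.CTSeries(slices=[_slice(9.0, 3), _slice(3.0, 1), _slice(6.0, 2)])
        assert list(series.z_positions) == [3.0, 6.0, 9.0]
        assert [s.pixels[0, 0] for s in series] == [1, 2, 3]
        assert [s.index for s in series] == [0, 1, 2]

    def test_duplicate_z_rejected(self):
        with pytest.raises(ImageIOError):
            eq.CTSeries(slices=[_slice(1.0), _slice(1.0)])

    def test_bad_spacing_rejected(self):
        with pytest.raises(ImageIOError):
            eq.CTSlice(pixels=np.zeros((4, 4)), sx=0.0, sy=0.5, z=0.0)


class TestNifti:
    def test_hu_round_trip(self, tmp_path, noiseless_spec):
        series, _, _ = eq.generate_phantom_series(noiseless_spec)
        path = tmp_path / "p.nii.gz"
        eq.write_ct_series(series, path)
        back = eq.read_ct_series(path)
        assert len(back) == len(series)
        assert np.allclose(back.stack(), series.stack(), atol=1e-3)
        assert back.spacing == pytest.approx(series.spacing)
        assert np.allclose(np.diff(back.z_positions), np.median(series.z_gaps), atol=1e-4)

    def test_missing_spacing_is_an_error(self):
        import nibabel as nib

        from eatquant.image_io import _nifti_series_from_img

        img = nib.Nifti1Image(np.zeros((8, 8, 3), dtype=np.float32), affine=np.eye(4))
        img.header["pixdim"][1:4] = 0.0  # what a header with no spacing reports
        with pytest.raises(ImageIOError, match="spacing"):
            _nifti_series_from_img(img, "bad")


class TestDicom:
    def _write_dicom(self, path, z, stored=924, slope=1.0, intercept=-1024.0,
                     patient="P1", spacing=(0.7, 0.7), drop=None):
        import pydicom
        from pydicom.dataset import FileDataset, FileMetaDataset
        from pydicom.uid import ExplicitVRLittleEndian, generate_uid

        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = pydicom.uid.CTImageStorage
        meta.MediaStorageSOPInstanceUID = generate_uid()
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds = FileDataset(str(path), {}, file_meta=meta, preamble=b"\0" * 128)
        ds.PatientID = patient
        ds.Modality = "CT"
        ds.PixelSpacing = list(spacing)
        ds.ImagePositionPatient = [0.0, 0.0, float(z)]
        ds.RescaleSlope = slope
        ds.RescaleIntercept = intercept
        ds.Rows = ds.Columns = 8
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 0
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.PixelData = np.full((8, 8), stored, dtype=np.uint16).tobytes()
        for tag in drop or []:
            delattr(ds, tag)
        ds.save_as(str(path), enforce_file_format=True)

    def test_rescale_to_hu_and_sorting(self, tmp_path):
        # stored 924, slope 1, intercept -1024 -> -100 HU; shuffled z order
        for name, z in (("b.dcm", 6.0), ("a.dcm", 3.0)):
            self._write_dicom(tmp_path / name, z)
        series = eq.read_ct_series(tmp_path)
        assert list(series.z_positions) == [3.0, 6.0]
        assert np.all(series[0].pixels == -100.0)

    def test_missing_pixel_spacing_named(self, tmp_path):
        self._write_dicom(tmp_path / "a.dcm", 0.0, drop=["PixelSpacing"])
        with pytest.raises(ImageIOError, match="PixelSpacing"):
            eq.read_ct_series(tmp_path)

    def test_mixed_patients_rejected(self, tmp_path):
        self._write_dicom(tmp_path / "a.dcm", 0.0, patient="P1")
        self._write_dicom(tmp_path / "b.dcm", 3.0, patient="P2")
        with pytest.raises(ImageIOError, match="mixes patients"):
            eq.read_ct_series(tmp_path)


class TestMasks:
    @pytest.fixture()
    def mask_series(self, noiseless_spec):
        _, masks, _ = eq.generate_phantom_series(noiseless_spec)
        return masks

    @pytest.mark.parametrize("fmt", ["nifti", "png"])
    def test_round_trip_bit_identical(self, tmp_path, mask_series, fmt):
        path = tmp_path / ("m.nii.gz" if fmt == "nifti" else "masks")
        eq.write_mask_series(mask_series, path, format=fmt)
        back = eq.read_mask_series(path)
        assert np.array_equal(back.stack(), mask_series.stack())

    def test_png_dialect_255_reads_as_1(self, tmp_path, mask_series):
        from PIL import Image

        eq.write_mask_series(mask_series, tmp_path / "masks", format="png")
        raw = np.asarray(Image.open(tmp_path / "masks" / "mask_0004.png"))
        assert set(np.unique(raw)) <= {0, 255}
        back = eq.read_mask_series(tmp_path / "masks")
        assert set(np.unique(back.stack())) <= {0, 1}

    def test_grid_mismatch_with_series_rejected(self, noiseless_spec):
        series, _, _ = eq.generate_phantom_series(noiseless_spec)
        wrong = eq.MaskSeries(
            [eq.BinaryMask(grid=np.zeros((8, 8), dtype=np.uint8), sx=1, sy=1)
             for _ in range(len(series))]
        )
        with pytest.raises(ImageIOError, match="does not match"):
            wrong.validate_against(series)


class TestSplit:
    @pytest.mark.parametrize(
        "n,expected",
        [(41979, (35683, 3148, 3148)), (23771, (20207, 1782, 1782)), (100, (86, 7, 7))],
    )
    def test_split_sizes(self, n, expected):
        assert eq.split_dataset(n, 0.15, seed=0).sizes == expected

    def test_partition_and_determinism(self):
        s1 = eq.split_dataset(523, 0.2, seed=9)
        s2 = eq.split_dataset(523, 0.2, seed=9)
        allidx = np.concatenate([s1.train_ids, s1.val_ids, s1.test_ids])
        assert sorted(allidx) == list(range(523))
        assert len(s1.val_ids) == len(s1.test_ids)
        for a, b in zip((s1.train_ids, s1.val_ids), (s2.train_ids, s2.val_ids)):
            assert np.array_equal(a, b)
        s3 = eq.split_dataset(523, 0.2, seed=10)
        assert not np.array_equal(s1.val_ids, s3.val_ids)

    def test_grouped_split_keeps_groups_together(self):
        groups = np.repeat(np.arange(40), 5)
        s = eq.split_dataset(200, 0.2, seed=1, groups=groups)
        val_groups = set(groups[s.val_ids])
        train_groups = set(groups[s.train_ids])
        assert val_groups.isdisjoint(train_groups)

    def test_too_small_holdout_rejected(self):
        with pytest.raises(ValueError):
            eq.split_dataset(5, 0.15)
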