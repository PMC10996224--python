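import numpy as np
import pandas as pd
import pytest

from calcinet.config import SyntheticCohortConfig
from calcinet.formats.dicom import VoiLut, write_dicom
from calcinet.formats.nrrd import write_nrrd
from calcinet.manifest import (
    EXCLUDED,
    CaseLabel,
    CohortManifest,
    ManifestError,
    assign_folds,
    read_image,
    read_manifest,
    read_mask,
    scenario_label,
    split_patient_level,
    write_manifest,
)
from calcinet.synthetic import generate_cohort


def synth_manifest(tmp_path, n, seed=0, size=128):
    return generate_cohort(
        SyntheticCohortConfig(n_patients=n, image_size=size, seed=seed), tmp_path
    )


def label_only_manifest(n_patients, grades, upstaged=None):
    """Manifest rows without materialized files (for partition logic)."""
    upstaged = upstaged or [False] * n_patients
    rows = []
    for i in range(n_patients):
        for view in ("CC", "MLO"):
            rows.append(
                dict(
                    patient_id=f"P{i:04d}",
                    image_path=f"img{i}_{view}.png",
                    mask_path=f"m{i}_{view}.png",
                    view=view,
                    laterality="L",
                    lesion_center_row=10,
                    lesion_center_col=10,
                    grade=grades[i],
                    upstaged=upstaged[i],
                    split="unassigned",
                    fold="unassigned",
                )
            )
    return CohortManifest(pd.DataFrame(rows))


def grades_like_table1(n):
    from calcinet.manifest import largest_remainder

    counts = largest_remainder((0.300, 0.416, 0.284), n)
    return ["I"] * counts[0] + ["II"] * counts[1] + ["III"] * counts[2]


class TestReadImage:
    def test_dicom_round_trip(self, tmp_path, rng):
        px = rng.integers(0, 65536, size=(32, 24)).astype(np.uint16)
        path = tmp_path / "img.dcm"
        write_dicom(path, px)
        sample = read_image(path)
        np.testing.assert_array_equal(sample.image, px)

    def test_monochrome1_inverted(self, tmp_path, rng):
        px = rng.integers(0, 65536, size=(16, 16)).astype(np.uint16)
        path = tmp_path / "img.dcm"
        write_dicom(path, px, photometric="MONOCHROME1")
        sample = read_image(path)
        manual_inversion = 65535 - px.astype(np.int64)  # independent oracle
        np.testing.assert_array_equal(sample.image, manual_inversion)

    def test_dicom_lut_family_parsed(self, tmp_path, rng):
        px = rng.integers(0, 4096, size=(8, 8)).astype(np.uint16)
        lut = VoiLut(0, np.linspace(0, 65535, 4096).astype(np.uint16))
        path = tmp_path / "img.dcm"
        write_dicom(path, px, luts=[lut])
        sample = read_image(path)
        assert len(sample.lut_family) == 1
        np.testing.assert_array_equal(sample.lut_family[0].table, lut.table)

    def test_png16_round_trip(self, tmp_path, rng):
        import imageio.v3 as iio

        px = rng.integers(0, 65536, size=(20, 30)).astype(np.uint16)
        path = tmp_path / "img.png"
        iio.imwrite(path, px)
        sample = read_image(path)
        assert sample.image.dtype == np.uint16
        np.testing.assert_array_equal(sample.image, px)

    def test_tiff_round_trip(self, tmp_path, rng):
        import tifffile

        px = rng.integers(0, 65536, size=(12, 15)).astype(np.uint16)
        path = tmp_path / "img.tif"
        tifffile.imwrite(path, px)
        np.testing.assert_array_equal(read_image(path).image, px)

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_image(tmp_path / "nope.png")

    def test_metadata_from_row(self, tmp_path, rng):
        import imageio.v3 as iio

        px = rng.integers(0, 65536, size=(20, 20)).astype(np.uint16)
        path = tmp_path / "img.png"
        iio.imwrite(path, px)
        row = dict(
            patient_id="P1", view="MLO", laterality="R",
            lesion_center_row=5, lesion_center_col=6,
        )
        sample = read_image(path, row=row)
        assert sample.view == "MLO"
        assert sample.lesion_center == (5, 6)


class TestReadMask:
    def test_png_binarization(self, tmp_path):
        import imageio.v3 as iio

        arr = np.array([[0, 255], [128, 0]], dtype=np.uint8)
        path = tmp_path / "m.png"
        iio.imwrite(path, arr)
        mask = read_mask(path)
        np.testing.assert_array_equal(mask.mask, [[0, 1], [1, 0]])

    def test_nrrd_png_cross_format_equality(self, tmp_path, rng):
        import imageio.v3 as iio

        m = (rng.random((16, 16)) > 0.5).astype(np.uint8)
        m[0, 0] = 1
        png = tmp_path / "m.png"
        nrrd = tmp_path / "m.nrrd"
        iio.imwrite(png, m * 255)
        write_nrrd(nrrd, m)
        np.testing.assert_array_equal(read_mask(png).mask, read_mask(nrrd).mask)

    def test_nrrd_singleton_axis_squeezed(self, tmp_path, rng):
        m = (rng.random((16, 16)) > 0.5).astype(np.uint8)
        m[3, 3] = 1
        path = tmp_path / "m.nrrd"
        write_nrrd(path, m[None, :, :])
        assert read_mask(path).mask.shape == (16, 16)

    def test_all_zero_annotated_rejected(self, tmp_path):
        import imageio.v3 as iio

        path = tmp_path / "m.png"
        iio.imwrite(path, np.zeros((8, 8), dtype=np.uint8))
        with pytest.raises(ManifestError, match="positive"):
            read_mask(path, annotated=True)
        assert read_mask(path, annotated=False).mask.sum() == 0

    def test_shape_mismatch_signaled(self, tmp_path):
        import imageio.v3 as iio

        path = tmp_path / "m.png"
        iio.imwrite(path, np.full((8, 8), 255, dtype=np.uint8))
        with pytest.raises(ManifestError, match="shape"):
            read_mask(path, image_shape=(10, 10))


class TestScenarioLabel:
    @pytest.mark.parametrize(
        "grade,upstaged,scenario,expected",
        [
            ("III", False, "pure", 1),
            ("II", True, "pure", EXCLUDED),
            ("I", True, "pure", EXCLUDED),
            ("I", False, "pure", 0),
            ("II", False, "pure", 0),
            ("I", False, "upstage", 0),
            ("II", True, "upstage", 1),
            ("III", False, "upstage", 1),
            ("III", True, "upstage", 1),
        ],
    )
    def test_label_table(self, grade, upstaged, scenario, expected):
        assert scenario_label(CaseLabel(grade, upstaged), scenario) == expected

    def test_unknown_scenario(self):
        with pytest.raises(ValueError):
            scenario_label(CaseLabel("I", False), "nope")

    def test_invalid_grade(self):
        with pytest.raises(ManifestError):
            CaseLabel("IV", False)


class TestSplit:
    def test_464_patients_gives_93_test(self):
        manifest = label_only_manifest(464, grades_like_table1(464))
        out = split_patient_level(manifest, 0.20, seed=0)
        pat = out.df.drop_duplicates("patient_id")
        assert int((pat["split"] == "test").sum()) == 93

    def test_zero_fraction_all_train(self):
        manifest = label_only_manifest(10, grades_like_table1(10))
        out = split_patient_level(manifest, 0.0, seed=0)
        assert set(out.df["split"]) == {"train"}

    def test_disjoint_patient_sets(self):
        manifest = label_only_manifest(50, grades_like_table1(50))
        out = split_patient_level(manifest, 0.20, seed=3)
        train = set(out.df.loc[out.df["split"] == "train", "patient_id"])
        test = set(out.df.loc[out.df["split"] == "test", "patient_id"])
        assert not (train & test)
        assert train | test == set(out.df["patient_id"])

    def test_stratified_within_one_patient(self):
        manifest = label_only_manifest(100, grades_like_table1(100))
        out = split_patient_level(manifest, 0.20, seed=1)
        pat = out.df.drop_duplicates("patient_id")
        for g in ("I", "II", "III"):
            sub = pat[pat["grade"] == g]
            expected = len(sub) * 0.20
            got = int((sub["split"] == "test").sum())
            assert abs(got - expected) < 1.0

    def test_deterministic(self):
        manifest = label_only_manifest(30, grades_like_table1(30))
        a = split_patient_level(manifest, 0.25, seed=9)
        b = split_patient_level(manifest, 0.25, seed=9)
        assert a.df.equals(b.df)

    def test_tiny_stratum_warns_and_trains(self):
        manifest = label_only_manifest(3, ["I", "I", "III"])
        with pytest.warns(UserWarning, match="stratum"):
            out = split_patient_level(manifest, 0.5, seed=0)
        pat = out.df.drop_duplicates("patient_id")
        assert (pat.loc[pat["grade"] == "III", "split"] == "train").all()

    def test_empty_rejected(self):
        with pytest.raises(ManifestError):
            split_patient_level(CohortManifest.empty(), 0.2, seed=0)


class TestFolds:
    def test_equal_partition_100_patients(self):
        manifest = label_only_manifest(100, grades_like_table1(100))
        out = split_patient_level(manifest, 0.0, seed=0)
        out = assign_folds(out, k=5, seed=0)
        pat = out.df.drop_duplicates("patient_id")
        sizes = pat["fold"].value_counts()
        assert sorted(sizes.index) == [1, 2, 3, 4, 5]
        assert all(sizes == 20)

    def test_union_disjoint_partition(self):
        manifest = label_only_manifest(23, grades_like_table1(23))
        out = assign_folds(split_patient_level(manifest, 0.0, seed=2), k=5, seed=2)
        pat = out.df.drop_duplicates("patient_id")
        assert set(pat["fold"]) <= {1, 2, 3, 4, 5}
        assert (pat["fold"] != "unassigned").all()
        sizes = pat["fold"].value_counts()
        assert sizes.max() - sizes.min() <= 1

    def test_per_stratum_balance(self):
        manifest = label_only_manifest(60, grades_like_table1(60))
        out = assign_folds(split_patient_level(manifest, 0.0, seed=5), k=5, seed=5)
        pat = out.df.drop_duplicates("patient_id")
        for g in ("I", "II", "III"):
            sizes = pat[pat["grade"] == g]["fold"].value_counts().reindex(
                range(1, 6), fill_value=0
            )
            assert sizes.max() - sizes.min() <= 1

    def test_deterministic(self):
        manifest = label_only_manifest(40, grades_like_table1(40))
        base = split_patient_level(manifest, 0.2, seed=4)
        a = assign_folds(base, k=5, seed=4)
        b = assign_folds(base, k=5, seed=4)
        assert a.df.equals(b.df)

    def test_fewer_patients_than_folds(self):
        manifest = label_only_manifest(3, ["I", "II", "III"])
        out = split_patient_level(manifest, 0.0, seed=0)
        with pytest.raises(ManifestError, match="fewer"):
            assign_folds(out, k=5, seed=0)

    def test_test_rows_not_folded(self):
        manifest = label_only_manifest(40, grades_like_table1(40))
        out = assign_folds(split_patient_level(manifest, 0.2, seed=4), k=5, seed=4)
        assert (out.df.loc[out.df["split"] == "test", "fold"] == "unassigned").all()


class TestManifestIO:
    def test_round_trip(self, tmp_path):
        manifest = label_only_manifest(8, grades_like_table1(8), upstaged=[True] * 2 + [False] * 6)
        manifest = split_patient_level(manifest, 0.25, seed=0)
        path = tmp_path / "manifest.csv"
        write_manifest(manifest, path)
        loaded = read_manifest(path)
        assert loaded.df.equals(manifest.df)

    def test_round_trip_with_folds(self, tmp_path):
        manifest = label_only_manifest(10, grades_like_table1(10))
        manifest = assign_folds(split_patient_level(manifest, 0.0, seed=0), k=2, seed=0)
        path = tmp_path / "manifest.csv"
        write_manifest(manifest, path)
        assert read_manifest(path).df.equals(manifest.df)

    def test_empty_round_trip(self, tmp_path):
        path = tmp_path / "manifest.csv"
        write_manifest(CohortManifest.empty(), path)
        assert len(read_manifest(path)) == 0

    def test_duplicate_patient_across_splits_rejected(self, tmp_path):
        manifest = label_only_manifest(4, grades_like_table1(4))
        df = manifest.df.copy()
        df["split"] = ["train", "test"] * 4  # same patient in both splits
        path = tmp_path / "manifest.csv"
        with open(path, "w") as fh:
            fh.write("# calcinet-manifest v1\n")
            df.to_csv(fh, index=False)
        with pytest.raises(ManifestError, match="more than one split"):
            read_manifest(path)

    def test_missing_columns_rejected(self, tmp_path):
        path = tmp_path / "manifest.csv"
        with open(path, "w") as fh:
            fh.write("# calcinet-manifest v1\n")
            fh.write("patient_id,grade\np1,I\n")
        with pytest.raises(ManifestError, match="columns"):
            read_manifest(path)

    def test_missing_version_header_rejected(self, tmp_path):
        path = tmp_path / "manifest.csv"
        path.write_text("patient_id\np1\n")
        with pytest.raises(ManifestError, match="version"):
            read_manifest(path)

    def test_real_cohort_round_trip(self, tmp_path, small_cohort):
        _, manifest = small_cohort
        path = tmp_path / "manifest.csv"
        write_manifest(manifest, path)
        assert read_manifest(path).df.equals(manifest.df)
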