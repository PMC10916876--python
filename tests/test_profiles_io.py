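import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import biomorph as bm
from biomorph.profiles_io import (
    TableFormatError,
    TableValidationError,
    write_metadata,
)


class TestLoadTable:
    def test_csv_roundtrip(self, toy_profiles, tmp_path):
        path = tmp_path / "t.csv"
        bm.write_table(toy_profiles, path)
        back = bm.load_table(path, schema="profiles")
        pd.testing.assert_frame_equal(back.data, toy_profiles.data)

    def test_parquet_roundtrip_bit_exact(self, rng, tmp_path):
        df = pd.DataFrame(
            rng.normal(size=(5, 3)), index=[f"r{i}" for i in range(5)],
            columns=["a", "b", "c"],
        )
        table = bm.MorphProfileTable(df)
        path = tmp_path / "t.parquet"
        bm.write_table(table, path)
        back = bm.load_table(path)
        assert (back.data.to_numpy() == table.data.to_numpy()).all()

    def test_missing_header_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("1,2\n3,4\n")
        with pytest.raises(TableFormatError, match="row_id"):
            bm.load_table(path)

    def test_duplicate_row_id_rejected(self, tmp_path):
        path = tmp_path / "dup.csv"
        path.write_text("row_id,f1\nr1,1\nr1,2\n")
        with pytest.raises(TableValidationError, match="duplicate row_id"):
            bm.load_table(path)

    def test_duplicate_feature_rejected(self):
        df = pd.DataFrame([[1.0, 2.0]], index=["r1"], columns=["f", "f"])
        with pytest.raises(TableValidationError, match="duplicate column"):
            bm.MorphProfileTable(df)

    def test_nan_policy_error_vs_drop(self, tmp_path):
        path = tmp_path / "nan.csv"
        path.write_text("row_id,f1\nr1,1.0\nr2,\n")
        with pytest.raises(TableValidationError, match="non-finite"):
            bm.load_table(path)
        kept = bm.load_table(path, nan_policy="drop")
        assert kept.row_ids == ["r1"]

    def test_non_numeric_rejected(self, tmp_path):
        path = tmp_path / "txt.csv"
        path.write_text("row_id,f1\nr1,abc\n")
        with pytest.raises(TableValidationError, match="non-numeric"):
            bm.load_table(path)


class TestPlateControlSubtraction:
    def test_constant_control_shifts_rows(self):
        df = pd.DataFrame(
            {"f": [5.0, 5.0, 8.0]}, index=["c1", "c2", "x1"]
        )
        out = bm.subtract_plate_control(
            bm.MorphProfileTable(df), ["p1"] * 3, [True, True, False]
        )
        assert out.data.loc["x1", "f"] == pytest.approx(3.0)
        assert out.data.loc["c1", "f"] == pytest.approx(0.0)

    def test_two_plates_corrected_independently(self):
        # hand computation: plate p1 control mean = 2, plate p2 control mean = 10
        df = pd.DataFrame(
            {"f": [2.0, 5.0, 10.0, 7.0]}, index=["c1", "x1", "c2", "x2"]
        )
        out = bm.subtract_plate_control(
            bm.MorphProfileTable(df),
            ["p1", "p1", "p2", "p2"],
            [True, False, True, False],
        )
        assert out.data["f"].tolist() == pytest.approx([0.0, 3.0, 0.0, -3.0])

    def test_all_control_plate_centers_to_zero(self, rng):
        df = pd.DataFrame(
            rng.normal(size=(6, 3)), index=[f"c{i}" for i in range(6)],
            columns=list("abc"),
        )
        out = bm.subtract_plate_control(
            bm.MorphProfileTable(df), ["p"] * 6, [True] * 6
        )
        assert np.allclose(out.data.mean(axis=0), 0.0, atol=1e-12)

    def test_plate_without_controls_errors(self, toy_profiles):
        with pytest.raises(ValueError, match="p9"):
            bm.subtract_plate_control(
                toy_profiles, ["p9"] * 3, [False, False, False]
            )

    def test_idempotent_on_centered_plates(self, rng):
        df = pd.DataFrame(
            rng.normal(size=(8, 4)), index=[f"r{i}" for i in range(8)],
            columns=list("abcd"),
        )
        plates = ["p1"] * 4 + ["p2"] * 4
        mask = [True, True, False, False] * 2
        once = bm.subtract_plate_control(bm.MorphProfileTable(df), plates, mask)
        twice = bm.subtract_plate_control(once, plates, mask)
        assert np.allclose(once.values, twice.values, atol=1e-10)


class TestConsensusByCompound:
    def _series(self, cid, doses, values=None, n_feat=2):
        doses = np.asarray(doses, dtype=float)
        if values is None:
            values = np.tile(doses[:, None], (1, n_feat))
        return bm.DoseSeries(cid, doses, values, [f"f{i}" for i in range(n_feat)])

    def test_singleton_returned_unchanged(self):
        out = bm.consensus_by_compound([self._series("c1", [2.0])])
        assert out.data.loc["c1"].tolist() == [2.0, 2.0]

    def test_outlier_dose_excluded(self):
        # doses {1,2,3,4,50}: mean 12, sample SD ~21.27; 50 deviates by 38 -> out
        out = bm.consensus_by_compound([self._series("c1", [1, 2, 3, 4, 50])])
        assert out.data.loc["c1", "f0"] == pytest.approx(np.median([1, 2, 3, 4]))

    def test_extreme_outlier_excluded_under_one_sd_rule(self):
        # doses {1,1,1,100}: mean 25.75, sample SD 49.5; |100-25.75| = 74.25 > SD
        # so only the three dose-1 wells are retained
        vals = np.array([[1.0], [2.0], [3.0], [99.0]])
        s = bm.DoseSeries("c1", [1, 1, 1, 100], vals, ["f0"])
        out = bm.consensus_by_compound([s])
        assert out.data.loc["c1", "f0"] == pytest.approx(2.0)

    def test_two_doses_both_retained(self):
        out = bm.consensus_by_compound([self._series("c1", [1.0, 9.0])])
        assert out.data.loc["c1", "f0"] == pytest.approx(5.0)

    @given(st.permutations(list(range(5))))
    def test_permutation_invariant(self, order):
        doses = np.array([1.0, 2.0, 3.0, 4.0, 50.0])
        vals = np.array([[1.0], [4.0], [9.0], [16.0], [500.0]])
        base = bm.consensus_by_compound(
            [bm.DoseSeries("c", doses, vals, ["f0"])]
        )
        perm = bm.consensus_by_compound(
            [bm.DoseSeries("c", doses[order], vals[order], ["f0"])]
        )
        assert base.data.equals(perm.data)

    def test_empty_series_errors(self):
        with pytest.raises(TableValidationError, match="empty"):
            bm.DoseSeries("c", [], np.empty((0, 1)), ["f0"])

    def test_nonpositive_dose_errors(self):
        with pytest.raises(TableValidationError, match="dose"):
            bm.DoseSeries("c", [0.0], np.array([[1.0]]), ["f0"])


class TestStandardizeFeatures:
    def test_known_column(self):
        df = pd.DataFrame({"f": [1.0, 2.0, 3.0]}, index=list("abc"))
        out = bm.standardize_features(bm.MorphProfileTable(df))
        expected = np.sqrt(1.5)  # population sigma of (1,2,3) = sqrt(2/3)
        assert out.data["f"].tolist() == pytest.approx([-expected, 0.0, expected])

    def test_constant_column_zeroed_with_warning(self, toy_profiles):
        with pytest.warns(UserWarning, match="zero-variance"):
            out = bm.standardize_features(toy_profiles)
        assert (out.data["f_b"] == 0).all()

    def test_columns_centered_and_unit_variance(self, rng):
        df = pd.DataFrame(
            rng.normal(3, 5, size=(50, 4)), index=[f"r{i}" for i in range(50)],
            columns=list("abcd"),
        )
        out = bm.standardize_features(bm.MorphProfileTable(df))
        assert np.all(np.abs(out.data.mean(axis=0)) < 1e-12)
        assert np.allclose(out.data.std(axis=0, ddof=0), 1.0)

    def test_idempotent(self, rng):
        df = pd.DataFrame(
            rng.normal(size=(20, 3)), index=[f"r{i}" for i in range(20)],
            columns=list("abc"),
        )
        once = bm.standardize_features(bm.MorphProfileTable(df))
        twice = bm.standardize_features(once)
        assert np.allclose(once.values, twice.values, atol=1e-10)

    def test_reference_population_scaling(self, rng):
        ref_df = pd.DataFrame(
            rng.normal(10, 2, size=(100, 2)), index=[f"r{i}" for i in range(100)],
            columns=["a", "b"],
        )
        ref = bm.MorphProfileTable(ref_df)
        new = bm.MorphProfileTable(
            pd.DataFrame({"a": [10.0], "b": [10.0]}, index=["x"])
        )
        out = bm.standardize_features(new, reference=ref)
        mu, sd = ref_df.mean(), ref_df.std(ddof=0)
        assert out.data.loc["x", "a"] == pytest.approx((10 - mu["a"]) / sd["a"])


class TestIntersectFeatures:
    def test_sorted_intersection(self):
        assert bm.intersect_features(["f3", "f2", "f1"], ["f2", "f4", "f3"]) == ["f2", "f3"]

    def test_disjoint_errors(self):
        with pytest.raises(ValueError, match="disjoint"):
            bm.intersect_features(["a"], ["b"])

    def test_self_intersection_is_sorted_identity(self):
        assert bm.intersect_features(["b", "a"], ["a", "b"]) == ["a", "b"]


class TestMetadata:
    def test_roundtrip_and_masks(self, tmp_path):
        df = pd.DataFrame(
            {
                "row_id": ["r1", "r2"],
                "perturbation_id": ["p1", "p2"],
                "cell_line": ["A549", "ES2"],
                "group_label": ["negative_control", "DNA Damage"],
                "is_negative_control": [True, False],
            }
        )
        meta = bm.PerturbationMeta(df)
        path = tmp_path / "meta.csv"
        write_metadata(meta, path)
        back = bm.load_metadata(path)
        assert back.control_mask(["r1", "r2"]).tolist() == [True, False]
        assert back.group_labels(["r2"]).tolist() == ["DNA Damage"]
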