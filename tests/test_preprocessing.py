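"""Observation-window filtering, encoding, coverage, outliers, imputation."""

import numpy as np
import pandas as pd
import pytest

from oncosep.preprocessing import (
    PreprocessingError,
    RobustOutlierTrimmer,
    StratifiedMeanImputer,
    age_bin,
    build_feature_table,
    filter_lab_coverage,
    filter_observation_window,
    impute_missing,
    remove_outliers,
    standardize_diagnosis_code,
)

ER = pd.Timestamp("2021-03-10 09:00:00")


def _events_at(day_offsets):
    return pd.DataFrame(
        {"timestamp": [ER + pd.Timedelta(days=d) for d in day_offsets], "x": day_offsets}
    )


class TestObservationWindow:
    @pytest.mark.parametrize(
        "offset,kept",
        [(-1, False), (-2, True), (-3, True), (-7, True), (-8, False), (0, False), (-7.5, False)],
    )
    def test_window_boundaries(self, offset, kept):
        out = filter_observation_window(_events_at([offset]), ER)
        assert (len(out) == 1) == kept

    def test_mixed_events_filtered(self):
        out = filter_observation_window(_events_at([-1, -3, -8]), ER)
        assert out["x"].tolist() == [-3]


class TestDiagnosisCode:
    @pytest.mark.parametrize(
        "raw,expected",
        [("C22.0", "C22"), ("c34", "C34"), ("C509", "C50"), ("c50.91", "C50")],
    )
    def test_standardization(self, raw, expected):
        assert standardize_diagnosis_code(raw) == expected

    @pytest.mark.parametrize("bad", ["", "C2", "C."])
    def test_invalid_codes_rejected(self, bad):
        with pytest.raises(PreprocessingError):
            standardize_diagnosis_code(bad)


class TestLabCoverage:
    def _labs(self, n_with, lab="alb"):
        return pd.DataFrame(
            {"patient_id": [f"p{i}" for i in range(n_with)], "lab_type": lab, "value": 1.0}
        )

    def _patients(self, n=100):
        return pd.DataFrame({"patient_id": [f"p{i}" for i in range(n)]})

    @pytest.mark.parametrize("n_with,kept", [(55, False), (60, False), (61, True)])
    def test_strict_60_percent_threshold(self, n_with, kept):
        out = filter_lab_coverage(self._labs(n_with), self._patients(), 0.6)
        assert (out == ["alb"]) == kept

    def test_monotone_in_threshold(self):
        labs = pd.concat([self._labs(61, "a"), self._labs(80, "b")])
        patients = self._patients()
        lo = filter_lab_coverage(labs, patients, 0.5)
        hi = filter_lab_coverage(labs, patients, 0.7)
        assert set(hi).issubset(set(lo))

    def test_empty_patients_rejected(self):
        with pytest.raises(PreprocessingError):
            filter_lab_coverage(self._labs(5), self._patients(0))


class TestOutliers:
    def test_extreme_value_removed(self):
        out = remove_outliers([1.0, 1.0, 1.0, 1.0, 1000.0], k=5)
        assert np.isnan(out[-1])
        assert np.isfinite(out[:-1]).all()

    def test_constant_feature_untouched(self):
        out = remove_outliers([3.0] * 6, k=5)
        assert np.isfinite(out).all()

    def test_tight_values_untouched(self):
        vals = [1.0, 1.1, 0.9, 1.05, 0.95]
        assert np.isfinite(remove_outliers(vals, k=5)).all()

    def test_transformer_marks_then_imputer_fills(self):
        df = pd.DataFrame(
            {
                "cancer_type": ["lung"] * 5,
                "sex": ["M"] * 5,
                "age_bin": ["55-60"] * 5,
                "v": [1.0, 1.0, 1.0, 1.0, 1000.0],
            }
        )
        trimmed = RobustOutlierTrimmer(k=5, columns=["v"]).fit_transform(df)
        assert trimmed["v"].isna().sum() == 1
        filled = StratifiedMeanImputer(columns=["v"]).fit_transform(trimmed)
        assert filled["v"].notna().all()
        assert filled.loc[4, "v"] == 1.0


class TestImputation:
    def _table(self):
        return pd.DataFrame(
            {
                "cancer_type": ["lung", "lung", "lung", "breast"],
                "sex": ["M", "M", "M", "F"],
                "age_bin": ["55-60", "55-60", "55-60", "40-45"],
                "alb": [3.0, 5.0, np.nan, 2.0],
            }
        )

    def test_stratum_mean_imputed(self):
        out = impute_missing(self._table(), columns=["alb"])
        assert out.loc[2, "alb"] == 4.0

    def test_no_missing_is_identity(self):
        t = self._table().dropna()
        pd.testing.assert_frame_equal(impute_missing(t, columns=["alb"]), t)

    def test_singleton_stratum_falls_back(self):
        t = pd.DataFrame(
            {
                "cancer_type": ["lung", "lung", "lung"],
                "sex": ["F", "F", "F"],
                "age_bin": ["40-45", "55-60", "55-60"],
                "alb": [np.nan, 4.0, 6.0],
            }
        )
        out = impute_missing(t, columns=["alb"])
        # empty (lung, F, 40-45) stratum -> (lung, F) mean
        assert out.loc[0, "alb"] == 5.0

    def test_all_missing_feature_rejected(self):
        t = self._table()
        t["alb"] = np.nan
        with pytest.raises(PreprocessingError):
            impute_missing(t, columns=["alb"])

    def test_age_bins_are_five_years(self):
        assert age_bin(58.9) == "55-60"
        assert age_bin(60.0) == "60-65"


class TestFeatureTable:
    def test_build_produces_complete_matrix(self, small_events, small_labels):
        ft = build_feature_table(small_events, small_labels)
        assert not ft.X.isna().any().any()
        assert [m["name"] for m in ft.manifest] == list(ft.X.columns)
        assert set(ft.y.unique()) <= {0, 1}
        # one-hot encodings are 0/1
        for m in ft.manifest:
            if m["encoding"] in ("binary", "onehot"):
                assert set(ft.X[m["name"]].unique()) <= {0, 1}

    def test_row_order_invariance(self, small_events, small_labels):
        ft1 = build_feature_table(small_events, small_labels)
        shuffled = small_labels.sample(frac=1.0, random_state=5).reset_index(drop=True)
        ft2 = build_feature_table(small_events, shuffled)
        a = pd.concat([ft1.index, ft1.X], axis=1).sort_values("visit_id").reset_index(drop=True)
        b = pd.concat([ft2.index, ft2.X], axis=1).sort_values("visit_id").reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b[a.columns])

    def test_imputation_preserves_row_count(self, small_events, small_labels):
        ft = build_feature_table(small_events, small_labels)
        ft2 = build_feature_table(small_events, small_labels, outlier_k=3.0)
        assert len(ft.X) == len(ft2.X)

    def test_excluded_labs_dropped(self, small_events, small_labels):
        ft = build_feature_table(small_events, small_labels, excluded_labs=["albumin"])
        assert "lab_albumin" not in ft.X.columns
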