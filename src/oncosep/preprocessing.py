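"""Filtering, encoding and imputation rules producing a model-ready table.

Predictive features for a visit are drawn exclusively from the observation
window 2-7 days *before* the ER visit (prediction in advance, not detection).
Diagnosis codes are truncated to their 3-character category; lab tests kept
only when measured in more than 60% of patients; extreme values removed by a
robust z-score rule; missing values imputed by the mean of patients with the
same cancer type, sex and (binned) age, with a fallback cascade for empty
strata; categoricals one-hot encoded.

The imputer and outlier trimmer are sklearn-compatible transformers so they
can also sit inside model-selection pipelines.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

WINDOW_DAYS = (2.0, 7.0)  # days before the ER visit, inclusive on both ends
LAB_COVERAGE_MIN = 0.6
OUTLIER_K = 5.0
AGE_BIN_YEARS = 5.0


class PreprocessingError(ValueError):
    pass


# ---------------------------------------------------------------------------
# elementary rules
# ---------------------------------------------------------------------------

def filter_observation_window(
    events: pd.DataFrame,
    er_visit_time: pd.Timestamp,
    time_column: str = "timestamp",
    window_days: tuple[float, float] = WINDOW_DAYS,
) -> pd.DataFrame:
    """Keep events with timestamp in [visit - 7 d, visit - 2 d] (inclusive)."""
    near, far = window_days
    t = pd.to_datetime(events[time_column])
    lo = er_visit_time - pd.Timedelta(days=far)
    hi = er_visit_time - pd.Timedelta(days=near)
    return events[(t >= lo) & (t <= hi)]


def standardize_diagnosis_code(code: str) -> str:
    """Truncate a diagnosis code to its 3-character category (e.g. C22.0 -> C22)."""
    if not code:
        raise PreprocessingError("empty diagnosis code")
    cleaned = re.sub(r"[^0-9A-Za-z]", "", str(code)).upper()
    if len(cleaned) < 3:
        raise PreprocessingError(f"diagnosis code too short: {code!r}")
    return cleaned[:3]


def filter_lab_coverage(
    labs: pd.DataFrame,
    patients: pd.DataFrame,
    min_fraction: float = LAB_COVERAGE_MIN,
) -> list[str]:
    """Lab types measured in strictly more than ``min_fraction`` of patients."""
    if not 0.0 < min_fraction <= 1.0:
        raise PreprocessingError("min_fraction must be in (0, 1]")
    n_patients = patients["patient_id"].nunique()
    if n_patients == 0:
        raise PreprocessingError("empty patient set")
    cov = labs.groupby("lab_type")["patient_id"].nunique() / n_patients
    return sorted(cov.index[cov > min_fraction])


# ---------------------------------------------------------------------------
# sklearn-style transformers
# ---------------------------------------------------------------------------

class RobustOutlierTrimmer(BaseEstimator, TransformerMixin):
    """Mark extreme entries missing by a robust z-score on median/MAD.

    An entry is extreme when |x - median| > k * (1.4826 * MAD).  With zero
    MAD the robust z-score is infinite, so any deviation from the median is
    extreme (a constant feature is never trimmed: its deviation is 0).
    Trimmed entries become NaN and are left to the imputer.
    """

    def __init__(self, k: float = OUTLIER_K, columns: list[str] | None = None):
        self.k = k
        self.columns = columns

    def fit(self, X: pd.DataFrame, y=None):
        cols = self.columns or [c for c in X.columns if pd.api.types.is_numeric_dtype(X[c])]
        self.columns_ = list(cols)
        self.median_ = X[self.columns_].median()
        mad = (X[self.columns_] - self.median_).abs().median()
        self.scale_ = 1.4826 * mad
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        check_is_fitted(self, "scale_")
        X = X.copy()
        for c in self.columns_:
            extreme = (X[c] - self.median_[c]).abs() > self.k * self.scale_[c]
            X.loc[extreme, c] = np.nan
        return X


class StratifiedMeanImputer(BaseEstimator, TransformerMixin):
    """Impute by the mean of same-cancer, same-sex, same-age-bin patients.

    Fallback cascade when a stratum has no observed values: drop age, then
    sex, then the global feature mean.  Requires the stratification columns
    in the frame at fit and transform time.
    """

    def __init__(
        self,
        strata: tuple[str, ...] = ("cancer_type", "sex", "age_bin"),
        columns: list[str] | None = None,
    ):
        self.strata = strata
        self.columns = columns

    def _cascades(self):
        s = list(self.strata)
        return [tuple(s[: len(s) - i]) for i in range(len(s))] + [()]

    def fit(self, X: pd.DataFrame, y=None):
        cols = self.columns or [
            c
            for c in X.columns
            if c not in self.strata and pd.api.types.is_numeric_dtype(X[c])
        ]
        self.columns_ = list(cols)
        for c in self.columns_:
            if X[c].isna().all():
                raise PreprocessingError(f"feature {c!r} missing in all rows")
        self.means_ = {}
        for keys in self._cascades():
            if keys:
                self.means_[keys] = X.groupby(list(keys), observed=True)[self.columns_].mean()
            else:
                self.means_[keys] = X[self.columns_].mean()
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        check_is_fitted(self, "means_")
        X = X.copy()
        for c in self.columns_:
            na = X.index[X[c].isna()]
            for idx in na:
                X.loc[idx, c] = self._lookup(X.loc[idx], c)
        return X

    def _lookup(self, row: pd.Series, column: str) -> float:
        for keys in self._cascades():
            if not keys:
                return float(self.means_[()][column])
            table = self.means_[keys]
            key = tuple(row[k] for k in keys)
            key = key[0] if len(key) == 1 else key
            try:
                v = table.loc[key, column]
            except KeyError:
                continue
            if not pd.isna(v):
                return float(v)
        return float(self.means_[()][column])


def remove_outliers(values, k: float = OUTLIER_K) -> np.ndarray:
    """Robust z-score trim on one feature: extreme entries become NaN."""
    arr = np.asarray(values, dtype=float)
    med = np.nanmedian(arr)
    scale = 1.4826 * np.nanmedian(np.abs(arr - med))
    out = arr.copy()
    out[np.abs(arr - med) > k * scale] = np.nan
    return out


def impute_missing(
    table: pd.DataFrame,
    columns: list[str] | None = None,
    strata: tuple[str, ...] = ("cancer_type", "sex", "age_bin"),
) -> pd.DataFrame:
    """Functional wrapper over :class:`StratifiedMeanImputer` (fit+transform)."""
    return StratifiedMeanImputer(strata=strata, columns=columns).fit_transform(table)


def age_bin(age: float, width: float = AGE_BIN_YEARS) -> str:
    lo = int(np.floor(age / width) * width)
    return f"{lo}-{lo + int(width)}"


# ---------------------------------------------------------------------------
# feature-table assembly
# ---------------------------------------------------------------------------

@dataclass
class FeatureTable:
    """Model-ready matrix: one row per retained ER visit.

    ``manifest`` records (name, source_stage, encoding) per column;
    ``y`` carries the visit label (1 = sepsis) aligned with ``X``.
    """

    X: pd.DataFrame
    y: pd.Series
    manifest: list[dict] = field(default_factory=list)
    index: pd.DataFrame | None = None  # (patient_id, visit_id) per row

    def __post_init__(self):
        names = [m["name"] for m in self.manifest]
        assert names == list(self.X.columns), "manifest out of sync with columns"
        assert not self.X.isna().any().any(), "missing values after imputation"

    def columns_from(self, stage: str) -> list[str]:
        return [m["name"] for m in self.manifest if m["source_stage"] == stage]

    def write(self, path: str, manifest_path: str | None = None) -> None:
        out = pd.concat([self.index, self.X], axis=1) if self.index is not None else self.X
        out = out.assign(group_label=self.y.values)
        out.to_csv(path, index=False)
        if manifest_path:
            with open(manifest_path, "w", encoding="utf-8") as fh:
                json.dump(self.manifest, fh, indent=1)


def build_feature_table(
    events,
    labels: pd.DataFrame,
    lab_coverage_min: float = LAB_COVERAGE_MIN,
    outlier_k: float = OUTLIER_K,
    excluded_labs: list[str] | None = None,
    window_days: tuple[float, float] = WINDOW_DAYS,
) -> FeatureTable:
    """Assemble the per-visit feature table from an event table and labels.

    Stages: window-filter labs per visit; drop visits with no in-window
    events; coverage-filter lab types (strict > ``lab_coverage_min``), minus
    any user-supplied leakage exclusion list; average repeated in-window
    measurements; trim outliers; impute by (cancer, sex, age-bin) means;
    one-hot encode sex, cancer type and the 3-character diagnosis code.
    """
    excluded = set(excluded_labs or [])
    visits = events.visits.merge(events.patients, on="patient_id")
    visits = visits.merge(labels[["visit_id", "label"]], on="visit_id")

    # per-visit window-filtered lab events
    lab_parts = []
    labs_by_visit = dict(tuple(events.labs.groupby("visit_id", sort=False)))
    rx_by_visit = dict(tuple(events.prescriptions.groupby("visit_id", sort=False)))
    keep_rows = []
    for _, v in visits.iterrows():
        vl = labs_by_visit.get(v["visit_id"])
        in_window = (
            filter_observation_window(vl, v["er_visit_time"], window_days=window_days)
            if vl is not None
            else None
        )
        rx = rx_by_visit.get(v["visit_id"])
        rx_in = (
            filter_observation_window(
                rx, v["er_visit_time"], time_column="timestamp", window_days=window_days
            )
            if rx is not None
            else None
        )
        has_events = (in_window is not None and len(in_window)) or (
            rx_in is not None and len(rx_in)
        )
        if not has_events:
            continue  # visit has no usable pre-visit information
        keep_rows.append(v)
        if in_window is not None and len(in_window):
            lab_parts.append(in_window)
    if not keep_rows:
        raise PreprocessingError("no visits with in-window events")
    visits = pd.DataFrame(keep_rows).reset_index(drop=True)
    window_labs = (
        pd.concat(lab_parts, ignore_index=True)
        if lab_parts
        else events.labs.iloc[0:0]
    )
    window_labs = window_labs[~window_labs["lab_type"].isin(excluded)]

    kept_labs = (
        filter_lab_coverage(window_labs, events.patients, lab_coverage_min)
        if len(window_labs)
        else []
    )
    lab_wide = (
        window_labs[window_labs["lab_type"].isin(kept_labs)]
        .groupby(["visit_id", "lab_type"])["value"]
        .mean()
        .unstack()
        .reindex(columns=kept_labs)
    )

    table = visits.set_index("visit_id")
    table = table.join(lab_wide)
    table["age_bin"] = table["age"].map(age_bin)
    table["dx3"] = table["diagnosis_code"].map(standardize_diagnosis_code)

    if kept_labs:
        trimmed = RobustOutlierTrimmer(k=outlier_k, columns=kept_labs).fit_transform(
            table
        )
        table[kept_labs] = StratifiedMeanImputer(columns=kept_labs).fit_transform(
            trimmed
        )[kept_labs]

    manifest: list[dict] = []
    X = pd.DataFrame(index=table.index)

    X["sex_male"] = (table["sex"] == "M").astype(int)
    manifest.append({"name": "sex_male", "source_stage": "ehr", "encoding": "binary"})
    for col in ("age", "weight"):
        X[col] = table[col].astype(float)
        manifest.append({"name": col, "source_stage": "ehr", "encoding": "numeric"})
    for col, prefix in (("cancer_type", "cancer"), ("dx3", "dx")):
        for value in sorted(table[col].unique()):
            name = f"{prefix}_{value}"
            X[name] = (table[col] == value).astype(int)
            manifest.append({"name": name, "source_stage": "ehr", "encoding": "onehot"})
    for lab in kept_labs:
        X[f"lab_{lab}"] = table[lab].astype(float)
        manifest.append({"name": f"lab_{lab}", "source_stage": "lab", "encoding": "numeric"})

    y = (table["label"] == "sepsis").astype(int)
    y.name = "group_label"
    index = table.reset_index()[["patient_id", "visit_id"]]
    return FeatureTable(
        X=X.reset_index(drop=True),
        y=y.reset_index(drop=True),
        manifest=manifest,
        index=index,
    )
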