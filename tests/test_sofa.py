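"""SOFA scoring and Sepsis-3 visit labeling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from oncosep.sofa import (
    InfectionWindow,
    MeasurementError,
    compute_sofa_score,
    find_infection_windows,
    label_cohort,
    label_visit,
    sofa_series,
)

T0 = pd.Timestamp("2020-01-10 12:00:00")


def hours(h):
    return pd.Timedelta(hours=h)


# Independent encoding of the standard six-system threshold table, written
# directly from the clinical definition (not loaded from the package data).
SOFA_FIXTURE = [
    # (measurements, expected subscore dict)
    ({"pao2_fio2": 450}, {"respiration": 0}),
    ({"pao2_fio2": 350}, {"respiration": 1}),
    ({"pao2_fio2": 250}, {"respiration": 2}),
    ({"pao2_fio2": 150}, {"respiration": 3}),
    ({"pao2_fio2": 80}, {"respiration": 4}),
    ({"platelets": 250}, {"coagulation": 0}),
    ({"platelets": 120}, {"coagulation": 1}),
    ({"platelets": 90}, {"coagulation": 2}),
    ({"platelets": 40}, {"coagulation": 3}),
    ({"platelets": 10}, {"coagulation": 4}),
    ({"bilirubin": 0.5}, {"liver": 0}),
    ({"bilirubin": 1.5}, {"liver": 1}),
    ({"bilirubin": 3.0}, {"liver": 2}),
    ({"bilirubin": 8.0}, {"liver": 3}),
    ({"bilirubin": 14.0}, {"liver": 4}),
    ({"map": 80}, {"cardiovascular": 0}),
    ({"map": 65}, {"cardiovascular": 1}),
    ({"map": 80, "vasopressor": 1}, {"cardiovascular": 2}),
    ({"gcs": 15}, {"cns": 0}),
    ({"gcs": 14}, {"cns": 1}),
    ({"gcs": 11}, {"cns": 2}),
    ({"gcs": 7}, {"cns": 3}),
    ({"gcs": 4}, {"cns": 4}),
    ({"creatinine": 0.9}, {"renal": 0}),
    ({"creatinine": 1.5}, {"renal": 1}),
    ({"creatinine": 2.5}, {"renal": 2}),
    ({"creatinine": 4.0}, {"renal": 3}),
    ({"creatinine": 6.0}, {"renal": 4}),
]


class TestComputeSofa:
    @pytest.mark.parametrize("measurements,expected", SOFA_FIXTURE)
    def test_threshold_table(self, measurements, expected):
        a = compute_sofa_score(measurements)
        for system, score in expected.items():
            assert a.subscores[system] == score
        assert a.total == sum(expected.values())

    def test_all_missing_scores_zero_and_flags(self):
        a = compute_sofa_score({})
        assert a.total == 0
        assert len(a.components_missing) == 6

    def test_all_normal_physiology_totals_zero(self):
        a = compute_sofa_score(
            {
                "platelets": 250,
                "bilirubin": 0.5,
                "map": 80,
                "gcs": 15,
                "creatinine": 0.8,
                "pao2_fio2": 450,
            }
        )
        assert a.total == 0
        assert not a.components_missing

    def test_isolated_thrombocytopenia_scores_two(self):
        a = compute_sofa_score(
            {
                "platelets": 90,
                "bilirubin": 0.5,
                "map": 80,
                "gcs": 15,
                "creatinine": 0.8,
                "pao2_fio2": 450,
            }
        )
        assert a.total == 2
        assert a.subscores["coagulation"] == 2

    def test_negative_measurement_rejected(self):
        with pytest.raises(MeasurementError):
            compute_sofa_score({"platelets": -5})

    def test_total_equals_sum_of_subscores(self):
        a = compute_sofa_score({"platelets": 40, "creatinine": 2.5, "gcs": 11})
        assert a.total == sum(a.subscores.values())
        assert a.components_missing == {"respiration", "liver", "cardiovascular"}


class TestInfectionWindows:
    def _frames(self, abx_offset_h, route="IV", drug="cephalosporin_iv"):
        cultures = pd.DataFrame({"patient_id": ["p1"], "timestamp": [T0]})
        rx = pd.DataFrame(
            {
                "patient_id": ["p1"],
                "timestamp": [T0 + hours(abx_offset_h)],
                "drug_id": [drug],
                "route": [route],
            }
        )
        return cultures, rx

    def test_iv_antibiotic_inside_window(self):
        w = find_infection_windows(*self._frames(10))
        assert len(w) == 1
        assert w[0].window_start == T0 - hours(24)
        assert w[0].window_end == T0 + hours(24)

    def test_antibiotic_outside_window(self):
        assert find_infection_windows(*self._frames(30)) == []

    def test_boundary_exactly_24h_is_inclusive(self):
        assert len(find_infection_windows(*self._frames(24))) == 1

    def test_oral_route_ignored(self):
        assert find_infection_windows(*self._frames(1, route="PO")) == []

    def test_route_case_insensitive(self):
        assert len(find_infection_windows(*self._frames(1, route="iv"))) == 1

    def test_non_antibiotic_drug_filtered(self):
        cultures, rx = self._frames(1, drug="saline_solution")
        assert find_infection_windows(cultures, rx, antibiotic_ids=["cephalosporin_iv"]) == []


def _series(points):
    """Build a SOFA series with prescribed totals via the renal+coag channels."""
    out = []
    for ts, total in points:
        meas = {}
        # encode any total 0..8 using two components scored 0..4 each
        a, b = min(total, 4), max(total - 4, 0)
        meas["platelets"] = {0: 250, 1: 140, 2: 90, 3: 40, 4: 10}[a]
        meas["creatinine"] = {0: 0.8, 1: 1.5, 2: 2.5, 3: 4.0, 4: 6.0}[b]
        s = compute_sofa_score(meas, timestamp=ts)
        assert s.total == total
        out.append(s)
    return out


def _window(center):
    return InfectionWindow("p", center, center - hours(24), center + hours(24), center)


class TestLabelVisit:
    def test_unmeasured_baseline_counts_zero(self):
        series = _series([(T0 + hours(2), 2)])
        lab = label_visit(series, [_window(T0)], T0)
        assert lab.label == "sepsis"
        assert lab.baseline_sofa == 0
        assert lab.max_delta == 2

    def test_delta_below_threshold_is_nonsepsis(self):
        series = _series([(T0 - hours(30), 3), (T0 + hours(2), 4)])
        lab = label_visit(series, [_window(T0)], T0)
        assert lab.label == "nonsepsis"
        assert lab.baseline_sofa == 3
        assert lab.max_delta == 1

    def test_delta_above_threshold_is_sepsis(self):
        series = _series([(T0 - hours(30), 1), (T0 + hours(2), 6)])
        lab = label_visit(series, [_window(T0)], T0)
        assert lab.label == "sepsis"
        assert lab.max_delta == 5

    def test_no_windows_is_nonsepsis(self):
        series = _series([(T0 + hours(2), 8)])
        assert label_visit(series, [], T0).label == "nonsepsis"

    def test_earliest_qualifying_window_triggers(self):
        series = _series([(T0 + hours(2), 3), (T0 + hours(60), 3)])
        w1, w2 = _window(T0), _window(T0 + hours(58))
        lab = label_visit(series, [w2, w1], T0)
        assert lab.triggering_window is w1

    def test_idempotent_relabeling(self, small_events, antibiotic_ids, small_labels):
        again = label_cohort(small_events, antibiotic_ids=antibiotic_ids)
        pd.testing.assert_frame_equal(small_labels, again)


def brute_force_label(series, windows):
    """Exhaustive enumeration over (window x assessment) pairs."""
    sepsis = False
    for w in windows:
        pre = [a for a in series if a.timestamp < w.window_start]
        baseline = pre[-1].total if pre else 0
        for a in series:
            if w.window_start <= a.timestamp <= w.window_end:
                if a.total - baseline >= 2:
                    sepsis = True
    return "sepsis" if sepsis else "nonsepsis"


@settings(max_examples=150, deadline=None, derandomize=True)
@given(
    totals=st.lists(st.integers(0, 8), min_size=1, max_size=20),
    offsets=st.lists(st.integers(-80, 80), min_size=1, max_size=20),
    centers=st.lists(st.integers(-40, 40), min_size=0, max_size=3),
)
def test_label_visit_matches_enumeration(totals, offsets, centers):
    n = min(len(totals), len(offsets))
    pts = sorted(zip([T0 + hours(o) for o in offsets[:n]], totals[:n]))
    series = _series(pts)
    windows = [_window(T0 + hours(c)) for c in centers]
    assert label_visit(series, windows, T0).label == brute_force_label(series, windows)


def test_raising_severity_never_decreases_delta():
    """Monotonicity: worsening an in-window measurement cannot lower max_delta."""
    base = [(T0 - hours(30), 0)]
    for total in range(0, 8):
        series = _series(base + [(T0 + hours(2), total)])
        worse = _series(base + [(T0 + hours(2), total + 1)])
        d1 = label_visit(series, [_window(T0)], T0).max_delta
        d2 = label_visit(worse, [_window(T0)], T0).max_delta
        assert d2 >= d1


def test_locf_series_carries_components_forward():
    df = pd.DataFrame(
        {
            "timestamp": [T0, T0 + hours(1)],
            "component": ["platelets", "creatinine"],
            "value": [90.0, 2.5],
        }
    )
    series = sofa_series(df)
    assert series[0].total == 2           # platelets only
    assert series[1].total == 4           # platelets carried forward + creatinine
    assert "coagulation" not in series[1].components_missing


def test_end_to_end_recovery(small_events, small_labels):
    """The Sepsis-3 labeler recovers generator ground truth >= 95%."""
    merged = small_labels.merge(small_events.ground_truth, on=["patient_id", "visit_id"])
    expected = merged["group"].map({"sepsis": "sepsis", "control": "nonsepsis"})
    assert (merged["label"] == expected).mean() >= 0.95
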