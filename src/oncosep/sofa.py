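"""Sepsis-3 visit labeling from longitudinal SOFA scores.

The rule: a visit is sepsis when, within a suspected-infection window (a
bacterial culture with an intravenous antibiotic administered within 24 h
before or after it), the SOFA total rises by >= 2 points over the last
assessment preceding the window.  An unmeasured baseline counts as 0, so a
first ER visit with an in-window SOFA of >= 2 is labeled sepsis.

SOFA totals sum six organ-system subscores (respiration, coagulation, liver,
cardiovascular, CNS, renal), each 0-4, mapped from raw measurements through
the threshold table in ``data/sofa_thresholds.yaml``.  Missing components
score 0 and are flagged.  Scores are recomputed at every timestamp carrying a
new component value, with last observation carried forward per component.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

ORGAN_SYSTEMS = ("respiration", "coagulation", "liver", "cardiovascular", "cns", "renal")

#: raw measurements that must be nonnegative
_NONNEG = {"platelets", "creatinine", "bilirubin"}

WINDOW_HOURS = 24.0


class MeasurementError(ValueError):
    """Raised for physically impossible raw component values."""


@functools.lru_cache(maxsize=None)
def load_sofa_thresholds(path: str | None = None) -> dict:
    """Load the (overridable) SOFA threshold table."""
    if path is None:
        src = resources.files("oncosep").joinpath("data/sofa_thresholds.yaml")
        text = src.read_text(encoding="utf-8")
    else:
        with open(path, encoding="utf-8") as fh:
            text = fh.read()
    table = yaml.safe_load(text)
    missing = set(ORGAN_SYSTEMS) - set(table)
    if missing:
        raise ValueError(f"threshold table missing systems: {sorted(missing)}")
    return table


@dataclass(frozen=True)
class SofaAssessment:
    patient_id: str
    timestamp: pd.Timestamp
    subscores: Mapping[str, int]
    total: int
    components_missing: frozenset[str]

    def __post_init__(self):
        assert self.total == sum(self.subscores.values())


@dataclass(frozen=True)
class InfectionWindow:
    patient_id: str
    culture_time: pd.Timestamp
    window_start: pd.Timestamp
    window_end: pd.Timestamp
    antibiotic_time: pd.Timestamp


@dataclass(frozen=True)
class VisitLabel:
    patient_id: str
    visit_id: str
    label: str                      # "sepsis" | "nonsepsis"
    baseline_sofa: int
    max_delta: int
    triggering_window: InfectionWindow | None = field(default=None, compare=False)


def _band_score(value: float, spec: dict) -> int:
    if spec["direction"] == "low":
        for threshold, score in spec["bands"]:
            if value < threshold:
                return int(score)
    else:
        for threshold, score in spec["bands"]:
            if value >= threshold:
                return int(score)
    return 0


def compute_sofa_score(
    measurements: Mapping[str, float],
    patient_id: str = "",
    timestamp: pd.Timestamp | None = None,
    thresholds: dict | None = None,
) -> SofaAssessment:
    """Score one timepoint's raw component measurements.

    ``measurements`` maps raw-measurement names (pao2_fio2, platelets,
    bilirubin, map, vasopressor, gcs, creatinine) to values; absent or NaN
    components score 0 and are reported in ``components_missing``.
    """
    table = thresholds or load_sofa_thresholds()
    for name in _NONNEG:
        v = measurements.get(name)
        if v is not None and not (isinstance(v, float) and np.isnan(v)) and v < 0:
            raise MeasurementError(f"{name} must be nonnegative, got {v}")
    subscores: dict[str, int] = {}
    missing: set[str] = set()
    for system in ORGAN_SYSTEMS:
        spec = table[system]
        raw = measurements.get(spec["measurement"])
        absent = raw is None or (isinstance(raw, float) and np.isnan(raw))
        score = 0 if absent else _band_score(float(raw), spec)
        if system == "cardiovascular":
            vaso = measurements.get("vasopressor")
            if vaso is not None and not (isinstance(vaso, float) and np.isnan(vaso)) and vaso:
                score = max(score, int(spec.get("vasopressor_score", 2)))
                absent = False
        if absent:
            missing.add(system)
        subscores[system] = score
    return SofaAssessment(
        patient_id=patient_id,
        timestamp=timestamp,
        subscores=subscores,
        total=sum(subscores.values()),
        components_missing=frozenset(missing),
    )


def sofa_series(
    sofa_inputs: pd.DataFrame,
    patient_id: str = "",
    thresholds: dict | None = None,
) -> list[SofaAssessment]:
    """Recompute SOFA at every timestamp with a new value, LOCF per component.

    ``sofa_inputs`` is long-form (timestamp, component, value) for one
    patient/visit.
    """
    if sofa_inputs.empty:
        return []
    current: dict[str, float] = {}
    out = []
    for ts, grp in sofa_inputs.sort_values("timestamp").groupby("timestamp", sort=True):
        for _, r in grp.iterrows():
            current[r["component"]] = r["value"]
        out.append(
            compute_sofa_score(dict(current), patient_id, ts, thresholds=thresholds)
        )
    return out


def find_infection_windows(
    cultures: pd.DataFrame,
    prescriptions: pd.DataFrame,
    antibiotic_ids: Iterable[str] | None = None,
    window_hours: float = WINDOW_HOURS,
) -> list[InfectionWindow]:
    """Suspected-infection windows: culture ± ``window_hours`` containing an
    intravenous antibiotic administration (boundary inclusive).

    ``antibiotic_ids`` restricts which drugs count as antibiotics; with None,
    every IV-route prescription qualifies.  Non-IV routes never qualify.
    """
    out: list[InfectionWindow] = []
    if cultures.empty or prescriptions.empty:
        return out
    rx = prescriptions
    rx = rx[rx["route"].astype(str).str.upper() == "IV"]
    if antibiotic_ids is not None:
        rx = rx[rx["drug_id"].isin(set(antibiotic_ids))]
    if rx.empty:
        return out
    half = pd.Timedelta(hours=window_hours)
    for _, c in cultures.sort_values("timestamp").iterrows():
        t0 = c["timestamp"]
        mine = rx[rx["patient_id"] == c["patient_id"]]
        hits = mine[(mine["timestamp"] - t0).abs() <= half]
        if len(hits):
            out.append(
                InfectionWindow(
                    patient_id=c["patient_id"],
                    culture_time=t0,
                    window_start=t0 - half,
                    window_end=t0 + half,
                    antibiotic_time=hits["timestamp"].min(),
                )
            )
    return out


def label_visit(
    series: Sequence[SofaAssessment],
    windows: Sequence[InfectionWindow],
    er_visit_time: pd.Timestamp,
    patient_id: str = "",
    visit_id: str = "",
) -> VisitLabel:
    """Apply the Sepsis-3 rule to one visit.

    Per window: baseline is the last SOFA total strictly before window_start
    (0 when unmeasured), delta is the in-window maximum total minus baseline.
    The visit is sepsis when any window reaches delta >= 2; the triggering
    window is the earliest such window.
    """
    evaluated: list[tuple[int, int, InfectionWindow]] = []
    for w in sorted(windows, key=lambda w: w.culture_time):
        pre = [a.total for a in series if a.timestamp < w.window_start]
        baseline = pre[-1] if pre else 0
        inside = [
            a.total
            for a in series
            if w.window_start <= a.timestamp <= w.window_end
        ]
        if not inside:
            continue
        evaluated.append((max(inside) - baseline, baseline, w))
    trigger = next((w for d, _, w in evaluated if d >= 2), None)
    if trigger is not None:
        delta, baseline = next((d, b) for d, b, w in evaluated if w is trigger)
        max_delta = max(d for d, _, _ in evaluated)
        return VisitLabel(patient_id, visit_id, "sepsis", baseline, max_delta, trigger)
    if evaluated:
        max_delta, baseline, _ = max(evaluated, key=lambda t: t[0])
    else:
        max_delta, baseline = 0, 0
    return VisitLabel(patient_id, visit_id, "nonsepsis", baseline, max_delta, None)


def label_cohort(
    events,
    antibiotic_ids: Iterable[str] | None = None,
    thresholds: dict | None = None,
) -> pd.DataFrame:
    """Label every visit of an :class:`~oncosep.cohort.EventTable`.

    Returns a DataFrame (patient_id, visit_id, label, baseline_sofa,
    max_delta, window_start, window_end), one row per visit.
    """
    rows = []
    sofa_by_visit = dict(tuple(events.sofa_inputs.groupby("visit_id", sort=False)))
    cult_by_visit = dict(tuple(events.cultures.groupby("visit_id", sort=False)))
    rx_by_visit = dict(tuple(events.prescriptions.groupby("visit_id", sort=False)))
    empty_c = events.cultures.iloc[0:0]
    empty_r = events.prescriptions.iloc[0:0]
    for _, v in events.visits.iterrows():
        vid, pid = v["visit_id"], v["patient_id"]
        series = sofa_series(
            sofa_by_visit.get(vid, events.sofa_inputs.iloc[0:0]),
            pid,
            thresholds=thresholds,
        )
        windows = find_infection_windows(
            cult_by_visit.get(vid, empty_c),
            rx_by_visit.get(vid, empty_r),
            antibiotic_ids=antibiotic_ids,
        )
        lab = label_visit(series, windows, v["er_visit_time"], pid, vid)
        rows.append(
            {
                "patient_id": pid,
                "visit_id": vid,
                "label": lab.label,
                "baseline_sofa": lab.baseline_sofa,
                "max_delta": lab.max_delta,
                "window_start": lab.triggering_window.window_start
                if lab.triggering_window
                else pd.NaT,
                "window_end": lab.triggering_window.window_end
                if lab.triggering_window
                else pd.NaT,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "patient_id",
            "visit_id",
            "label",
            "baseline_sofa",
            "max_delta",
            "window_start",
            "window_end",
        ],
    )
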