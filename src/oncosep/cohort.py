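"""Synthetic longitudinal EHR cohort generator.

Emulates the statistical structure the downstream analysis assumes: two
patient groups (sepsis / non-sepsis controls) with the published demographic
mix, per-group lab-value distributions, group-differential same-day
co-prescription patterns, and raw SOFA-component trajectories plus
culture/antibiotic timing constructed so the Sepsis-3 labeler can recover the
ground-truth group.

All randomness flows through one ``numpy.random.Generator`` seeded from the
config, so identical (config, seed) yields identical tables.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, fields

import numpy as np
import pandas as pd

from .config import (
    CANCER_ICD_ROOT,
    CANCER_TYPES,
    CohortConfig,
    ConfigurationError,
)
from .distributions import sample_lab_values

_EPOCH = pd.Timestamp("2017-01-01 08:00:00")

PATIENT_COLUMNS = ["patient_id", "sex", "age", "weight", "cancer_type", "diagnosis_code"]
VISIT_COLUMNS = ["patient_id", "visit_id", "er_visit_time"]
LAB_COLUMNS = ["patient_id", "visit_id", "timestamp", "lab_type", "value"]
RX_COLUMNS = ["patient_id", "visit_id", "date", "timestamp", "drug_id", "route"]
CULTURE_COLUMNS = ["patient_id", "visit_id", "timestamp"]
SOFA_COLUMNS = ["patient_id", "visit_id", "timestamp", "component", "value"]
TRUTH_COLUMNS = ["patient_id", "visit_id", "group"]

#: SOFA-relevant raw components emitted by the trajectory generator.
SOFA_COMPONENTS = (
    "pao2_fio2",        # mmHg ratio (respiration)
    "platelets",        # 10^3/uL   (coagulation)
    "bilirubin",        # mg/dL     (liver)
    "map",              # mmHg      (cardiovascular)
    "vasopressor",      # 0/1 flag  (cardiovascular)
    "gcs",              # 3-15      (CNS)
    "creatinine",       # mg/dL     (renal)
)


@dataclass
class EventTable:
    """Longitudinal per-patient event streams as tidy DataFrames.

    ``ground_truth`` records the generating group per visit and is metadata:
    no analysis stage reads it except for validation against recovered labels.
    """

    patients: pd.DataFrame
    visits: pd.DataFrame
    labs: pd.DataFrame
    prescriptions: pd.DataFrame
    cultures: pd.DataFrame
    sofa_inputs: pd.DataFrame
    ground_truth: pd.DataFrame

    def __post_init__(self):
        pids = set(self.patients["patient_id"])
        for name in ("visits", "labs", "prescriptions", "cultures", "sofa_inputs"):
            df = getattr(self, name)
            if len(df) and not set(df["patient_id"]).issubset(pids):
                raise ValueError(f"{name} references unknown patient_id")

    def equals(self, other: "EventTable") -> bool:
        return all(
            getattr(self, f.name).reset_index(drop=True).equals(
                getattr(other, f.name).reset_index(drop=True)
            )
            for f in fields(self)
        )

    # -- round-trip to a directory of delimited text files ----------------
    _FILES = {
        "patients": "patients.csv",
        "visits": "visits.csv",
        "labs": "labs.csv",
        "prescriptions": "prescriptions.csv",
        "cultures": "cultures.csv",
        "sofa_inputs": "sofa_inputs.csv",
        "ground_truth": "ground_truth.csv",
    }

    def to_csv_dir(self, path: str) -> None:
        os.makedirs(path, exist_ok=True)
        for name, fname in self._FILES.items():
            getattr(self, name).to_csv(os.path.join(path, fname), index=False)

    @classmethod
    def from_csv_dir(cls, path: str) -> "EventTable":
        kw = {}
        parse = {
            "visits": ["er_visit_time"],
            "labs": ["timestamp"],
            "prescriptions": ["timestamp"],
            "cultures": ["timestamp"],
            "sofa_inputs": ["timestamp"],
        }
        for name, fname in cls._FILES.items():
            df = pd.read_csv(os.path.join(path, fname))
            for col in parse.get(name, []):
                df[col] = pd.to_datetime(df[col])
            kw[name] = df
        return cls(**kw)


# ---------------------------------------------------------------------------
# trajectory + panel generators (exposed individually for testing)
# ---------------------------------------------------------------------------

# Pre-ER baseline physiology (all components in the zero-score band).
_BASELINE = {
    "pao2_fio2": (450.0, 20.0),
    "platelets": (250.0, 30.0),
    "bilirubin": (0.6, 0.15),
    "map": (85.0, 5.0),
    "gcs": (15.0, 0.0),
    "creatinine": (0.8, 0.1),
}

# Acute in-window physiology for sepsis patients: respiration and coagulation
# deteriorate into the score-2 bands, guaranteeing a SOFA rise >= 2 over the
# (near-zero) baseline even when one component is missed.
_SEPSIS_ACUTE = {
    "pao2_fio2": (240.0, 25.0),
    "platelets": (80.0, 10.0),
    "bilirubin": (2.6, 0.4),
    "map": (62.0, 4.0),
    "gcs": (14.0, 0.0),
    "creatinine": (1.5, 0.2),
}


def _clip(value: float, lo: float, hi: float) -> float:
    return float(min(max(value, lo), hi))


def generate_sofa_trajectory(
    patient_group: str,
    er_time: pd.Timestamp,
    config: CohortConfig,
    rng: np.random.Generator,
) -> tuple[list[dict], list[dict], list[dict]]:
    """Raw SOFA-component series plus culture and IV-antibiotic events.

    Sepsis-group visits get a bacterial culture near the ER arrival, an
    intravenous antibiotic within 24 h of it, and in-window component values
    implying a SOFA rise of >= 2 over the pre-ER baseline.  Controls either
    get no culture, or a culture with stable physiology (rise <= 1).

    Returns ``(sofa_rows, culture_rows, antibiotic_rx_rows)`` as dicts without
    patient/visit keys (the caller attaches them).
    """
    if patient_group not in ("sepsis", "control"):
        raise ConfigurationError(f"unknown group {patient_group!r}")
    sofa_rows: list[dict] = []
    culture_rows: list[dict] = []
    rx_rows: list[dict] = []

    def emit(ts, means, vaso_p=0.0):
        for comp, (m, s) in means.items():
            v = rng.normal(m, s) if s > 0 else m
            if comp == "platelets":
                v = _clip(v, 1.0, 1000.0)
            elif comp == "gcs":
                v = _clip(round(v), 3, 15)
            elif comp == "map":
                v = _clip(v, 30.0, 130.0)
            elif comp in ("bilirubin", "creatinine"):
                v = _clip(v, 0.05, 30.0)
            elif comp == "pao2_fio2":
                v = _clip(v, 40.0, 600.0)
            sofa_rows.append({"timestamp": ts, "component": comp, "value": round(v, 2)})
        sofa_rows.append(
            {
                "timestamp": ts,
                "component": "vasopressor",
                "value": float(rng.random() < vaso_p),
            }
        )

    baseline_t = er_time - pd.Timedelta(days=3)
    emit(baseline_t, _BASELINE)

    if patient_group == "sepsis":
        culture_t = er_time + pd.Timedelta(hours=float(rng.uniform(0.5, 4.0)))
        abx_t = culture_t + pd.Timedelta(hours=float(rng.uniform(-12.0, 18.0)))
        acute_t = culture_t + pd.Timedelta(hours=float(rng.uniform(2.0, 12.0)))
        culture_rows.append({"timestamp": culture_t})
        abx = rng.choice(["cephalosporin_iv", "carbapenem_iv"])
        rx_rows.append(
            {"date": abx_t.normalize(), "timestamp": abx_t, "drug_id": str(abx), "route": "IV"}
        )
        emit(acute_t, _SEPSIS_ACUTE, vaso_p=0.4)
    else:
        if rng.random() < config.control_culture_rate:
            culture_t = er_time + pd.Timedelta(hours=float(rng.uniform(0.5, 4.0)))
            abx_t = culture_t + pd.Timedelta(hours=float(rng.uniform(-12.0, 18.0)))
            culture_rows.append({"timestamp": culture_t})
            abx = rng.choice(["cephalosporin_iv", "carbapenem_iv"])
            rx_rows.append(
                {"date": abx_t.normalize(), "timestamp": abx_t, "drug_id": str(abx), "route": "IV"}
            )
            stable_t = culture_t + pd.Timedelta(hours=float(rng.uniform(2.0, 12.0)))
            emit(stable_t, _BASELINE)
        else:
            emit(er_time + pd.Timedelta(hours=6.0), _BASELINE)
    return sofa_rows, culture_rows, rx_rows


def generate_lab_panel(
    group: str,
    config: CohortConfig,
    rng: np.random.Generator,
    n: int | None = None,
    lab_types: list[str] | None = None,
) -> pd.DataFrame:
    """Draw one lab panel (one value per lab type) for ``n`` visits of a group.

    Values come from the moment-matched nonnegative family for the configured
    per-group (mean, sd); entries are set missing (NaN) at
    ``config.missingness_rate``.  Returns a long DataFrame
    (row index 0..n-1, lab_type, value).
    """
    if group not in ("sepsis", "control"):
        raise ConfigurationError(f"unknown group {group!r}")
    lab_types = list(lab_types or config.lab_params)
    for lt in lab_types:
        if lt not in config.lab_params:
            raise ConfigurationError(f"unknown lab type {lt!r}")
    n = 1 if n is None else int(n)
    frames = []
    for lt in lab_types:
        lp = config.lab_params[lt]
        vals = sample_lab_values(
            lp.mean[group], lp.sd[group], n, rng, nonnegative=lp.nonnegative
        )
        if config.missingness_rate > 0:
            vals = np.where(rng.random(n) < config.missingness_rate, np.nan, vals)
        frames.append(pd.DataFrame({"row": np.arange(n), "lab_type": lt, "value": vals}))
    return pd.concat(frames, ignore_index=True)


def _daily_prescriptions(group, config, rng) -> list[tuple[int, str]]:
    """Same-day drug baskets over the 2-7 day observation window.

    Returns (day_offset, drug_id) with day_offset in {-7..-2}; independent
    daily draws per catalog drug plus joint pair boosts.
    """
    out = []
    for day in range(-7, -1):
        basket = set()
        for d in config.drug_catalog:
            if rng.random() < d.p_daily.get(group, 0.0):
                basket.add(d.drug_id)
        for b in config.pair_boosts:
            if rng.random() < b.p_joint.get(group, 0.0):
                basket.add(b.drug_a)
                basket.add(b.drug_b)
        out.extend((day, did) for did in sorted(basket))
    return out


def generate_cohort(config: CohortConfig) -> EventTable:
    """Generate the full synthetic cohort described by ``config``.

    Deterministic in (config, seed).  Group membership is recorded in
    ``ground_truth`` only; events themselves carry no label.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    route_by_drug = {d.drug_id: "IV" if d.is_antibiotic else "PO" for d in config.drug_catalog}

    patients, visits, labs, rxs, cultures, sofas, truth = [], [], [], [], [], [], []
    groups = ["control"] * config.n_control + ["sepsis"] * config.n_sepsis

    visit_counter = 0
    for idx, group in enumerate(groups):
        pid = f"P{idx:05d}"
        male_p = config.male_fraction_by_group[group]
        sex = "M" if rng.random() < male_p else "F"
        a_m, a_s = config.age_params[group]
        age = _clip(rng.normal(a_m, a_s), *config.age_range)
        w_m, w_s = config.weight_params[group]
        weight = max(30.0, rng.normal(w_m, w_s))
        cancer = str(rng.choice(CANCER_TYPES, p=config.cancer_mix_by_group[group]))
        dx = f"{CANCER_ICD_ROOT[cancer]}.{rng.integers(0, 10)}"
        patients.append(
            {
                "patient_id": pid,
                "sex": sex,
                "age": round(age, 1),
                "weight": round(weight, 1),
                "cancer_type": cancer,
                "diagnosis_code": dx,
            }
        )

        n_visits = 1 + int(rng.random() < config.repeat_visit_rate)
        for v in range(n_visits):
            vid = f"V{visit_counter:05d}"
            visit_counter += 1
            er_time = (
                _EPOCH
                + pd.Timedelta(days=int(rng.integers(10, 700)) + 90 * v)
                + pd.Timedelta(hours=float(rng.uniform(0, 12)))
            )
            visits.append({"patient_id": pid, "visit_id": vid, "er_visit_time": er_time})
            truth.append({"patient_id": pid, "visit_id": vid, "group": group})

            # observation-window labs: one panel per visit, timestamped in-window
            panel = generate_lab_panel(group, config, rng, n=1)
            for _, r in panel.iterrows():
                if np.isnan(r["value"]):
                    continue
                t = er_time - pd.Timedelta(days=float(rng.uniform(2.0, 7.0)))
                labs.append(
                    {
                        "patient_id": pid,
                        "visit_id": vid,
                        "timestamp": t,
                        "lab_type": r["lab_type"],
                        "value": round(float(r["value"]), 4),
                    }
                )

            # observation-window prescriptions (oral supportive care, noon)
            for day, did in _daily_prescriptions(group, config, rng):
                day_ts = (er_time + pd.Timedelta(days=day)).normalize()
                rxs.append(
                    {
                        "patient_id": pid,
                        "visit_id": vid,
                        "date": day_ts.date().isoformat(),
                        "timestamp": day_ts + pd.Timedelta(hours=12),
                        "drug_id": did,
                        "route": route_by_drug.get(did, "PO"),
                    }
                )

            # SOFA trajectory + culture/antibiotic timing around the visit
            s_rows, c_rows, a_rows = generate_sofa_trajectory(group, er_time, config, rng)
            for r in s_rows:
                sofas.append({"patient_id": pid, "visit_id": vid, **r})
            for r in c_rows:
                cultures.append({"patient_id": pid, "visit_id": vid, **r})
            for r in a_rows:
                rxs.append(
                    {
                        "patient_id": pid,
                        "visit_id": vid,
                        "date": r["timestamp"].date().isoformat(),
                        "timestamp": r["timestamp"],
                        "drug_id": r["drug_id"],
                        "route": r["route"],
                    }
                )

    def frame(rows, cols):
        df = pd.DataFrame(rows, columns=cols)
        return df[cols]

    return EventTable(
        patients=frame(patients, PATIENT_COLUMNS),
        visits=frame(visits, VISIT_COLUMNS),
        labs=frame(labs, LAB_COLUMNS),
        prescriptions=frame(rxs, RX_COLUMNS),
        cultures=frame(cultures, CULTURE_COLUMNS),
        sofa_inputs=frame(sofas, SOFA_COLUMNS),
        ground_truth=frame(truth, TRUTH_COLUMNS),
    )
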