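"""Cohort configuration: group sizes, demographics, lab distributions, drug catalog.

Defaults encode the published cohort summary for a 1383-patient ER cohort of
liver/lung/breast cancer patients (928 non-sepsis controls, 455 sepsis) and
the eight lab tests whose per-group means/SDs are printed in the source
study's running text.  Everything is overridable; the generator consumes only
this object.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import yaml

GROUPS = ("control", "sepsis")
CANCER_TYPES = ("liver", "lung", "breast")

#: ICD-10 roots used as inclusion codes (liver, lung, breast carcinoma).
CANCER_ICD_ROOT = {"liver": "C22", "lung": "C34", "breast": "C50"}


class ConfigurationError(ValueError):
    """Raised when a cohort configuration violates its invariants."""


@dataclass(frozen=True)
class LabParams:
    """Per-group (mean, sd) for one lab test, in that lab's reporting units."""

    mean: Mapping[str, float]
    sd: Mapping[str, float]
    units: str = ""
    nonnegative: bool = True

    def validate(self, name: str) -> None:
        for g in GROUPS:
            if g not in self.mean or g not in self.sd:
                raise ConfigurationError(f"lab {name!r}: missing group {g!r}")
            if self.sd[g] < 0:
                raise ConfigurationError(f"lab {name!r}: sd < 0 for group {g!r}")


@dataclass(frozen=True)
class DrugSpec:
    """One abstract drug: per-group daily prescription probability and flags."""

    drug_id: str
    p_daily: Mapping[str, float]
    is_antibiotic: bool = False

    def validate(self) -> None:
        for g in GROUPS:
            p = self.p_daily.get(g, 0.0)
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(
                    f"drug {self.drug_id!r}: p_daily[{g!r}]={p} outside [0,1]"
                )


@dataclass(frozen=True)
class PairBoost:
    """Extra joint co-prescription probability for one drug pair, per group.

    On any observation-window day the pair is additionally prescribed
    together with this probability, on top of the independent daily draws.
    This is what gives the co-prescription miner a group contrast to detect.
    """

    drug_a: str
    drug_b: str
    p_joint: Mapping[str, float]

    def validate(self) -> None:
        if self.drug_a == self.drug_b:
            raise ConfigurationError(f"pair boost on identical drug {self.drug_a!r}")
        for g in GROUPS:
            p = self.p_joint.get(g, 0.0)
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(
                    f"pair ({self.drug_a},{self.drug_b}): p_joint[{g!r}]={p} outside [0,1]"
                )


# Lab means/SDs printed per group in the source study (sepsis vs control).
DEFAULT_LAB_PARAMS: dict[str, LabParams] = {
    "albumin": LabParams(
        mean={"sepsis": 2.73, "control": 3.30},
        sd={"sepsis": 1.57, "control": 1.47},
        units="g/dL",
    ),
    "total_protein": LabParams(
        mean={"sepsis": 4.77, "control": 5.27},
        sd={"sepsis": 2.98, "control": 2.82},
        units="g/dL",
    ),
    "cholesterol": LabParams(
        mean={"sepsis": 81.06, "control": 111.46},
        sd={"sepsis": 84.79, "control": 84.30},
        units="mg/dL",
    ),
    "ag_ratio": LabParams(
        mean={"sepsis": 0.76, "control": 1.14},
        sd={"sepsis": 0.70, "control": 0.69},
        units="ratio",
    ),
    "aptt": LabParams(
        mean={"sepsis": 14.06, "control": 6.89},
        sd={"sepsis": 19.72, "control": 15.01},
        units="sec",
    ),
    "pt_percent": LabParams(
        mean={"sepsis": 33.27, "control": 17.51},
        sd={"sepsis": 42.26, "control": 35.82},
        units="%",
    ),
    "pt_inr": LabParams(
        mean={"sepsis": 0.49, "control": 0.23},
        sd={"sepsis": 0.63, "control": 0.46},
        units="INR",
    ),
    "pt_sec": LabParams(
        mean={"sepsis": 6.14, "control": 2.90},
        sd={"sepsis": 7.69, "control": 5.84},
        units="sec",
    ),
}


def _drug(drug_id, p_control, p_sepsis, antibiotic=False):
    return DrugSpec(
        drug_id=drug_id,
        p_daily={"control": p_control, "sepsis": p_sepsis},
        is_antibiotic=antibiotic,
    )


# Abstract catalog: common supportive drugs appear in both groups; narcotic
# analgesics ("opioid_alkaloids", "synthetic_narcotics") are prescribed more,
# and more often together, in the sepsis group.
DEFAULT_DRUG_CATALOG: tuple[DrugSpec, ...] = (
    _drug("saline_solution", 0.55, 0.60),
    _drug("dextrose", 0.30, 0.32),
    _drug("opioid_alkaloids", 0.10, 0.35),
    _drug("synthetic_narcotics", 0.08, 0.30),
    _drug("antiemetic", 0.20, 0.25),
    _drug("ppi", 0.22, 0.24),
    _drug("acetaminophen", 0.25, 0.28),
    _drug("nsaid", 0.18, 0.12),
    _drug("heparin_flush", 0.15, 0.18),
    _drug("loop_diuretic", 0.08, 0.12),
    _drug("corticosteroid", 0.12, 0.16),
    _drug("antihistamine", 0.10, 0.10),
    _drug("laxative", 0.12, 0.12),
    _drug("benzodiazepine", 0.07, 0.09),
    _drug("insulin", 0.08, 0.09),
    _drug("antacid", 0.10, 0.09),
    _drug("cephalosporin_iv", 0.02, 0.04, antibiotic=True),
    _drug("carbapenem_iv", 0.005, 0.01, antibiotic=True),
)

DEFAULT_PAIR_BOOSTS: tuple[PairBoost, ...] = (
    PairBoost(
        "opioid_alkaloids",
        "synthetic_narcotics",
        {"control": 0.010, "sepsis": 0.20},
    ),
    PairBoost(
        "opioid_alkaloids",
        "antiemetic",
        {"control": 0.015, "sepsis": 0.10},
    ),
)


@dataclass
class CohortConfig:
    """Full specification of a synthetic longitudinal EHR cohort.

    Parameters
    ----------
    n_control, n_sepsis
        Patients per ground-truth group.  Defaults are the published filtered
        cohort sizes (928 / 455).
    male_fraction_by_group, cancer_mix_by_group
        Demographic mix per group; cancer mix is a probability vector over
        ``("liver", "lung", "breast")`` summing to 1.
    age_params, weight_params
        Per-group (mean, sd); ages are clipped to ``age_range`` (adults only).
    lab_params
        Per lab test, per-group (mean, sd) in reporting units.  Values are
        drawn from a moment-matched nonnegative distribution (see
        :mod:`oncosep.distributions`).
    drug_catalog, pair_boosts
        Abstract drugs with per-group daily prescription probabilities, plus
        joint co-prescription boosts that create the group-differential
        narcotic-analgesic pattern.
    missingness_rate
        Probability that any single lab measurement is absent.
    repeat_visit_rate
        Probability a patient contributes a second ER visit (the published
        cohort has ~1.06 visits/patient).
    """

    n_control: int = 928
    n_sepsis: int = 455
    male_fraction_by_group: dict[str, float] = field(
        default_factory=lambda: {"control": 0.528, "sepsis": 0.712}
    )
    cancer_mix_by_group: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: {
            "control": (0.194, 0.574, 0.232),
            "sepsis": (0.308, 0.602, 0.090),
        }
    )
    age_params: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"control": (58.2, 11.0), "sepsis": (60.3, 11.0)}
    )
    age_range: tuple[float, float] = (18.0, 95.0)
    weight_params: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"control": (63.7, 10.7), "sepsis": (64.3, 11.3)}
    )
    lab_params: dict[str, LabParams] = field(
        default_factory=lambda: dict(DEFAULT_LAB_PARAMS)
    )
    drug_catalog: Sequence[DrugSpec] = DEFAULT_DRUG_CATALOG
    pair_boosts: Sequence[PairBoost] = DEFAULT_PAIR_BOOSTS
    missingness_rate: float = 0.10
    repeat_visit_rate: float = 0.06
    control_culture_rate: float = 0.30
    seed: int = 0

    def validate(self) -> "CohortConfig":
        if self.n_control < 0 or self.n_sepsis < 0:
            raise ConfigurationError("group sizes must be >= 0")
        if not 0.0 <= self.missingness_rate <= 1.0:
            raise ConfigurationError("missingness_rate outside [0,1]")
        if not 0.0 <= self.repeat_visit_rate <= 1.0:
            raise ConfigurationError("repeat_visit_rate outside [0,1]")
        for g in GROUPS:
            f = self.male_fraction_by_group[g]
            if not 0.0 <= f <= 1.0:
                raise ConfigurationError(f"male fraction for {g!r} outside [0,1]")
            mix = self.cancer_mix_by_group[g]
            if len(mix) != len(CANCER_TYPES) or any(p < 0 for p in mix):
                raise ConfigurationError(f"cancer mix for {g!r} is not a probability vector")
            if abs(sum(mix) - 1.0) > 1e-9:
                raise ConfigurationError(
                    f"cancer mix for {g!r} sums to {sum(mix)}, not 1"
                )
        for name, lp in self.lab_params.items():
            lp.validate(name)
        ids = [d.drug_id for d in self.drug_catalog]
        if len(set(ids)) != len(ids):
            raise ConfigurationError("duplicate drug_id in catalog")
        for d in self.drug_catalog:
            d.validate()
        for b in self.pair_boosts:
            b.validate()
            for did in (b.drug_a, b.drug_b):
                if did not in ids:
                    raise ConfigurationError(f"pair boost references unknown drug {did!r}")
        return self

    # -- serialization ---------------------------------------------------
    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(_to_plain(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "CohortConfig":
        raw = dict(raw)
        if "lab_params" in raw:
            raw["lab_params"] = {
                k: LabParams(**v) for k, v in raw["lab_params"].items()
            }
        if "drug_catalog" in raw:
            raw["drug_catalog"] = tuple(DrugSpec(**d) for d in raw["drug_catalog"])
        if "pair_boosts" in raw:
            raw["pair_boosts"] = tuple(PairBoost(**b) for b in raw["pair_boosts"])
        for key in ("cancer_mix_by_group", "age_params", "weight_params"):
            if key in raw:
                raw[key] = {g: tuple(v) for g, v in raw[key].items()}
        if "age_range" in raw:
            raw["age_range"] = tuple(raw["age_range"])
        return cls(**raw).validate()


def _to_plain(cfg: CohortConfig) -> dict:
    d = asdict(cfg)
    d["drug_catalog"] = [asdict(x) for x in cfg.drug_catalog]
    d["pair_boosts"] = [asdict(x) for x in cfg.pair_boosts]
    for key in ("cancer_mix_by_group", "age_params", "weight_params"):
        d[key] = {g: list(v) for g, v in d[key].items()}
    d["age_range"] = list(d["age_range"])
    d["lab_params"] = {
        k: {
            "mean": dict(v.mean),
            "sd": dict(v.sd),
            "units": v.units,
            "nonnegative": v.nonnegative,
        }
        for k, v in cfg.lab_params.items()
    }
    return d
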