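"""End-to-end analysis: generate -> label -> features -> mine -> vectorize ->
screen labs -> cross-validated evaluation.

This is the whole study pipeline wired together on synthetic data: visits are
labeled by the Sepsis-3 rule (never by generator ground truth), co-prescription
pairs are mined per recovered group, the union of selected drugs is
vectorized into (I, H, T) relationship features, lab tests are screened by
Welch's t-test, and each requested model family is evaluated over the three
nested feature sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .association import (
    MIN_SUPPORT,
    PairSupport,
    build_transactions,
    mine_frequent_pairs,
    selected_drugs as _pair_drugs,
)
from .cohort import CohortConfig, EventTable, generate_cohort
from .labstats import (
    SELECTION_ALPHA,
    compare_all_labs,
    select_significant_labs,
)
from .models import EvalReport, ModelConfig, run_cross_validation
from .preprocessing import FeatureTable, build_feature_table, filter_observation_window
from .sofa import label_cohort
from .vectorization import relationship_block_for_visits


@dataclass
class PipelineResult:
    events: EventTable
    labels: pd.DataFrame
    label_agreement: float
    feature_table: FeatureTable
    pairs_by_group: dict[str, list[PairSupport]]
    selected_drugs: list[str]
    lab_comparisons: list
    selected_labs: list[str]
    relationship_block: pd.DataFrame | None
    reports: dict[tuple[str, str], EvalReport] = field(default_factory=dict)

    def feature_matrix(self, feature_set: str):
        ft = self.feature_table
        cols = ft.columns_from("ehr")
        if feature_set in ("ehr_drug", "ehr_drug_lab") and self.relationship_block is not None:
            X = pd.concat(
                [ft.X[cols].reset_index(drop=True), self.relationship_block], axis=1
            )
        else:
            X = ft.X[cols].copy()
        if feature_set == "ehr_drug_lab":
            lab_cols = [f"lab_{l}" for l in self.selected_labs if f"lab_{l}" in ft.X.columns]
            X = pd.concat([X, ft.X[lab_cols].reset_index(drop=True)], axis=1)
        return X


def label_agreement(labels: pd.DataFrame, ground_truth: pd.DataFrame) -> float:
    """Fraction of visits whose Sepsis-3 label matches generator ground truth."""
    merged = labels.merge(ground_truth, on=["patient_id", "visit_id"])
    expected = merged["group"].map({"sepsis": "sepsis", "control": "nonsepsis"})
    return float((merged["label"] == expected).mean())


def mine_groups(
    events: EventTable,
    labels: pd.DataFrame,
    min_support: float = MIN_SUPPORT,
) -> dict[str, list[PairSupport]]:
    """Mine same-day co-prescription pairs separately per recovered group,
    over observation-window prescriptions only."""
    er_by_visit = events.visits.set_index("visit_id")["er_visit_time"]
    rx_parts = []
    for vid, rx in events.prescriptions.groupby("visit_id", sort=False):
        rx_parts.append(
            filter_observation_window(rx, er_by_visit[vid], time_column="timestamp")
        )
    rx_window = (
        pd.concat(rx_parts, ignore_index=True) if rx_parts else events.prescriptions.iloc[0:0]
    )
    label_by_visit = labels.set_index("visit_id")["label"]
    out: dict[str, list[PairSupport]] = {}
    for group, want in (("sepsis", "sepsis"), ("control", "nonsepsis")):
        vids = label_by_visit.index[label_by_visit == want]
        rx_g = rx_window[rx_window["visit_id"].isin(set(vids))]
        tx = build_transactions(rx_g)
        out[group] = mine_frequent_pairs(tx, min_support) if tx.n_transactions else []
    return out


def run_analysis(
    config: CohortConfig | None = None,
    seed: int = 0,
    families: tuple[str, ...] = ("random_forest",),
    feature_sets: tuple[str, ...] = ("ehr_only", "ehr_drug", "ehr_drug_lab"),
    n_folds: int = 5,
    min_support: float = MIN_SUPPORT,
    alpha: float = SELECTION_ALPHA,
    model_hyperparameters: dict | None = None,
) -> PipelineResult:
    """Run the full synthetic study once; see module docstring."""
    if config is None:
        config = CohortConfig(seed=seed)
    else:
        config = CohortConfig(**{**config.__dict__, "seed": seed})
    events = generate_cohort(config)
    antibiotic_ids = [d.drug_id for d in config.drug_catalog if d.is_antibiotic]
    labels = label_cohort(events, antibiotic_ids=antibiotic_ids)
    agreement = label_agreement(labels, events.ground_truth)

    feature_table = build_feature_table(events, labels)

    pairs_by_group = mine_groups(events, labels, min_support)
    union_drugs = sorted(
        set(_pair_drugs(pairs_by_group["sepsis"])) | set(_pair_drugs(pairs_by_group["control"]))
    )
    block = None
    if len(union_drugs) >= 2:
        block = relationship_block_for_visits(events, feature_table.index, union_drugs)

    lab_cols = feature_table.columns_from("lab")
    comparisons = compare_all_labs(
        feature_table.X[lab_cols].rename(columns=lambda c: c.removeprefix("lab_")),
        feature_table.y,
    )
    sig_labs = select_significant_labs(comparisons, alpha=alpha)

    result = PipelineResult(
        events=events,
        labels=labels,
        label_agreement=agreement,
        feature_table=feature_table,
        pairs_by_group=pairs_by_group,
        selected_drugs=union_drugs,
        lab_comparisons=comparisons,
        selected_labs=sig_labs,
        relationship_block=block,
    )
    hp = model_hyperparameters or {}
    for family in families:
        for fs in feature_sets:
            cfg = ModelConfig(
                family=family,
                hyperparameters=hp.get(family, {}),
                feature_set=fs,
                seed=seed,
            )
            X = result.feature_matrix(fs)
            result.reports[(family, fs)] = run_cross_validation(
                X, feature_table.y, cfg, n_folds=n_folds
            )
    return result
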