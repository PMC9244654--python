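"""Drug-pair relationship vectors: (I, H, T) per pair, per visit.

Each drug selected by the association analysis is weighted by its
prescription frequency in the observation window (number of distinct days it
was prescribed).  For a pair with frequencies (x, y) the relationship is
summarized by three scalars:

    I = x * y              level of interaction
    H = 2xy / (x + y)      harmonic mean — overall intensity, sensitive to
                           the weaker member (0 when either is absent)
    T = arctan2(y, x)      geometric angle of the pair, in [0, pi/2] —
                           scale-invariant balance between the two drugs

The triple (0, 0) maps to (0, 0, 0).  The published algebra for these three
summaries is not printed legibly in the source study; these forms are this
package's reconstruction of the verbal definitions and are injected through
a strategy hook (``formulas=``) so alternatives can be swapped in.

With k selected drugs the feature block has 3 * C(k, 2) columns in fixed
lexicographic pair order (k = 31 gives 465 pairs, 1395 columns).
"""

from __future__ import annotations

import itertools
import math
from typing import Callable, Iterable, Mapping

import numpy as np
import pandas as pd

from sklearn.base import BaseEstimator, TransformerMixin


class VectorizationError(ValueError):
    pass


def default_formulas(x: float, y: float) -> tuple[float, float, float]:
    """(I, H, T) for one pair of nonnegative prescription frequencies."""
    if x < 0 or y < 0:
        raise VectorizationError("frequencies must be nonnegative")
    i_value = x * y
    h_value = 0.0 if x + y == 0 else 2.0 * x * y / (x + y)
    t_value = 0.0 if x == y == 0 else math.atan2(y, x)
    return i_value, h_value, t_value


#: signature of a pluggable pair-summary strategy
PairFormulas = Callable[[float, float], tuple[float, float, float]]


def vectorize_pair(x: float, y: float, formulas: PairFormulas = default_formulas):
    return formulas(x, y)


def compute_drug_frequencies(
    prescriptions: pd.DataFrame, selected_drugs: Iterable[str]
) -> dict[str, int]:
    """Distinct prescription days per selected drug (window-filtered input)."""
    sel = set(selected_drugs)
    rx = prescriptions[prescriptions["drug_id"].isin(sel)]
    if rx.empty:
        return {}
    return (
        rx.groupby("drug_id")["date"].nunique().astype(int).to_dict()
    )


def pair_columns(selected_drugs: Iterable[str]) -> list[str]:
    """Fixed column order: lexicographic pairs × (I, H, T)."""
    drugs = sorted(set(selected_drugs))
    cols = []
    for a, b in itertools.combinations(drugs, 2):
        cols.extend([f"{a}__{b}__I", f"{a}__{b}__H", f"{a}__{b}__T"])
    return cols


class DrugRelationshipVectorizer(BaseEstimator, TransformerMixin):
    """Transformer: per-visit drug frequencies -> (I, H, T) feature block.

    Parameters
    ----------
    selected_drugs : the k >= 2 drugs to pair (union of the per-group
        association selections).
    formulas : pair-summary strategy, default :func:`default_formulas`.

    ``transform`` accepts a list/Series of frequency mappings
    (drug -> day count) and returns a DataFrame with 3*C(k,2) columns.
    """

    def __init__(self, selected_drugs=None, formulas: PairFormulas = default_formulas):
        self.selected_drugs = selected_drugs
        self.formulas = formulas

    def fit(self, X=None, y=None):
        drugs = sorted(set(self.selected_drugs or []))
        if len(drugs) < 2:
            raise VectorizationError("need at least 2 selected drugs to pair")
        self.drugs_ = drugs
        self.pairs_ = list(itertools.combinations(drugs, 2))
        self.columns_ = pair_columns(drugs)
        return self

    def transform(self, X: Iterable[Mapping[str, int]]) -> pd.DataFrame:
        if not hasattr(self, "drugs_"):
            self.fit()
        profiles = list(X)
        rows = np.zeros((len(profiles), len(self.columns_)))
        for r, freq in enumerate(profiles):
            for c, (a, b) in enumerate(self.pairs_):
                x = float(freq.get(a, 0))
                y = float(freq.get(b, 0))
                rows[r, 3 * c : 3 * c + 3] = self.formulas(x, y)
        return pd.DataFrame(rows, columns=self.columns_)


def build_relationship_features(
    profiles: Iterable[Mapping[str, int]],
    selected_drugs: Iterable[str],
    formulas: PairFormulas = default_formulas,
) -> pd.DataFrame:
    """Functional wrapper: k drugs -> 3*C(k,2)-column block, one row/profile."""
    vec = DrugRelationshipVectorizer(list(selected_drugs), formulas).fit()
    return vec.transform(list(profiles))


def relationship_block_for_visits(
    events,
    visit_index: pd.DataFrame,
    selected_drugs: Iterable[str],
    window_days: tuple[float, float] = (2.0, 7.0),
    formulas: PairFormulas = default_formulas,
) -> pd.DataFrame:
    """(I, H, T) block aligned with a feature table's (patient, visit) rows."""
    from .preprocessing import filter_observation_window

    rx_by_visit = dict(tuple(events.prescriptions.groupby("visit_id", sort=False)))
    er_by_visit = events.visits.set_index("visit_id")["er_visit_time"]
    profiles = []
    for _, row in visit_index.iterrows():
        rx = rx_by_visit.get(row["visit_id"])
        if rx is None:
            profiles.append({})
            continue
        rx_in = filter_observation_window(
            rx, er_by_visit[row["visit_id"]], time_column="timestamp", window_days=window_days
        )
        profiles.append(compute_drug_frequencies(rx_in, selected_drugs))
    return build_relationship_features(profiles, selected_drugs, formulas)
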