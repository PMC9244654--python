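"""Group comparison of lab-test distributions and biomarker selection.

Each lab test is compared between the sepsis and control groups with a
two-sided Welch (unequal-variance) t-test; p-values map to significance
tiers and labs below a selection threshold (default alpha = .001, per-test,
uncorrected) become model features.  An optional Bonferroni correction is
available but off by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

#: tier thresholds, most stringent last; the symbol of the smallest
#: satisfied threshold is reported.
DEFAULT_TIER_MAP: tuple[tuple[float, str], ...] = (
    (0.05, "*"),
    (0.005, "**"),
    (0.001, "***"),
    (0.0001, "****"),
)

SELECTION_ALPHA = 0.001


class LabStatsError(ValueError):
    pass


@dataclass(frozen=True)
class LabComparison:
    lab_type: str
    mean_sepsis: float
    sd_sepsis: float
    n_sepsis: int
    mean_control: float
    sd_control: float
    n_control: int
    t_statistic: float
    p_value: float
    tier: str


def compare_lab_distributions(
    values_sepsis, values_control, lab_type: str = "", tier_map=DEFAULT_TIER_MAP
) -> LabComparison:
    """Welch two-sided t-test between the groups' finite lab values."""
    a = np.asarray(values_sepsis, dtype=float)
    b = np.asarray(values_control, dtype=float)
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if len(a) < 2 or len(b) < 2:
        raise LabStatsError(f"lab {lab_type!r}: each group needs >= 2 finite values")
    t, p = stats.ttest_ind(a, b, equal_var=False)
    # identical degenerate samples: define the null result explicitly
    if np.isnan(t):
        t, p = 0.0, 1.0
    return LabComparison(
        lab_type=lab_type,
        mean_sepsis=float(a.mean()),
        sd_sepsis=float(a.std(ddof=1)),
        n_sepsis=len(a),
        mean_control=float(b.mean()),
        sd_control=float(b.std(ddof=1)),
        n_control=len(b),
        t_statistic=float(t),
        p_value=float(p),
        tier=assign_significance_tier(float(p), tier_map),
    )


def assign_significance_tier(p_value: float, tier_map=DEFAULT_TIER_MAP) -> str:
    """Most stringent satisfied tier symbol, or ``NS``.

    ``tier_map`` is a sequence of (threshold, symbol) with strictly
    decreasing thresholds; the tier is the symbol of the smallest threshold
    with p < threshold.
    """
    thresholds = [t for t, _ in tier_map]
    if any(b >= a for a, b in zip(thresholds, thresholds[1:])):
        raise LabStatsError("tier thresholds must be strictly decreasing")
    tier = "NS"
    for threshold, symbol in tier_map:
        if p_value < threshold:
            tier = symbol
        else:
            break
    return tier


def compare_all_labs(
    labs_wide: pd.DataFrame,
    y: pd.Series,
    tier_map=DEFAULT_TIER_MAP,
) -> list[LabComparison]:
    """Compare every column of a wide lab table (rows aligned with y; 1=sepsis)."""
    y = np.asarray(y).astype(int)
    out = []
    for col in labs_wide.columns:
        v = labs_wide[col].to_numpy(dtype=float)
        out.append(
            compare_lab_distributions(v[y == 1], v[y == 0], lab_type=col, tier_map=tier_map)
        )
    return out


def select_significant_labs(
    comparisons: list[LabComparison],
    alpha: float = SELECTION_ALPHA,
    bonferroni: bool = False,
) -> list[str]:
    """Lab types with p < alpha (optionally Bonferroni-adjusted), sorted by
    (p ascending, name) for a deterministic order."""
    if not 0.0 < alpha <= 1.0:
        raise LabStatsError("alpha must be in (0, 1]")
    cutoff = alpha / len(comparisons) if (bonferroni and comparisons) else alpha
    hits = [c for c in comparisons if c.p_value < cutoff]
    hits.sort(key=lambda c: (c.p_value, c.lab_type))
    return [c.lab_type for c in hits]


def comparisons_to_frame(comparisons: list[LabComparison], selected=None) -> pd.DataFrame:
    sel = set(selected or [])
    return pd.DataFrame(
        [
            {
                "lab_type": c.lab_type,
                "mean_sepsis": c.mean_sepsis,
                "sd_sepsis": c.sd_sepsis,
                "n_sepsis": c.n_sepsis,
                "mean_control": c.mean_control,
                "sd_control": c.sd_control,
                "n_control": c.n_control,
                "t": c.t_statistic,
                "p": c.p_value,
                "tier": c.tier,
                "selected": c.lab_type in sel,
            }
            for c in comparisons
        ]
    )
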