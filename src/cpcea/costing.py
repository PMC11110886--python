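"""Societal cost accounting: component aggregation, productivity valuation,
arm-level summaries and between-arm comparison.

Costs are organised in three categories, all in 2020 AUD:

* direct intervention — camp registration, healthcare staff salaries;
* direct non-intervention — accommodation/travel, camp consumables;
* indirect — camp catering plus caregiver productivity losses, the
  latter valued as workdays missed times the caregiver's median daily
  earnings stratum.

Arm-level summaries report medians and interquartile ranges (costs are
right-skewed) and compare arms with the Mann-Whitney U test.  Components
that are deterministic in both arms (e.g. a fixed camp fee vs. zero) are
reported without a p-value, marked not-applicable.  No discounting is
applied over the 13-week horizon.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

from .errors import EarningsLookupError, ValidationError

CATEGORIES = {
    "direct_intervention": ["registration", "staff_salary"],
    "direct_nonintervention": ["accommodation_travel", "consumables"],
    "indirect": ["catering", "productivity_cost"],
}
COMPONENT_ORDER = [c for comps in CATEGORIES.values() for c in comps]

#: quantile rule used everywhere: linear interpolation between order stats
QUANTILE_METHOD = "linear"


def load_earnings_table(path=None) -> pd.DataFrame:
    """Daily median earnings by (age_band, sex, education_band).

    With no path, loads the packaged synthetic table — a constructed
    stand-in with plausible 2020 AUD magnitudes, not national survey
    figures.  Returns a frame indexed by the three key columns.
    """
    if path is None:
        ref = resources.files("cpcea.data").joinpath("earnings_table_synthetic.csv")
        with ref.open() as fh:
            table = pd.read_csv(fh)
    else:
        table = pd.read_csv(path)
    if (table["daily_earnings"] <= 0).any():
        raise ValidationError("daily_earnings: all earnings must be positive")
    return table.set_index(["age_band", "sex", "education_band"])


def productivity_cost(days_missed: float, caregiver_key, table: pd.DataFrame) -> float:
    """Value caregiver workdays lost: days x daily median earnings (AUD)."""
    if days_missed < 0:
        raise ValidationError("days_missed: must be >= 0")
    key = tuple(caregiver_key)
    try:
        rate = float(table.loc[key, "daily_earnings"])
    except KeyError:
        raise EarningsLookupError(key) from None
    return days_missed * rate


def aggregate_ledger(costs: pd.DataFrame) -> pd.DataFrame:
    """Add category subtotals and the societal total to a per-child ledger.

    Requires the six component columns; subtotals sum components within
    category and ``total`` sums the three subtotals.  Additive: scaling
    all components by c scales every subtotal and the total by c.
    """
    missing = [c for c in COMPONENT_ORDER if c not in costs.columns]
    if missing:
        raise ValidationError(f"cost ledger missing components: {missing}")
    comp = costs[COMPONENT_ORDER].astype(float)
    if (comp.to_numpy() < 0).any():
        bad = comp.columns[(comp < 0).any()][0]
        raise ValidationError(f"negative amount in component {bad!r}")
    out = costs.copy()
    for cat, comps in CATEGORIES.items():
        out[cat] = comp[comps].sum(axis=1)
    out["total"] = out[list(CATEGORIES)].sum(axis=1)
    return out


@dataclass(frozen=True)
class MannWhitneyResult:
    u: float  # U statistic for the first sample: #(a > b) + ties/2
    p: float  # two-sided, normal approximation with tie correction
    degenerate: bool = False


def mann_whitney(a, b) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U comparison of two independent samples.

    U for the first sample equals the number of (a, b) pairs with a > b
    plus half the tied pairs.  The p-value uses the normal approximation
    with tie correction (and continuity correction).  A pooled sample
    with no variation at all cannot be tested; it is reported as p = 1
    with the ``degenerate`` flag set.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("mann_whitney: both samples must be nonempty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return MannWhitneyResult(u=a.size * b.size / 2.0, p=1.0, degenerate=True)
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return MannWhitneyResult(u=float(res.statistic), p=float(res.pvalue))


def _quantiles(x: np.ndarray) -> tuple[float, float, float]:
    q1, med, q3 = np.quantile(x, [0.25, 0.5, 0.75], method=QUANTILE_METHOD)
    return float(med), float(q1), float(q3)


def summarize_costs(costs: pd.DataFrame) -> pd.DataFrame:
    """Arm-level cost table: median (IQR) per component/subtotal/total.

    ``costs`` must carry an ``arm`` column plus the six components (the
    subtotals are recomputed here).  Output is tidy: one row per line
    item with per-arm median/q1/q3 and the Mann-Whitney p-value, or NaN
    with ``comparison = 'not_applicable'`` where both arms are
    deterministic.
    """
    if "arm" not in costs.columns:
        raise ValidationError("cost table needs an 'arm' column")
    agg = aggregate_ledger(costs)
    arms = ("intervention", "control")
    for arm in arms:
        if not (agg["arm"] == arm).any():
            raise ValidationError(f"empty arm {arm!r} in cost table")

    lines = []
    for cat, comps in CATEGORIES.items():
        lines.extend([(c, "component", cat) for c in comps])
        lines.append((cat, "subtotal", cat))
    lines.append(("total", "total", ""))

    rows = []
    for name, level, cat in lines:
        vals = {arm: agg.loc[agg["arm"] == arm, name].to_numpy() for arm in arms}
        row = {"item": name, "level": level, "category": cat}
        for arm in arms:
            med, q1, q3 = _quantiles(vals[arm])
            row[f"{arm}_median"] = med
            row[f"{arm}_q1"] = q1
            row[f"{arm}_q3"] = q3
        const = {arm: np.all(v == v[0]) for arm, v in vals.items()}
        if const["intervention"] and const["control"]:
            # both arms deterministic (fixed fee vs zero): nothing to test
            if vals["intervention"][0] == vals["control"][0]:
                row["p_value"], row["comparison"] = 1.0, "degenerate"
            else:
                row["p_value"], row["comparison"] = np.nan, "not_applicable"
        else:
            mw = mann_whitney(vals["intervention"], vals["control"])
            row["p_value"] = mw.p
            row["comparison"] = "degenerate" if mw.degenerate else "mann_whitney"
        rows.append(row)
    return pd.DataFrame(rows)
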