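"""Scoring of the CPQoL-Child parent-proxy questionnaire.

The instrument has 66 items answered on a 1-9 Likert scale, partitioned
into 7 domains.  Scoring is two-stage: each raw item response is rescaled
to 0-100 by the unique affine map through the anchors (1 -> 0, 9 -> 100),
then a domain score is the mean of its available rescaled items.  For
every domain except Pain and Impact of Disability a higher score means
better quality of life; domain scores are reported on their native scale
and orientation is applied only in the cost-effectiveness stage.

The item -> domain allocation is not part of the published scoring key
available to us; the shipped partition (see ``data/instrument_map.csv``)
is a documented placeholder whose domain sizes are configurable.  All
downstream analyses depend only on domain scores, not on which specific
item sits in which domain.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .errors import InputFormatError, ValidationError

#: points per Likert step on the 0-100 scale: (9 - 1) steps span 100 points
ITEM_STEP = 12.5

HIGHER_IS_BETTER = "higher_is_better"
LOWER_IS_BETTER = "lower_is_better"

#: canonical domain keys -> display names
DOMAIN_NAMES = {
    "functioning": "Feelings about Functioning",
    "participation_physical": "Participation and Physical Health",
    "access_services": "Access to Services",
    "emotional_wellbeing": "Emotional Well-Being",
    "family_health": "Family Health",
    "pain_disability": "Pain and Impact of Disability",
    "social_wellbeing": "Social Well-Being and Acceptance",
}

DOMAINS = tuple(DOMAIN_NAMES)

BASELINE = "baseline"
FOLLOWUP = "week13"
TIMEPOINTS = (BASELINE, FOLLOWUP)


@dataclass(frozen=True)
class InstrumentMap:
    """Item -> domain allocation plus per-domain orientation flags.

    ``table`` has one row per item with columns ``item_id``, ``domain``
    and ``orientation``.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        required = {"item_id", "domain", "orientation"}
        if not required.issubset(t.columns):
            raise InputFormatError(f"instrument map needs columns {sorted(required)}")
        if t["item_id"].duplicated().any():
            raise ValidationError("instrument map assigns an item to more than one domain")
        missing_domains = set(DOMAINS) - set(t["domain"])
        if missing_domains:
            raise ValidationError(f"instrument map leaves domains empty: {sorted(missing_domains)}")
        bad = set(t["domain"]) - set(DOMAINS)
        if bad:
            raise ValidationError(f"unknown domains in instrument map: {sorted(bad)}")
        low = set(t.loc[t["orientation"] == LOWER_IS_BETTER, "domain"])
        if low != {"pain_disability"}:
            raise ValidationError(
                "exactly the pain_disability domain must carry lower_is_better orientation"
            )

    @classmethod
    def default(cls) -> "InstrumentMap":
        """Load the shipped 66-item partition (placeholder allocation)."""
        ref = resources.files("cpcea.data").joinpath("instrument_map.csv")
        with ref.open() as fh:
            return cls(pd.read_csv(fh))

    @classmethod
    def from_csv(cls, path) -> "InstrumentMap":
        return cls(pd.read_csv(path))

    @property
    def item_ids(self) -> list[str]:
        return list(self.table["item_id"])

    def items(self, domain: str) -> list[str]:
        return list(self.table.loc[self.table["domain"] == domain, "item_id"])

    def orientation(self, domain: str) -> str:
        rows = self.table.loc[self.table["domain"] == domain, "orientation"]
        if rows.empty:
            raise ValidationError(f"unknown domain {domain!r}")
        return rows.iloc[0]

    def n_items(self, domain: str) -> int:
        return int((self.table["domain"] == domain).sum())


def scale_item(raw):
    """Rescale a raw 1-9 response to the 0-100 scale.

    The unique affine map through the anchors: scale_item(1) = 0,
    scale_item(9) = 100, i.e. (raw - 1) * 12.5.  Accepts scalars or
    arrays; missing values (NaN) pass through.
    """
    arr = np.asarray(raw, dtype=float)
    valid = np.isnan(arr) | ((arr >= 1) & (arr <= 9) & (arr == np.round(arr)))
    if not np.all(valid):
        raise ValidationError("raw item responses must be integers in 1..9")
    out = (arr - 1.0) * ITEM_STEP
    return float(out) if np.isscalar(raw) else out


def score_domain(
    responses: dict,
    imap: InstrumentMap,
    domain: str,
    completeness_threshold: float = 0.5,
) -> float:
    """Score one domain for one child at one timepoint.

    ``responses`` maps item_id -> raw value (1-9) or NaN/None for
    missing.  Returns the mean of the rescaled available items when the
    answered fraction reaches ``completeness_threshold``; NaN otherwise
    (missing is a value here, not an error).
    """
    items = imap.items(domain)
    if not items:
        raise ValidationError(f"unknown domain {domain!r}")
    vals = np.array(
        [np.nan if responses.get(i) is None else float(responses.get(i, np.nan)) for i in items]
    )
    scaled = scale_item(vals)
    n_ok = int(np.sum(~np.isnan(scaled)))
    if n_ok / len(items) < completeness_threshold or n_ok == 0:
        return float("nan")
    return float(np.nanmean(scaled))


def score_dataset(
    items_long: pd.DataFrame,
    imap: InstrumentMap,
    completeness_threshold: float = 0.5,
) -> pd.DataFrame:
    """Score every (child, timepoint) in a long-format response table.

    ``items_long`` has columns ``child_id``, ``timepoint``, ``item_id``,
    ``response`` (raw 1-9, NaN for missing).  Returns a wide frame
    indexed by (child_id, timepoint) with one column per domain; cells
    are NaN where a domain fails the completeness rule.
    """
    required = {"child_id", "timepoint", "item_id", "response"}
    if not required.issubset(items_long.columns):
        raise InputFormatError(f"items table needs columns {sorted(required)}")
    dup = items_long.duplicated(subset=["child_id", "timepoint", "item_id"])
    if dup.any():
        first = items_long.loc[dup].iloc[0]
        raise InputFormatError(
            "duplicate response row for "
            f"({first['child_id']}, {first['timepoint']}, {first['item_id']})"
        )
    unknown = set(items_long["item_id"]) - set(imap.item_ids)
    if unknown:
        raise InputFormatError(f"responses for items not in the instrument map: {sorted(unknown)[:5]}")

    wide = items_long.pivot(index=["child_id", "timepoint"], columns="item_id", values="response")
    scaled = pd.DataFrame(scale_item(wide.to_numpy()), index=wide.index, columns=wide.columns)

    out = {}
    for domain in DOMAINS:
        cols = [c for c in imap.items(domain) if c in scaled.columns]
        n_total = imap.n_items(domain)
        block = scaled[cols] if cols else pd.DataFrame(index=scaled.index)
        n_ok = block.notna().sum(axis=1)
        means = block.mean(axis=1)
        means[n_ok / n_total < completeness_threshold] = np.nan
        means[n_ok == 0] = np.nan
        out[domain] = means
    result = pd.DataFrame(out)
    result.columns.name = None
    return result
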