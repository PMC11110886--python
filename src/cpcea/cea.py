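"""Incremental cost-effectiveness: ICERs, dominance classification,
nonparametric bootstrap uncertainty intervals, net monetary benefit and
cost-effectiveness acceptability curves.

Conventions.  Incremental quantities are intervention minus control.
``delta_E`` keeps the instrument's native sign; the orientation-corrected
benefit ``effective_delta_E`` equals ``delta_E`` for higher-is-better
domains and ``-delta_E`` for the lower-is-better pain domain.  The
(delta_C, effective_delta_E) plane is partitioned as:

* dominant      — cheaper and more effective (delta_C < 0, benefit > 0);
* dominated     — costlier and less effective (delta_C > 0, benefit < 0);
* tradeoff_NE   — costlier and more effective: ICER = delta_C / benefit;
* tradeoff_SW   — cheaper and less effective (savings per unit lost);
* undefined     — zero benefit with nonzero cost difference (no ratio).

Uncertainty is quantified by resampling children with replacement within
each arm at the original arm sizes, keeping each child's (cost, effect)
pair intact; run over an imputation set, the per-dataset replicate sets
are stacked before percentile extraction.  Uncertainty intervals are
equal-tail percentiles of the per-replicate ICERs — the convention that
yields the published-style sign-crossing intervals; replicates with an
undefined ratio are excluded with a logged count, and quadrant counts
plus the CEAC (which needs no ratio at all) are reported alongside as
the stable complement.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cpqol import HIGHER_IS_BETTER, LOWER_IS_BETTER
from .errors import ValidationError

DOMINANT = "dominant"
DOMINATED = "dominated"
TRADEOFF_NE = "tradeoff_NE"
TRADEOFF_SW = "tradeoff_SW"
UNDEFINED = "undefined"


def effective_effect(delta_E: float, orientation: str):
    """Orientation-corrected benefit: sign-flip lower-is-better domains."""
    if orientation == HIGHER_IS_BETTER:
        return delta_E
    if orientation == LOWER_IS_BETTER:
        return -delta_E
    raise ValidationError(f"unknown orientation {orientation!r}")


def classify(delta_C: float, effective_delta_E: float) -> str:
    """Dominance label for one point of the incremental plane.

    Boundaries: zero benefit with nonzero cost is 'undefined' (no ratio
    exists); zero cost difference falls with the trade-off quadrant of
    its benefit sign (ICER 0 when beneficial); the origin is undefined.
    """
    if effective_delta_E > 0:
        return DOMINANT if delta_C < 0 else TRADEOFF_NE
    if effective_delta_E < 0:
        return DOMINATED if delta_C > 0 else TRADEOFF_SW
    return UNDEFINED


@dataclass(frozen=True)
class IcerOutcome:
    classification: str
    icer: float | None  # AUD per orientation-corrected QoL unit; None when no ratio is reported
    delta_C: float
    delta_E: float
    effective_delta_E: float
    orientation: str

    @property
    def label(self) -> str:
        """Display form: whole-AUD ICER, or the dominance word."""
        if self.classification == TRADEOFF_NE:
            return str(display_round(self.icer))
        return {DOMINANT: "Dominant", DOMINATED: "Dominated",
                TRADEOFF_SW: "Trade-off (SW)", UNDEFINED: "Undefined"}[self.classification]


def display_round(x: float) -> int:
    """Round half away from zero to whole AUD for display."""
    return int(np.sign(x) * np.floor(abs(x) + 0.5))


def compute_icer(delta_C: float, delta_E: float, orientation: str = HIGHER_IS_BETTER) -> IcerOutcome:
    """Classify an incremental point and form its ICER where defined.

    The ratio delta_C / effective_delta_E is reported for the
    costlier-and-better quadrant (including the zero-cost boundary,
    where it is 0); dominance labels replace the ratio elsewhere.
    When the benefit is exactly zero with a nonzero cost difference the
    ratio is undefined and flagged as such, never reported as infinity.
    """
    if not (np.isfinite(delta_C) and np.isfinite(delta_E)):
        raise ValidationError("delta_C and delta_E must be finite")
    eff = effective_effect(delta_E, orientation)
    cls = classify(delta_C, eff)
    icer = delta_C / eff if cls == TRADEOFF_NE else None
    return IcerOutcome(
        classification=cls, icer=icer, delta_C=delta_C, delta_E=delta_E,
        effective_delta_E=eff, orientation=orientation,
    )


def incremental_estimates(costs_int, costs_ctl, effects_int, effects_ctl, orientation: str):
    """Point estimates (delta_C, delta_E, effective_delta_E) from arm data."""
    ci, cc = np.asarray(costs_int, float), np.asarray(costs_ctl, float)
    ei, ec = np.asarray(effects_int, float), np.asarray(effects_ctl, float)
    for arr, name in ((ci, "costs_int"), (cc, "costs_ctl"), (ei, "effects_int"), (ec, "effects_ctl")):
        if arr.size == 0:
            raise ValidationError(f"{name}: empty arm")
    delta_C = float(ci.mean() - cc.mean())
    delta_E = float(ei.mean() - ec.mean())
    return delta_C, delta_E, effective_effect(delta_E, orientation)


@dataclass
class BootstrapReplicates:
    """B resampled (delta_C_b, delta_E_b) pairs with seed provenance."""

    delta_C: np.ndarray
    delta_E: np.ndarray
    orientation: str
    seed: int
    stacked_over_imputations: bool = False
    excluded_undefined: int = field(default=0)

    @property
    def b(self) -> int:
        return self.delta_C.size

    @property
    def effective_delta_E(self) -> np.ndarray:
        if self.orientation == HIGHER_IS_BETTER:
            return self.delta_E
        if self.orientation == LOWER_IS_BETTER:
            return -self.delta_E
        raise ValidationError(f"unknown orientation {self.orientation!r}")

    def quadrant_counts(self) -> dict:
        eff = self.effective_delta_E
        return {
            DOMINANT: int(np.sum((self.delta_C < 0) & (eff > 0))),
            TRADEOFF_NE: int(np.sum((self.delta_C >= 0) & (eff > 0))),
            DOMINATED: int(np.sum((self.delta_C > 0) & (eff < 0))),
            TRADEOFF_SW: int(np.sum((self.delta_C <= 0) & (eff < 0))),
            UNDEFINED: int(np.sum(eff == 0)),
        }


def _as_effect_sets(effects) -> tuple[list[np.ndarray], bool]:
    """Normalise effects to a list of per-dataset arrays.

    A sequence whose elements are themselves arrays is an imputation
    stack; a flat sequence of numbers is a single dataset.
    """
    if isinstance(effects, (list, tuple)) and len(effects) and np.ndim(effects[0]) >= 1:
        return [np.asarray(e, float) for e in effects], True
    return [np.asarray(effects, float)], False


def bootstrap_cea(
    costs_int,
    costs_ctl,
    effects_int,
    effects_ctl,
    orientation: str,
    b: int = 10000,
    seed: int = 0,
) -> BootstrapReplicates:
    """Within-arm nonparametric bootstrap of (delta_C, delta_E).

    Children are resampled with replacement independently within each
    arm at the original arm sizes; each child keeps their (cost, effect)
    pair.  ``effects_*`` may be a list of m arrays (one per completed
    imputation), in which case b replicates are drawn within each
    completed dataset and stacked into m*b pairs.
    """
    if b < 1:
        raise ValidationError("b: need at least one bootstrap replicate")
    eff_int_sets, stacked = _as_effect_sets(effects_int)
    eff_ctl_sets, _ = _as_effect_sets(effects_ctl)
    if len(eff_int_sets) != len(eff_ctl_sets):
        raise ValidationError("effects_int and effects_ctl must have the same number of datasets")
    ci = np.asarray(costs_int, float)
    cc = np.asarray(costs_ctl, float)
    if ci.size == 0 or cc.size == 0:
        raise ValidationError("bootstrap_cea: empty arm")

    rng = np.random.default_rng(seed)
    dc_all, de_all = [], []
    for ei, ec in zip(eff_int_sets, eff_ctl_sets):
        ei = np.asarray(ei, float)
        ec = np.asarray(ec, float)
        if ei.size != ci.size or ec.size != cc.size:
            raise ValidationError("cost and effect arrays must align child-for-child within arm")
        idx_i = rng.integers(0, ci.size, size=(b, ci.size))
        idx_c = rng.integers(0, cc.size, size=(b, cc.size))
        dc_all.append(ci[idx_i].mean(axis=1) - cc[idx_c].mean(axis=1))
        de_all.append(ei[idx_i].mean(axis=1) - ec[idx_c].mean(axis=1))
    return BootstrapReplicates(
        delta_C=np.concatenate(dc_all),
        delta_E=np.concatenate(de_all),
        orientation=orientation,
        seed=seed,
        stacked_over_imputations=stacked,
    )


def replicate_icers(reps: BootstrapReplicates) -> tuple[np.ndarray, int]:
    """Per-replicate ratios delta_C_b / effective_delta_E_b.

    Replicates with exactly zero benefit have no ratio; they are dropped
    and counted (the count is logged on the replicate set).  Ratios from
    dominated/SW quadrants are retained — the naive-percentile convention
    that produces sign-crossing intervals.
    """
    eff = reps.effective_delta_E
    defined = eff != 0.0
    excluded = int(np.sum(~defined))
    reps.excluded_undefined = excluded
    return reps.delta_C[defined] / eff[defined], excluded


def percentile_ui(values, level: float = 0.95) -> tuple[float, float]:
    """Equal-tail percentile interval (linear-interpolation quantiles)."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        if v.size == 1:
            return float(v[0]), float(v[0])
        raise ValidationError("percentile_ui needs at least one replicate")
    if not 0.0 < level < 1.0:
        raise ValidationError("level: must lie in (0, 1)")
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(v, [alpha, 1.0 - alpha], method="linear")
    return float(lo), float(hi)


@dataclass(frozen=True)
class IncrementalResult:
    """Full per-domain cost-effectiveness readout."""

    domain: str
    delta_C: float
    delta_E: float
    orientation: str
    effective_delta_E: float
    classification: str
    icer: float | None
    ui_low: float | None
    ui_high: float | None
    delta_C_ui: tuple[float, float]
    delta_E_ui: tuple[float, float]
    quadrants: dict
    excluded_undefined: int


def ceac(reps: BootstrapReplicates, wtp_grid) -> pd.DataFrame:
    """Cost-effectiveness acceptability curve over a willingness-to-pay grid.

    At each lambda the probability is the fraction of replicates with
    positive incremental net monetary benefit,
    lambda * effective_delta_E_b - delta_C_b > 0.  At lambda = 0 this is
    P(delta_C_b < 0); as lambda grows it approaches
    P(effective_delta_E_b > 0).
    """
    grid = np.asarray(wtp_grid, dtype=float)
    if grid.size == 0:
        raise ValidationError("wtp_grid: empty grid")
    if (grid < 0).any():
        raise ValidationError("wtp_grid: willingness-to-pay must be >= 0")
    if reps.b == 0:
        raise ValidationError("ceac: empty replicate set")
    grid = np.sort(grid)
    eff = reps.effective_delta_E
    nmb = grid[:, None] * eff[None, :] - reps.delta_C[None, :]
    prob = (nmb > 0).mean(axis=1)
    return pd.DataFrame({"wtp_lambda": grid, "probability": prob})


def evaluate_domain(
    domain: str,
    costs_int,
    costs_ctl,
    effects_int,
    effects_ctl,
    orientation: str,
    b: int = 10000,
    seed: int = 0,
    level: float = 0.95,
) -> tuple[IncrementalResult, BootstrapReplicates]:
    """Point estimates, classification, ICER and bootstrap UIs for one domain."""
    eff_int_sets, _ = _as_effect_sets(effects_int)
    eff_ctl_sets, _ = _as_effect_sets(effects_ctl)
    # point estimate pools the per-dataset arm means (Rubin Q-bar)
    d_c = float(np.mean(np.asarray(costs_int, float)) - np.mean(np.asarray(costs_ctl, float)))
    d_e = float(
        np.mean([np.mean(np.asarray(e, float)) for e in eff_int_sets])
        - np.mean([np.mean(np.asarray(e, float)) for e in eff_ctl_sets])
    )
    outcome = compute_icer(d_c, d_e, orientation)
    reps = bootstrap_cea(costs_int, costs_ctl, effects_int, effects_ctl, orientation, b=b, seed=seed)
    ratios, excluded = replicate_icers(reps)
    ui = percentile_ui(ratios, level) if ratios.size else (None, None)
    result = IncrementalResult(
        domain=domain,
        delta_C=d_c,
        delta_E=d_e,
        orientation=orientation,
        effective_delta_E=outcome.effective_delta_E,
        classification=outcome.classification,
        icer=outcome.icer,
        ui_low=ui[0],
        ui_high=ui[1],
        delta_C_ui=percentile_ui(reps.delta_C, level),
        delta_E_ui=percentile_ui(reps.delta_E, level),
        quadrants=reps.quadrant_counts(),
        excluded_undefined=excluded,
    )
    return result, reps
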