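"""Effect estimation: change scores, Welch difference-in-difference tests,
and the design-stage sample-size calculation.

Change is follow-up minus baseline on the 0-100 domain scale; the
between-arm contrast (difference-in-difference) is tested with an
unequal-variance (Welch) t-test using the Satterthwaite degrees of
freedom.  All seven domains are tested without multiplicity adjustment,
as every comparison is of standalone interest.  Sample SDs use the n-1
denominator throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import ValidationError


def change_score(baseline, followup):
    """Follow-up minus baseline; missing if either timepoint is missing.

    Accepts scalars or arrays of 0-100 domain scores; NaN propagates.
    """
    b = np.asarray(baseline, dtype=float)
    f = np.asarray(followup, dtype=float)
    with np.errstate(invalid="ignore"):
        ok_b = np.isnan(b) | ((b >= 0) & (b <= 100))
        ok_f = np.isnan(f) | ((f >= 0) & (f <= 100))
    if not (np.all(ok_b) and np.all(ok_f)):
        raise ValidationError("domain scores must lie in [0, 100]")
    out = f - b
    return float(out) if np.isscalar(baseline) and np.isscalar(followup) else out


def welch_from_stats(mean1, sd1, n1, mean2, sd2, n2):
    """Welch t statistic, Satterthwaite df and two-sided p from summaries.

    Zero-variance arms are allowed: with spread in only one arm the
    formulas degrade gracefully; with both arms degenerate the result is
    flagged by ``df = nan`` (t is 0 or +/-inf by the mean difference).
    """
    if n1 < 2 or n2 < 2:
        raise ValidationError("welch test needs at least 2 observations per arm")
    v1, v2 = sd1**2 / n1, sd2**2 / n2
    diff = mean1 - mean2
    if v1 + v2 == 0.0:
        t = 0.0 if diff == 0 else math.copysign(math.inf, diff)
        return t, math.nan, 1.0 if diff == 0 else 0.0
    t = diff / math.sqrt(v1 + v2)
    den = v1**2 / (n1 - 1) + v2**2 / (n2 - 1)
    # den can underflow to 0 for subnormal variances; fall back to pooled df
    df = (v1 + v2) ** 2 / den if den > 0 else float(n1 + n2 - 2)
    p = 2.0 * stats.t.sf(abs(t), df)
    return t, df, p


@dataclass(frozen=True)
class DiffInDiff:
    """Between-arm contrast of mean change scores for one domain."""

    mean_a: float
    sd_a: float
    n_a: int
    mean_b: float
    sd_b: float
    n_b: int
    difference: float  # mean_a - mean_b, exactly
    t: float
    df: float
    p: float
    degenerate: bool = False


def diff_in_diff(changes_a, changes_b) -> DiffInDiff:
    """Welch comparison of per-arm change scores (arm a minus arm b)."""
    a = np.asarray(changes_a, dtype=float)
    b = np.asarray(changes_b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if a.size < 2 or b.size < 2:
        raise ValidationError("diff_in_diff needs >= 2 children with change scores per arm")
    ma, mb = float(a.mean()), float(b.mean())
    sa, sb = float(a.std(ddof=1)), float(b.std(ddof=1))
    t, df, p = welch_from_stats(ma, sa, a.size, mb, sb, b.size)
    return DiffInDiff(
        mean_a=ma, sd_a=sa, n_a=a.size,
        mean_b=mb, sd_b=sb, n_b=b.size,
        difference=ma - mb, t=t, df=df, p=p,
        degenerate=sa == 0.0 and sb == 0.0,
    )


@dataclass(frozen=True)
class SampleSizeSpec:
    """Design inputs for a two-arm comparison of means."""

    delta: float  # minimum clinically important difference, instrument units
    sigma: float  # anticipated SD, same units
    alpha: float = 0.05  # two-sided type-I error
    power: float = 0.80

    def validate(self) -> "SampleSizeSpec":
        if self.delta <= 0:
            raise ValidationError("delta: must be positive")
        if self.sigma <= 0:
            raise ValidationError("sigma: must be positive")
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha: must lie in (0, 1)")
        if not 0 < self.power < 1:
            raise ValidationError("power: must lie in (0, 1)")
        return self


def required_n_per_group(spec: SampleSizeSpec) -> int:
    """Per-group n for a two-arm mean comparison, normal approximation.

    ceil( 2 (z_{1-alpha/2} + z_{power})^2 (sigma / delta)^2 ).  The
    convention is the plain normal-approximation formula with no
    small-sample t correction and no attrition inflation; software that
    rounds differently can print a neighbouring integer for the same
    inputs.
    """
    spec.validate()
    z_a = stats.norm.ppf(1.0 - spec.alpha / 2.0)
    z_b = stats.norm.ppf(spec.power)
    n = 2.0 * (z_a + z_b) ** 2 * (spec.sigma / spec.delta) ** 2
    return math.ceil(n - 1e-12)
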