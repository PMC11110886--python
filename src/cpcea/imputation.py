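"""Multiple imputation by chained equations and Rubin's-rules pooling.

Missing follow-up domain scores are imputed m times (default 10) with
chained equations; each variable's conditional model is predictive mean
matching (k = 5 donors) over the remaining analysis columns (baseline
scores, arm, age, sex), so imputed values are always drawn from observed
donors and stay in range.  Per-imputation estimates are combined with
Rubin's rules: pooled point estimate Q-bar, within-imputation variance
W-bar, between-imputation variance B and total variance
T = W-bar + (1 + 1/m) B.

The chained-equation engine is statsmodels' MICEData; it draws from
numpy's global RandomState, so imputation runs inside a save/seed/restore
guard to honour the package-wide determinism contract.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.imputation.mice import MICEData

from .errors import UnimputableError, ValidationError


@dataclass
class ImputationSet:
    """m completed copies of the analysis table plus provenance."""

    m: int
    completed: list[pd.DataFrame]
    seed: int
    cycles: int

    def __post_init__(self) -> None:
        if self.m != len(self.completed):
            raise ValidationError("ImputationSet: m must equal the number of completed datasets")

    def write(self, out_dir) -> None:
        import json
        import pathlib

        out = pathlib.Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for j, df in enumerate(self.completed, start=1):
            df.to_csv(out / f"imputed_{j:02d}.csv")
        (out / "manifest.json").write_text(
            json.dumps(
                {"m": self.m, "seed": self.seed, "cycles": self.cycles,
                 "model": "pmm(k=5) chained equations"},
                indent=2,
            )
        )


def mice_impute(
    data: pd.DataFrame,
    m: int = 10,
    seed: int = 0,
    cycles: int = 10,
    k_pmm: int = 5,
    clip: tuple[float, float] | None = (0.0, 100.0),
) -> ImputationSet:
    """Impute missing cells of a numeric analysis table m times.

    ``data`` must be all-numeric (encode categoricals first).  Observed
    cells are never altered; each completed dataset has no missing cells.
    With ``clip`` set, imputed values are clipped into range (a no-op for
    PMM, which only reuses observed donor values, but enforced anyway).
    Reproducible given ``seed``.
    """
    if m < 2:
        raise ValidationError("m: at least 2 imputations required")
    non_numeric = [c for c in data.columns if not pd.api.types.is_numeric_dtype(data[c])]
    if non_numeric:
        raise ValidationError(f"mice_impute needs a numeric table; offending columns: {non_numeric}")
    frac_missing = data.isna().mean()
    all_missing = list(frac_missing.index[frac_missing == 1.0])
    if all_missing:
        raise UnimputableError(f"variables with no observed values: {all_missing}")
    heavy = list(frac_missing.index[frac_missing >= 0.5])
    if heavy:
        raise UnimputableError(f"variables with >= 50% missingness: {heavy}")

    if not data.isna().to_numpy().any():
        return ImputationSet(m=m, completed=[data.copy() for _ in range(m)], seed=seed, cycles=cycles)

    obs_mask = data.notna()
    state = np.random.get_state()
    try:
        np.random.seed(seed % 2**31)
        md = MICEData(data.reset_index(drop=True), perturbation_method="gaussian", k_pmm=k_pmm)
        completed = []
        for _ in range(m):
            md.update_all(cycles)
            filled = md.data.copy()
            filled.index = data.index
            filled.columns = data.columns
            if clip is not None:
                imputed_only = filled.where(~obs_mask, other=np.nan).clip(*clip)
                filled = filled.where(obs_mask, other=imputed_only)
            completed.append(filled)
    finally:
        np.random.set_state(state)

    for df in completed:
        if not df.where(obs_mask).equals(data.where(obs_mask)):
            raise AssertionError("imputation altered observed cells")
    return ImputationSet(m=m, completed=completed, seed=seed, cycles=cycles)


@dataclass(frozen=True)
class PooledEstimate:
    """Rubin's-rules combination of m point estimates and variances."""

    q_bar: float  # pooled point estimate
    w_bar: float  # mean within-imputation variance
    b: float      # between-imputation variance (sample variance of estimates)
    t: float      # total variance = w_bar + (1 + 1/m) b
    df: float     # degrees of freedom
    m: int

    @property
    def se(self) -> float:
        return math.sqrt(self.t)


def rubins_pool(estimates, variances, df_complete: float | None = None) -> PooledEstimate:
    """Combine m estimates and their variances with Rubin's rules.

    Q-bar is the mean estimate, W-bar the mean variance, B the n-1
    sample variance of the estimates and T = W-bar + (1 + 1/m) B.  The
    degrees of freedom use the classical large-sample formula
    nu = (m - 1) (1 + W-bar / ((1 + 1/m) B))^2; passing ``df_complete``
    switches to the Barnard-Rubin small-sample adjustment.  B = 0 gives
    infinite df.
    """
    q = np.asarray(estimates, dtype=float)
    w = np.asarray(variances, dtype=float)
    if q.shape != w.shape or q.ndim != 1:
        raise ValidationError("estimates and variances must be 1-d and of equal length")
    m = q.size
    if m < 2:
        raise ValidationError("rubins_pool needs m >= 2")
    if (w < 0).any():
        raise ValidationError("variances must be >= 0")
    q_bar = float(q.mean())
    w_bar = float(w.mean())
    b = float(q.var(ddof=1))
    t = w_bar + (1.0 + 1.0 / m) * b
    if b == 0.0:
        df = math.inf
    else:
        r = (1.0 + 1.0 / m) * b
        df = (m - 1) * (1.0 + w_bar / r) ** 2
        if df_complete is not None:
            gamma = r / t
            df_obs = (df_complete + 1.0) / (df_complete + 3.0) * df_complete * (1.0 - gamma)
            df = 1.0 / (1.0 / df + 1.0 / df_obs)
    return PooledEstimate(q_bar=q_bar, w_bar=w_bar, b=b, t=t, df=df, m=m)
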