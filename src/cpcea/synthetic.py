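"""Synthetic patient-level trial data with the study's statistical structure.

The generator emulates a two-arm matched-pairs trial: a participant
roster with baseline covariates, an itemized cost ledger per child, and
66-item questionnaire responses at baseline and week 13.

Item responses are produced top-down: a latent domain score per
child x timepoint is drawn from a bivariate normal (baseline, follow-up)
with the configured within-child correlation, clipped to [0, 100]; each
of the domain's items then inverts the 0-100 transform with small
item-level jitter and rounds to the nearest 1..9 response.  Scored
synthetic domains therefore converge to the configured moments as n
grows (edge-of-scale domains carry a small clipping bias, below one
scale point at the shipped parameters).

Missingness: MCAR removes individual item cells everywhere; the
MAR-on-baseline mechanism drops whole follow-up assessments with a
child-level probability that is logistic in the child's (always fully
observed) mean baseline domain score — lower baseline quality of life
means a higher dropout chance, mimicking loss to follow-up.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .config import MAR_ON_BASELINE, MCAR, TrialConfig
from .costing import load_earnings_table, productivity_cost
from .cpqol import BASELINE, DOMAINS, FOLLOWUP, ITEM_STEP, InstrumentMap
from .errors import ValidationError

#: logistic slope of follow-up dropout on the standardized baseline score
MAR_SLOPE = -1.0

GMFCS_LEVELS = ["I", "II"]
GMFCS_P = [0.6, 0.4]
MACS_LEVELS = ["I", "II", "III"]
MACS_P = [0.3, 0.5, 0.2]
INCOME_BANDS = ["<25k", "25-50k", "50-75k", ">=75k"]
INCOME_P = [0.50, 0.30, 0.18, 0.02]
SEIFA_BANDS = ["low", "medium", "high"]
SEIFA_P = [0.40, 0.40, 0.20]


@dataclass
class TrialData:
    """One simulated trial: roster, cost ledger and long item responses."""

    participants: pd.DataFrame
    costs: pd.DataFrame
    items: pd.DataFrame
    config: TrialConfig

    def write(self, out_dir) -> None:
        """Emit participants.csv, costs.csv, items_long.csv + config.yaml."""
        import pathlib

        out = pathlib.Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.participants.to_csv(out / "participants.csv", index=False)
        self.costs.to_csv(out / "costs.csv", index=False)
        self.items.to_csv(out / "items_long.csv", index=False)
        self.config.to_yaml(out / "config.yaml")

    @classmethod
    def read(cls, data_dir, config: TrialConfig | None = None) -> "TrialData":
        import pathlib

        d = pathlib.Path(data_dir)
        if config is None:
            config = TrialConfig.from_yaml(d / "config.yaml")
        return cls(
            participants=pd.read_csv(d / "participants.csv"),
            costs=pd.read_csv(d / "costs.csv"),
            items=pd.read_csv(d / "items_long.csv"),
            config=config,
        )


def _draw_profiles(cfg: TrialConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Roster with matched pairs sharing age band, GMFCS and MACS."""
    n_pairs = min(cfg.n_intervention, cfg.n_control)
    rows = []

    def covariates(shared):
        age_band, gmfcs, macs = shared
        return {
            "age_years": round(age_band + rng.uniform(0.0, 1.0), 2),
            "sex": rng.choice(["female", "male"], p=[0.3, 0.7]),
            "gmfcs": gmfcs,
            "macs": macs,
            "hemiplegia_side": rng.choice(["left", "right"]),
            "income_band": rng.choice(INCOME_BANDS, p=INCOME_P),
            "seifa_band": rng.choice(SEIFA_BANDS, p=SEIFA_P),
        }

    def shared_draw():
        # 12-month age bands over the eligible 4-13 range
        return (
            int(rng.integers(4, 13)),
            rng.choice(GMFCS_LEVELS, p=GMFCS_P),
            rng.choice(MACS_LEVELS, p=MACS_P),
        )

    for p in range(n_pairs):
        shared = shared_draw()
        for arm, idx in (("intervention", p), ("control", p)):
            prefix = "I" if arm == "intervention" else "C"
            rows.append(
                {
                    "child_id": f"{prefix}{idx + 1:02d}",
                    "arm": arm,
                    "pair_id": f"P{p + 1:02d}",
                    **covariates(shared),
                }
            )
    # unmatched remainder in whichever arm is larger (singleton pair ids)
    extra_arm = "intervention" if cfg.n_intervention > cfg.n_control else "control"
    n_extra = abs(cfg.n_intervention - cfg.n_control)
    for k in range(n_extra):
        idx = n_pairs + k
        prefix = "I" if extra_arm == "intervention" else "C"
        rows.append(
            {
                "child_id": f"{prefix}{idx + 1:02d}",
                "arm": extra_arm,
                "pair_id": f"S{idx + 1:02d}",
                **covariates(shared_draw()),
            }
        )
    return pd.DataFrame(rows)


def _draw_latent_scores(cfg: TrialConfig, profiles: pd.DataFrame, rng: np.random.Generator) -> pd.DataFrame:
    """Latent (baseline, follow-up) domain scores per child, clipped to [0, 100]."""
    rho = cfg.within_child_correlation
    frames = {}
    for dom in DOMAINS:
        base = np.empty(len(profiles))
        fol = np.empty(len(profiles))
        for arm in ("intervention", "control"):
            mask = (profiles["arm"] == arm).to_numpy()
            mb, sb = cfg.domain_params[dom][arm]["baseline"]
            mf, sf = cfg.domain_params[dom][arm]["followup"]
            n = int(mask.sum())
            cov = [[sb**2, rho * sb * sf], [rho * sb * sf, sf**2]]
            draws = rng.multivariate_normal([mb, mf], cov, size=n)
            base[mask] = draws[:, 0]
            fol[mask] = draws[:, 1]
        frames[(dom, BASELINE)] = np.clip(base, 0.0, 100.0)
        frames[(dom, FOLLOWUP)] = np.clip(fol, 0.0, 100.0)
    out = pd.DataFrame(frames, index=profiles["child_id"])
    out.columns = pd.MultiIndex.from_tuples(out.columns, names=["domain", "timepoint"])
    return out


def _items_from_latent(
    cfg: TrialConfig,
    latent: pd.DataFrame,
    imap: InstrumentMap,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Invert the 0-100 transform per item with jitter; round into 1..9."""
    child_ids = latent.index.to_numpy()
    n = len(child_ids)
    frames = []
    for tp in (BASELINE, FOLLOWUP):
        cols = {}
        for dom in DOMAINS:
            item_ids = imap.items(dom)
            lat = latent[(dom, tp)].to_numpy()
            jitter = rng.normal(0.0, cfg.item_jitter_sd, size=(n, len(item_ids)))
            raw = np.clip(np.round((lat[:, None] + jitter) / ITEM_STEP) + 1, 1, 9)
            for j, item in enumerate(item_ids):
                cols[item] = raw[:, j]
        wide = pd.DataFrame(cols, index=pd.Index(child_ids, name="child_id"))
        long = wide.reset_index().melt(
            id_vars="child_id", var_name="item_id", value_name="response"
        )
        long.insert(1, "timepoint", tp)
        frames.append(long)
    items = pd.concat(frames, ignore_index=True)
    return items.sort_values(["child_id", "timepoint", "item_id"], kind="stable").reset_index(
        drop=True
    )


def _draw_component(spec: dict, n: int, rng: np.random.Generator) -> np.ndarray:
    kind = spec["kind"]
    if kind == "fixed":
        return np.full(n, float(spec["amount"]))
    if kind == "lognormal":
        return rng.lognormal(spec["mu"], spec["sigma"], size=n)
    if kind == "zero_inflated_lognormal":
        pos = rng.lognormal(spec["mu"], spec["sigma"], size=n)
        zero = rng.random(n) < spec["p_zero"]
        return np.where(zero, 0.0, pos)
    if kind == "two_point":
        zero = rng.random(n) < spec["p_zero"]
        return np.where(zero, 0.0, float(spec["value"]))
    raise ValidationError(f"unknown cost component kind {kind!r}")


def _draw_costs(cfg: TrialConfig, profiles: pd.DataFrame, rng: np.random.Generator) -> pd.DataFrame:
    earnings = load_earnings_table()
    out = profiles[["child_id", "arm"]].copy()
    for comp in ("registration", "staff_salary", "accommodation_travel", "consumables", "catering"):
        vals = np.empty(len(profiles))
        for arm in ("intervention", "control"):
            mask = (profiles["arm"] == arm).to_numpy()
            vals[mask] = _draw_component(cfg.cost_params[arm][comp], int(mask.sum()), rng)
        out[comp] = np.round(vals, 2)
    days = np.empty(len(profiles))
    for arm in ("intervention", "control"):
        mask = (profiles["arm"] == arm).to_numpy()
        days[mask] = _draw_component(cfg.cost_params[arm]["caregiver_days_missed"], int(mask.sum()), rng)
    out["caregiver_days_missed"] = np.round(days, 2)
    band, sex, edu = cfg.caregiver_key
    out["caregiver_age_band"] = band
    out["caregiver_sex"] = sex
    out["caregiver_education"] = edu
    out["productivity_cost"] = [
        round(productivity_cost(d, cfg.caregiver_key, earnings), 2)
        for d in out["caregiver_days_missed"]
    ]
    return out


def _baseline_child_means(items: pd.DataFrame) -> pd.Series:
    """Mean scaled baseline response per child (always fully observed)."""
    base = items[items["timepoint"] == BASELINE]
    return base.groupby("child_id")["response"].mean().mul(ITEM_STEP).sub(ITEM_STEP)


def _solve_intercept(linpred: np.ndarray, rate: float) -> float:
    """Bisection for c such that mean sigmoid(c + linpred) == rate."""
    lo, hi = -30.0, 30.0
    for _ in range(200):
        mid = (lo + hi) / 2.0
        if np.mean(1.0 / (1.0 + np.exp(-(mid + linpred)))) < rate:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


def apply_missingness(
    data: TrialData,
    rate: float,
    mechanism: str,
    seed: int,
) -> TrialData:
    """Blank out item responses at the given rate.

    MCAR removes each item cell (both timepoints) independently with
    probability ``rate``.  MAR-on-baseline removes entire week-13
    assessments: child i's dropout probability is logistic in their
    standardized mean baseline score (slope ``MAR_SLOPE``), with the
    intercept solved so the expected fraction of missing week-13 cells
    equals ``rate``.  Baseline covariates and baseline responses stay
    complete under MAR.
    """
    if not 0.0 <= rate <= 0.5:
        raise ValidationError("missing_rate: must lie in [0, 0.5]")
    if rate == 0.0:
        return data
    rng = np.random.default_rng(seed)
    items = data.items.copy()
    if mechanism == MCAR:
        mask = rng.random(len(items)) < rate
        items.loc[mask, "response"] = np.nan
    elif mechanism == MAR_ON_BASELINE:
        base_means = _baseline_child_means(items)
        z = (base_means - base_means.mean()) / max(base_means.std(ddof=0), 1e-9)
        linpred = MAR_SLOPE * z.to_numpy()
        c = _solve_intercept(linpred, rate)
        p_drop = 1.0 / (1.0 + np.exp(-(c + linpred)))
        dropped = base_means.index[rng.random(len(p_drop)) < p_drop]
        sel = (items["timepoint"] == FOLLOWUP) & items["child_id"].isin(dropped)
        items.loc[sel, "response"] = np.nan
    else:
        raise ValidationError(f"missing_mechanism: unknown mechanism {mechanism!r}")
    return replace(data, items=items)


def simulate_trial(config: TrialConfig, imap: InstrumentMap | None = None) -> TrialData:
    """Generate one complete synthetic trial, then apply missingness.

    Deterministic given ``config.seed``: the roster, latent scores,
    items, costs and missingness each consume an independent child
    stream of the master seed, so the same config reproduces the same
    dataset byte for byte.
    """
    config.validate()
    if imap is None:
        imap = InstrumentMap.default()
    streams = np.random.SeedSequence(config.seed).spawn(4)
    rng_roster = np.random.default_rng(streams[0])
    rng_scores = np.random.default_rng(streams[1])
    rng_costs = np.random.default_rng(streams[2])
    miss_seed = int(streams[3].generate_state(1)[0] % (2**31))

    profiles = _draw_profiles(config, rng_roster)
    latent = _draw_latent_scores(config, profiles, rng_scores)
    items = _items_from_latent(config, latent, imap, rng_scores)
    costs = _draw_costs(config, profiles, rng_costs)

    data = TrialData(participants=profiles, costs=costs, items=items, config=config)
    return apply_missingness(data, config.missing_rate, config.missing_mechanism, miss_seed)
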