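"""End-to-end orchestration: simulate -> score -> impute -> infer -> CEA -> report.

``run_pipeline`` executes the whole within-trial economic evaluation on a
configuration and writes six outputs to a directory:

* ``table1_baseline.csv``  — baseline characteristics, counts (percent) per arm
* ``table2_costs.csv``     — per-component cost medians (IQR) and p-values
* ``table3_effects.csv``   — per-domain baseline/follow-up/change means (SD)
  per arm with pooled difference-in-difference p-values
* ``table4_cea.csv``       — incremental cost/effect with bootstrap UIs and
  ICER or dominance label per domain
* ``ceac.csv``             — acceptability-curve points per domain
* ``manifest.json``        — config hash, stage seeds, row counts, versions

All numeric outputs are fully determined by (config, seed).
"""

from __future__ import annotations

import json
import pathlib
import time

import numpy as np
import pandas as pd

from . import __version__
from .cea import DOMINANT, DOMINATED, TRADEOFF_NE, display_round, evaluate_domain, ceac as _ceac
from .config import TrialConfig
from .costing import aggregate_ledger, summarize_costs
from .cpqol import BASELINE, DOMAIN_NAMES, DOMAINS, FOLLOWUP, InstrumentMap, score_dataset
from .errors import ValidationError
from .imputation import mice_impute, rubins_pool
from .inference import welch_from_stats
from .synthetic import TrialData, simulate_trial

BASELINE_CHARACTERISTICS = {
    "age_band": lambda p: np.where(p["age_years"] < 9, "4-8", "9-13"),
    "sex": lambda p: p["sex"],
    "gmfcs": lambda p: p["gmfcs"],
    "macs": lambda p: p["macs"],
    "hemiplegia_side": lambda p: p["hemiplegia_side"],
    "income_band": lambda p: p["income_band"],
    "seifa_band": lambda p: p["seifa_band"],
}


def _pct(count: int, total: int) -> int:
    """Column percentage rounded half-up to an integer."""
    return int(np.floor(100.0 * count / total + 0.5))


def summarize_baseline(profiles: pd.DataFrame) -> pd.DataFrame:
    """Table-1-shaped counts (percentages) per arm and overall."""
    if profiles.empty:
        raise ValidationError("summarize_baseline: empty roster")
    arms = ["intervention", "control"]
    rows = []
    for char, fn in BASELINE_CHARACTERISTICS.items():
        levels = pd.Series(fn(profiles), index=profiles.index, name=char)
        for level in pd.unique(levels):
            row = {"characteristic": char, "level": level}
            sel = levels == level
            row["total_n"] = int(sel.sum())
            row["total_pct"] = _pct(int(sel.sum()), len(profiles))
            for arm in arms:
                in_arm = profiles["arm"] == arm
                n_arm = int(in_arm.sum())
                n = int((sel & in_arm).sum())
                row[f"{arm}_n"] = n
                row[f"{arm}_pct"] = _pct(n, n_arm) if n_arm else 0
            rows.append(row)
    return pd.DataFrame(rows)


def build_analysis_table(data: TrialData, imap: InstrumentMap) -> pd.DataFrame:
    """Numeric child-level table: covariates + per-domain scores at both timepoints."""
    scores = score_dataset(data.items, imap, data.config.completeness_threshold)
    wide = scores.unstack("timepoint")
    wide.columns = [f"{dom}_{'b' if tp == BASELINE else 'f'}" for dom, tp in wide.columns]
    roster = data.participants.set_index("child_id")
    tbl = pd.DataFrame(index=wide.index)
    tbl["arm"] = (roster["arm"] == "intervention").astype(float)
    tbl["age_years"] = roster["age_years"].astype(float)
    tbl["sex_female"] = (roster["sex"] == "female").astype(float)
    ordered = [f"{dom}_b" for dom in DOMAINS] + [f"{dom}_f" for dom in DOMAINS]
    return pd.concat([tbl, wide[ordered]], axis=1)


def effects_table(completed: list[pd.DataFrame]) -> pd.DataFrame:
    """Table-3 analogue pooled over imputations with Rubin's rules.

    Means are pooled as Q-bar; the reported SDs are the means of the
    per-imputation sample SDs; the difference-in-difference p-value uses
    the pooled Welch statistic with Rubin degrees of freedom.
    """
    from scipy import stats

    rows = []
    for dom in DOMAINS:
        per_imp: dict[str, dict[str, list[float]]] = {
            a: {k: [] for k in ("bm", "bs", "fm", "fs", "cm", "cs")} for a in ("intervention", "control")
        }
        diffs, variances, ns = [], [], None
        for df in completed:
            ch = df[f"{dom}_f"] - df[f"{dom}_b"]
            stats_by_arm = {}
            for arm, val in (("intervention", 1.0), ("control", 0.0)):
                sel = df["arm"] == val
                b, f, c = df.loc[sel, f"{dom}_b"], df.loc[sel, f"{dom}_f"], ch[sel]
                per_imp[arm]["bm"].append(b.mean())
                per_imp[arm]["bs"].append(b.std(ddof=1))
                per_imp[arm]["fm"].append(f.mean())
                per_imp[arm]["fs"].append(f.std(ddof=1))
                per_imp[arm]["cm"].append(c.mean())
                per_imp[arm]["cs"].append(c.std(ddof=1))
                stats_by_arm[arm] = (c.mean(), c.std(ddof=1), int(sel.sum()))
            (mi, si, ni), (mc, sc, nc) = stats_by_arm["intervention"], stats_by_arm["control"]
            diffs.append(mi - mc)
            variances.append(si**2 / ni + sc**2 / nc)
            ns = (ni, nc)
        pooled = rubins_pool(diffs, variances)
        if pooled.t > 0 and np.isfinite(pooled.df):
            p = 2.0 * stats.t.sf(abs(pooled.q_bar) / pooled.se, pooled.df)
        else:
            _, _, p = welch_from_stats(
                float(np.mean(per_imp["intervention"]["cm"])),
                float(np.mean(per_imp["intervention"]["cs"])),
                ns[0],
                float(np.mean(per_imp["control"]["cm"])),
                float(np.mean(per_imp["control"]["cs"])),
                ns[1],
            )
        row = {"domain": dom, "domain_name": DOMAIN_NAMES[dom]}
        for arm in ("intervention", "control"):
            for key, name in (("bm", "baseline_mean"), ("bs", "baseline_sd"),
                              ("fm", "followup_mean"), ("fs", "followup_sd"),
                              ("cm", "change_mean"), ("cs", "change_sd")):
                row[f"{arm}_{name}"] = round(float(np.mean(per_imp[arm][key])), 2)
        row["difference"] = round(float(pooled.q_bar), 2)
        row["p_value"] = round(float(p), 3)
        rows.append(row)
    return pd.DataFrame(rows)


def run_pipeline(
    config: TrialConfig,
    out_dir,
    seed: int | None = None,
    imap: InstrumentMap | None = None,
    data: TrialData | None = None,
) -> pathlib.Path:
    """Run the full evaluation and write the six declared outputs.

    ``seed`` overrides ``config.seed``; ``data`` (an externally ingested
    trial in the simulator's schema) skips the simulation stage.
    """
    t0 = time.time()
    config = config.copy()
    if seed is not None:
        config.seed = int(seed)
    config.validate()
    if imap is None:
        imap = InstrumentMap.default()
    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    stage_seeds = {}
    ss = np.random.SeedSequence(config.seed)
    s_sim, s_mi, s_boot = (int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(3))

    if data is None:
        sim_cfg = config.copy()
        sim_cfg.seed = s_sim
        data = simulate_trial(sim_cfg, imap)
        stage_seeds["simulate"] = s_sim
    table1 = summarize_baseline(data.participants)

    analysis = build_analysis_table(data, imap)
    imputations = mice_impute(
        analysis, m=config.m_imputations, seed=s_mi, cycles=config.mice_cycles
    )
    stage_seeds["impute"] = s_mi
    table3 = effects_table(imputations.completed)

    costs_agg = aggregate_ledger(data.costs)
    table2 = summarize_costs(data.costs)

    roster = data.participants.set_index("child_id")
    cost_totals = costs_agg.set_index("child_id")["total"].reindex(analysis.index)
    int_ids = analysis.index[analysis["arm"] == 1.0]
    ctl_ids = analysis.index[analysis["arm"] == 0.0]
    costs_int = cost_totals.loc[int_ids].to_numpy()
    costs_ctl = cost_totals.loc[ctl_ids].to_numpy()

    domain_seeds = {
        dom: int(s.generate_state(1)[0] % 2**31)
        for dom, s in zip(DOMAINS, np.random.SeedSequence(s_boot).spawn(len(DOMAINS)))
    }
    stage_seeds["bootstrap_master"] = s_boot

    wtp_grid = np.arange(0.0, config.wtp_max + 1e-9, config.wtp_step)
    t4_rows, ceac_frames = [], []
    for dom in DOMAINS:
        orientation = imap.orientation(dom)
        eff_int = [
            (df.loc[int_ids, f"{dom}_f"] - df.loc[int_ids, f"{dom}_b"]).to_numpy()
            for df in imputations.completed
        ]
        eff_ctl = [
            (df.loc[ctl_ids, f"{dom}_f"] - df.loc[ctl_ids, f"{dom}_b"]).to_numpy()
            for df in imputations.completed
        ]
        result, reps = evaluate_domain(
            dom, costs_int, costs_ctl, eff_int, eff_ctl, orientation,
            b=config.bootstrap_reps, seed=domain_seeds[dom],
        )
        t4_rows.append(
            {
                "domain": dom,
                "domain_name": DOMAIN_NAMES[dom],
                "orientation": orientation,
                "delta_C": round(result.delta_C, 2),
                "delta_C_ui_low": round(result.delta_C_ui[0], 2),
                "delta_C_ui_high": round(result.delta_C_ui[1], 2),
                "delta_E": round(result.delta_E, 2),
                "delta_E_ui_low": round(result.delta_E_ui[0], 2),
                "delta_E_ui_high": round(result.delta_E_ui[1], 2),
                "classification": result.classification,
                "icer": display_round(result.icer) if result.icer is not None else "",
                "icer_ui_low": display_round(result.ui_low) if result.ui_low is not None else "",
                "icer_ui_high": display_round(result.ui_high) if result.ui_high is not None else "",
                "excluded_undefined": result.excluded_undefined,
            }
        )
        curve = _ceac(reps, wtp_grid)
        curve.insert(0, "domain", dom)
        curve["probability"] = curve["probability"].round(2)
        ceac_frames.append(curve)

    table4 = pd.DataFrame(t4_rows)
    ceac_table = pd.concat(ceac_frames, ignore_index=True)

    table1.to_csv(out / "table1_baseline.csv", index=False)
    table2.round(3).to_csv(out / "table2_costs.csv", index=False)
    table3.to_csv(out / "table3_effects.csv", index=False)
    table4.to_csv(out / "table4_cea.csv", index=False)
    ceac_table.to_csv(out / "ceac.csv", index=False)

    manifest = {
        "config_hash": config.digest(),
        "master_seed": config.seed,
        "stage_seeds": {**stage_seeds, "bootstrap_per_domain": domain_seeds},
        "package_version": __version__,
        "m_imputations": config.m_imputations,
        "bootstrap_reps_per_dataset": config.bootstrap_reps,
        "quantile_convention": "linear interpolation",
        "rows": {
            "participants": int(len(data.participants)),
            "cost_ledgers": int(len(data.costs)),
            "item_responses": int(len(data.items)),
            "table3_domains": int(len(table3)),
            "table4_domains": int(len(table4)),
            "ceac_points": int(len(ceac_table)),
        },
        "excluded_undefined_replicates": {
            r["domain"]: int(r["excluded_undefined"]) for r in t4_rows
        },
        "elapsed_seconds": round(time.time() - t0, 2),
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out
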