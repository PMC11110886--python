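"""Synthetic trial generator: determinism, calibration and missingness."""

import numpy as np
import pandas as pd
import pytest

from cpcea import TrialConfig, apply_missingness, score_dataset, simulate_trial
from cpcea.cpqol import BASELINE, FOLLOWUP
from cpcea.errors import ValidationError


def small_config(**kw):
    defaults = dict(n_intervention=8, n_control=6, seed=99, missing_rate=0.0)
    defaults.update(kw)
    return TrialConfig(**defaults)


class TestDeterminism:
    def test_same_config_same_seed_byte_identical(self, imap):
        a = simulate_trial(small_config(missing_rate=0.2, missing_mechanism="MCAR"), imap)
        b = simulate_trial(small_config(missing_rate=0.2, missing_mechanism="MCAR"), imap)
        for left, right in ((a.participants, b.participants), (a.costs, b.costs), (a.items, b.items)):
            assert left.to_csv(index=False) == right.to_csv(index=False)

    def test_different_seed_differs(self, imap):
        a = simulate_trial(small_config(seed=1), imap)
        b = simulate_trial(small_config(seed=2), imap)
        assert not a.items["response"].equals(b.items["response"])


class TestRosterStructure:
    def test_matched_pairs_share_matching_covariates(self, complete_trial):
        p = complete_trial.participants
        paired = p[p["pair_id"].str.startswith("P")]
        for _, grp in paired.groupby("pair_id"):
            assert len(grp) == 2
            assert set(grp["arm"]) == {"intervention", "control"}
            assert grp["gmfcs"].nunique() == 1
            assert grp["macs"].nunique() == 1
            assert np.floor(grp["age_years"]).nunique() == 1  # same 12-month band

    def test_arm_sizes_and_itt_labels(self, complete_trial):
        p = complete_trial.participants
        assert (p["arm"] == "intervention").sum() == 27
        assert (p["arm"] == "control").sum() == 20
        assert p["child_id"].is_unique

    def test_baseline_covariates_complete(self, complete_trial):
        assert complete_trial.participants.notna().all().all()


class TestCostStructure:
    def test_fixed_camp_components_have_zero_spread(self, complete_trial):
        costs = complete_trial.costs
        camp = costs[costs["arm"] == "intervention"]
        for comp, value in [("registration", 425.0), ("staff_salary", 1631.0),
                            ("consumables", 16.0), ("catering", 272.0)]:
            assert (camp[comp] == value).all()

    def test_control_arm_has_no_camp_fees(self, complete_trial):
        ctl = complete_trial.costs[complete_trial.costs["arm"] == "control"]
        for comp in ("registration", "consumables", "catering"):
            assert (ctl[comp] == 0.0).all()

    def test_productivity_is_days_times_rate(self, complete_trial):
        c = complete_trial.costs
        np.testing.assert_allclose(
            c["productivity_cost"], (c["caregiver_days_missed"] * 269.20).round(2), atol=0.011
        )


class TestCalibration:
    def test_large_n_scored_mean_matches_configured_pain_mean(self, imap):
        # intervention Pain baseline configured 27.72 (SD 16.05); at n=2000 the
        # scored sample mean lands within 1.0 despite edge-of-scale clipping
        cfg = TrialConfig(n_intervention=2000, n_control=2, missing_rate=0.0, seed=7)
        data = simulate_trial(cfg, imap)
        scores = score_dataset(data.items, imap)
        ids = data.participants.loc[data.participants["arm"] == "intervention", "child_id"]
        pain = scores.xs(BASELINE, level="timepoint").loc[ids, "pain_disability"]
        assert abs(pain.mean() - 27.72) < 1.0
        assert abs(pain.std(ddof=1) - 16.05) < 1.5

    def test_mid_scale_domain_mean_and_sd_converge(self, imap):
        cfg = TrialConfig(n_intervention=2000, n_control=2, missing_rate=0.0, seed=8)
        data = simulate_trial(cfg, imap)
        scores = score_dataset(data.items, imap)
        ids = data.participants.loc[data.participants["arm"] == "intervention", "child_id"]
        dom = scores.xs(BASELINE, level="timepoint").loc[ids, "participation_physical"]
        assert abs(dom.mean() - 66.33) < 1.0
        assert abs(dom.std(ddof=1) - 14.57) < 1.0


class TestMissingness:
    def test_rate_zero_leaves_dataset_unchanged(self, complete_trial):
        assert complete_trial.items["response"].notna().all()
        out = apply_missingness(complete_trial, 0.0, "MCAR", seed=5)
        assert out.items["response"].equals(complete_trial.items["response"])

    def test_mcar_count_within_binomial_bound(self, imap):
        cfg = TrialConfig(missing_rate=0.3, missing_mechanism="MCAR", seed=31)
        data = simulate_trial(cfg, imap)
        n_cells = 66 * 47 * 2
        assert len(data.items) == n_cells
        n_missing = int(data.items["response"].isna().sum())
        sd = np.sqrt(n_cells * 0.3 * 0.7)
        assert abs(n_missing - 0.3 * n_cells) < 3 * sd

    def test_mar_keeps_baseline_complete_and_drops_whole_followups(self, imap):
        cfg = TrialConfig(missing_rate=0.25, missing_mechanism="MAR-on-baseline", seed=17)
        data = simulate_trial(cfg, imap)
        items = data.items
        assert items.loc[items["timepoint"] == BASELINE, "response"].notna().all()
        per_child = items[items["timepoint"] == FOLLOWUP].groupby("child_id")["response"].apply(
            lambda s: s.isna().mean()
        )
        assert set(per_child.round(6).unique()) <= {0.0, 1.0}

    def test_mar_probability_depends_on_baseline_score(self, imap):
        # generator self-consistency: logistic regression of the dropout
        # indicator on the mean baseline score recovers a negative slope
        import statsmodels.api as sm

        cfg = TrialConfig(
            n_intervention=150, n_control=150, missing_rate=0.25,
            missing_mechanism="MAR-on-baseline", seed=23,
        )
        data = simulate_trial(cfg, imap)
        items = data.items
        base_mean = (
            items[items["timepoint"] == BASELINE]
            .groupby("child_id")["response"].mean()
        )
        dropped = (
            items[items["timepoint"] == FOLLOWUP]
            .groupby("child_id")["response"]
            .apply(lambda s: s.isna().all())
            .astype(float)
        )
        x = sm.add_constant(base_mean.loc[dropped.index].to_numpy())
        fit = sm.Logit(dropped.to_numpy(), x).fit(disp=0)
        slope, pval = fit.params[1], fit.pvalues[1]
        assert slope < 0 and pval < 0.01

    def test_rate_out_of_range_rejected(self, complete_trial):
        with pytest.raises(ValidationError):
            apply_missingness(complete_trial, 0.7, "MCAR", seed=1)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kw,field",
        [
            (dict(n_intervention=1), "n_intervention"),
            (dict(missing_rate=0.6), "missing_rate"),
            (dict(within_child_correlation=1.5), "within_child_correlation"),
            (dict(missing_mechanism="MNAR"), "missing_mechanism"),
            (dict(m_imputations=1), "m_imputations"),
        ],
    )
    def test_invalid_field_named_in_error(self, kw, field):
        with pytest.raises(ValidationError, match=field):
            TrialConfig(**kw).validate()

    def test_bad_domain_sd_rejected(self):
        cfg = TrialConfig()
        cfg.domain_params["pain_disability"]["control"]["baseline"] = [27.05, -1.0]
        with pytest.raises(ValidationError, match="pain_disability"):
            cfg.validate()

    def test_yaml_round_trip(self, tmp_path):
        cfg = TrialConfig(seed=77, bootstrap_reps=123)
        path = tmp_path / "cfg.yaml"
        cfg.to_yaml(path)
        back = TrialConfig.from_yaml(path)
        assert back == cfg
        assert back.digest() == cfg.digest()
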