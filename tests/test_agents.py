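"""Synthetic participants: decision model, learning rule, reproducibility."""

import numpy as np
import pytest
from scipy.stats import norm

from memcrit.agents import (
    AgentConfig,
    RecallConfig,
    default_cohort_configs,
    simulate_cohort,
    simulate_recall,
    simulate_session,
    update_criterion,
)
from memcrit.io import validate_trials
from memcrit.sdt import criterion_trajectory


class TestUpdateCriterion:
    def test_zero_learning_rate_freezes_criterion(self):
        assert update_criterion(0.3, "old", 0.9, alpha=0.0, alpha_neg=0.0) == 0.3

    def test_positive_pe_after_old_response_turns_liberal(self):
        assert update_criterion(0.0, "old", 0.5, alpha=0.1) < 0.0

    def test_positive_pe_after_new_response_turns_conservative(self):
        assert update_criterion(0.0, "new", 0.5, alpha=0.1) > 0.0

    def test_negative_pe_reverses_the_push_at_punishment_rate(self):
        up = update_criterion(0.0, "new", 0.4, alpha=0.1, alpha_neg=0.025)
        down = update_criterion(0.0, "new", -0.4, alpha=0.1, alpha_neg=0.025)
        assert up == pytest.approx(0.04)
        assert down == pytest.approx(-0.01)  # punished at the reduced rate


class TestSession:
    def test_alpha_zero_keeps_criterion_constant_all_session(self):
        cfg = AgentConfig(condition="fmri_liberal", design="fmri", alpha=0.0,
                          c0=0.2, seed=5)
        session = simulate_session(cfg)
        assert (session["criterion"] == 0.2).all()

    def test_decision_rule_matches_normal_cdf_at_neutral_criterion(self):
        """d'=1.5, c=0: P(call an old item old) -> Phi(d'/2) before the
        deadline censors slow (disproportionately incorrect) responses."""
        cfg = AgentConfig(condition="veridical", design="fmri", alpha=0.0, seed=8)
        session = simulate_session(cfg)
        old = session[session.item_status == "old"]
        assert (old.strength > 0.75).mean() == pytest.approx(norm.cdf(0.75), abs=0.035)
        responded = session[session.response.notna()]
        # the response is exactly the strength/threshold comparison
        assert (
            (responded.strength > 0.75) == (responded.response == "old")
        ).all()

    def test_neutral_equal_variance_observer_is_response_symmetric(self):
        sessions = [
            simulate_session(
                AgentConfig(condition="veridical", design="fmri", alpha=0.0, seed=s)
            )
            for s in range(4)
        ]
        fa, miss = [], []
        for session in sessions:
            r = session[session.response.notna()]
            fa.append((r[r.item_status == "new"].response == "old").mean())
            miss.append((r[r.item_status == "old"].response == "new").mean())
        assert np.mean(fa) == pytest.approx(np.mean(miss), abs=0.03)

    def test_same_config_and_seed_is_byte_identical(self):
        cfg = AgentConfig(condition="new_high", design="behav", seed=42)
        a = simulate_session(cfg).to_csv(index=False)
        b = simulate_session(cfg).to_csv(index=False)
        assert a == b

    def test_non_response_rate_below_five_percent(self):
        rates = [
            simulate_session(
                AgentConfig(condition="fmri_liberal", design="fmri", seed=s)
            ).response.isna().mean()
            for s in range(5)
        ]
        assert np.mean(rates) < 0.05

    def test_sessions_pass_schema_validation(self, behav_session):
        assert validate_trials(behav_session) == []

    def test_confidence_bounded_and_missing_only_on_non_response(self, fmri_session):
        responded = fmri_session.response.notna()
        conf = fmri_session.loc[responded, "confidence"]
        assert conf.between(0, 1).all()
        assert fmri_session.loc[~responded, "confidence"].isna().all()

    def test_veridical_cohort_terminal_criterion_stays_at_start(self):
        terms = []
        for seed in range(25):
            cfg = AgentConfig(condition="veridical", design="behav", seed=seed)
            traj = [s for s in criterion_trajectory(simulate_session(cfg), "thirds") if s]
            terms.append(traj[-1].criterion_c)
        assert np.mean(terms) == pytest.approx(0.0, abs=0.12)

    def test_bad_configs_rejected(self):
        with pytest.raises(ValueError):
            AgentConfig(d_prime=-1)
        with pytest.raises(ValueError):
            AgentConfig(coding="MS_star")  # starred coding is analysis-only
        with pytest.raises(ValueError):
            AgentConfig(condition="placebo")


class TestCohort:
    def test_duplicate_seeds_warn(self):
        configs = [AgentConfig(seed=1, n_trials=96), AgentConfig(seed=1, n_trials=96)]
        with pytest.warns(UserWarning, match="duplicate seeds"):
            simulate_cohort(configs)

    def test_manifest_matches_sessions(self):
        configs = default_cohort_configs(["veridical", "old_low"], 2, n_trials=96)
        sessions, manifest = simulate_cohort(configs)
        assert len(sessions) == 4
        assert list(manifest.condition) == ["veridical"] * 2 + ["old_low"] * 2
        assert (manifest.n_trials == 96).all()


class TestRecall:
    def test_extreme_liberal_criterion_recalls_every_lure(self):
        assert simulate_recall(-50.0, seed=0)["lure_count"] == 10

    def test_extreme_conservative_criterion_recalls_no_lure(self):
        assert simulate_recall(50.0, seed=0)["lure_count"] == 0

    def test_lure_recall_anticorrelates_with_criterion(self):
        rng = np.random.default_rng(3)
        cs = rng.normal(0, 0.8, 60)
        lures = [simulate_recall(c, seed=i)["lure_count"] for i, c in enumerate(cs)]
        assert np.corrcoef(cs, lures)[0, 1] < -0.3

    def test_strength_ordering_enforced(self):
        with pytest.raises(ValueError):
            RecallConfig(studied_strength_mean=0.5, lure_strength_mean=0.75)
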