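"""Synthetic cohort generator: determinism, archetype guarantees, calibration."""

import numpy as np
import pandas as pd
import pytest

from cardiorenal import (
    BaselineEstimate,
    HazardConfig,
    SimulationConfig,
    apply_exclusions,
    archetype_trajectory,
    classify_patient,
    estimate_baseline,
    generate_cohort,
    simulate_outcomes,
    simulate_study_cohort,
    write_cohort,
)
from cardiorenal.classify import classify_cohort
from cardiorenal.simulate import ARCHETYPES, DEFAULT_MIX

from conftest import make_patient


def _mix(**overrides):
    mix = {k: 0.0 for k in ARCHETYPES}
    mix.update(overrides)
    return mix


class TestConfigValidation:
    def test_mix_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            SimulationConfig(archetype_mix=_mix(stable=0.5))

    def test_unknown_archetype_rejected(self):
        with pytest.raises(ValueError, match="unknown archetype"):
            SimulationConfig(archetype_mix={"levitating": 1.0})

    def test_unknown_kind_rejected_by_trajectory(self, rng):
        with pytest.raises(ValueError, match="unknown archetype"):
            archetype_trajectory("wobble", 90.0, 240.0, rng)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            HazardConfig(baseline_daily_death_rate=-0.1)


class TestDeterminism:
    def test_same_seed_same_cohort(self):
        a, ta = generate_cohort(SimulationConfig(n=30, seed=11))
        b, tb = generate_cohort(SimulationConfig(n=30, seed=11))
        assert a.patients == b.patients
        pd.testing.assert_frame_equal(ta, tb)

    def test_same_seed_identical_files(self, tmp_path):
        for sub in ("x", "y"):
            cohort, _, _ = simulate_study_cohort(SimulationConfig(n=30, seed=5))
            write_cohort(cohort, tmp_path / sub)
        for name in ("patients.csv", "measurements.csv"):
            assert (tmp_path / "x" / name).read_bytes() == (tmp_path / "y" / name).read_bytes()

    def test_different_seeds_differ(self):
        a, _ = generate_cohort(SimulationConfig(n=30, seed=1))
        b, _ = generate_cohort(SimulationConfig(n=30, seed=2))
        assert a.patients != b.patients


class TestArchetypeGuarantees:
    """Each archetype must realize its intended detection pattern.

    Run the real classifier (baseline cascade included) over repeated noisy
    draws per archetype at the default noise level.
    """

    N_DRAWS = 250

    def _classified_draws(self, kind, n=N_DRAWS):
        mix = _mix(**{kind: 1.0})
        config = SimulationConfig(n=n, seed=99, archetype_mix=mix)
        cohort, truth = generate_cohort(config)
        baselines = {p.patient_id: estimate_baseline(p) for p in cohort}
        table = classify_cohort(cohort, baselines)
        return cohort, table, truth

    def test_stable_triggers_nothing(self):
        _, table, _ = self._classified_draws("stable")
        for row in table.rows.values():
            assert not (row.rifle.detected or row.akin.detected or row.kdigo.detected)

    def test_fast_riser_triggers_all_three(self):
        _, table, _ = self._classified_draws("fast_riser")
        for row in table.rows.values():
            assert row.rifle.detected and row.akin.detected and row.kdigo.detected

    def test_slow_creeper_is_kdigo_and_rifle_only(self):
        _, table, _ = self._classified_draws("slow_creeper")
        for row in table.rows.values():
            assert row.rifle.detected and row.kdigo.detected
            assert not row.akin.detected

    def test_small_bump_is_kdigo_and_akin_only(self):
        _, table, _ = self._classified_draws("small_bump")
        for row in table.rows.values():
            assert row.akin.detected and row.kdigo.detected
            assert not row.rifle.detected

    def test_high_baseline_with_prior_is_stage3_rifle_negative(self):
        mix = _mix(high_baseline_abs=1.0)
        config = SimulationConfig(
            n=self.N_DRAWS, seed=99, archetype_mix=mix, prior_value_availability=1.0
        )
        cohort, _ = generate_cohort(config)
        baselines = {p.patient_id: estimate_baseline(p) for p in cohort}
        table = classify_cohort(cohort, baselines)
        for row in table.rows.values():
            assert row.kdigo.stage == 3 and row.akin.stage == 3
            assert not row.rifle.detected
            assert row.baseline.source == "prior_minimum"

    def test_high_baseline_without_prior_is_concordant_aki(self):
        # no pre-admission value: the cascade back-calculates a low baseline,
        # so the elevated admission itself is AKI under every criterion
        mix = _mix(high_baseline_abs=1.0)
        config = SimulationConfig(
            n=50, seed=99, archetype_mix=mix, prior_value_availability=0.0
        )
        cohort, _ = generate_cohort(config)
        baselines = {p.patient_id: estimate_baseline(p) for p in cohort}
        table = classify_cohort(cohort, baselines)
        for row in table.rows.values():
            assert row.baseline.source == "mdrd_backcalc"
            assert row.rifle.detected and row.akin.detected and row.kdigo.detected

    def test_noiseless_trajectories_keep_guarantees(self, rng):
        checks = {
            "stable": ((60.0, 79.5), lambda r: not r.kdigo.detected),
            "fast_riser": ((60.0, 79.5), lambda r: r.rifle.detected and r.akin.detected),
            "slow_creeper": ((60.0, 79.5), lambda r: r.rifle.detected and not r.akin.detected),
            "small_bump": ((79.5, 95.0), lambda r: r.akin.detected and not r.rifle.detected),
        }
        for kind, (baselines, ok) in checks.items():
            for b in baselines:
                t, v = archetype_trajectory(kind, b, 10 * 24.0, rng)
                p = make_patient("T", scr=list(zip(t, v)), outcome_hours=240.0)
                row = classify_patient(p, BaselineEstimate(b, "admission"))
                assert ok(row), f"{kind} at baseline {b}"

    def test_out_of_domain_baselines_rejected(self, rng):
        with pytest.raises(ValueError, match="small_bump"):
            archetype_trajectory("small_bump", 60.0, 240.0, rng)
        with pytest.raises(ValueError, match="high_baseline_abs"):
            archetype_trajectory("high_baseline_abs", 120.0, 240.0, rng)


class TestCohortProperties:
    def test_default_cohort_passes_filter_without_exclusions(self):
        cohort, _ = generate_cohort(SimulationConfig(n=300, seed=4))
        retained, tally = apply_exclusions(cohort)
        assert len(retained) == 300
        assert sum(tally.values()) == 0

    def test_prior_value_source_frequency_matches_availability(self):
        # among elevated-admission patients, a prior value (and hence the
        # prior_minimum source) appears at the configured availability
        mix = _mix(high_baseline_abs=1.0)
        config = SimulationConfig(
            n=600, seed=21, archetype_mix=mix, prior_value_availability=0.27
        )
        cohort, _ = generate_cohort(config)
        sources = [estimate_baseline(p).source for p in cohort]
        frac = sources.count("prior_minimum") / len(sources)
        assert frac == pytest.approx(0.27, abs=0.06)
        assert set(sources) == {"prior_minimum", "mdrd_backcalc"}

    def test_stable_only_mix_has_zero_aki(self):
        config = SimulationConfig(n=400, seed=13, archetype_mix=_mix(stable=1.0))
        _, table, truth = simulate_study_cohort(config)
        assert all(not r.kdigo.detected for r in table.rows.values())
        assert (truth.true_group == "no_aki").all()

    def test_measurement_times_irregular_and_ordered(self):
        cohort, _ = generate_cohort(SimulationConfig(n=50, seed=2))
        for p in cohort:
            t = [m.time_hours for m in p.measurements if m.time_hours >= 0]
            assert all(b > a for a, b in zip(t, t[1:]))
            gaps = np.diff(t)
            assert ((gaps >= 18.0) & (gaps <= 30.0)).all()


class TestOutcomeSimulation:
    def test_zero_rate_means_no_deaths(self):
        config = SimulationConfig(
            n=100, seed=3, hazard=HazardConfig(baseline_daily_death_rate=0.0)
        )
        cohort, _, truth = simulate_study_cohort(config)
        assert not any(p.died_in_hospital for p in cohort)

    def test_null_hazard_ratios_equalize_group_mortality(self):
        config = SimulationConfig(
            n=4000,
            seed=17,
            hazard=HazardConfig(
                baseline_daily_death_rate=0.012,
                hr_concordant_aki=1.0,
                hr_discordant_aki=1.0,
            ),
        )
        _, _, truth = simulate_study_cohort(config)
        rates = truth.groupby("true_group")["died"].mean()
        assert rates.max() - rates.min() < 0.05

    def test_elevated_hazard_raises_aki_mortality(self):
        _, _, truth = simulate_study_cohort(SimulationConfig(n=2000, seed=23))
        rates = truth.groupby("true_group")["died"].mean()
        assert rates["concordant_aki"] > rates["no_aki"]
        assert rates["discordant_aki"] > rates["no_aki"]

    def test_no_deaths_before_48h_and_times_consistent(self):
        cohort, _, _ = simulate_study_cohort(SimulationConfig(n=500, seed=8))
        for p in cohort:
            assert p.outcome_time_hours >= 48.0
            if p.rrt_started:
                assert p.rrt_start_hours <= p.outcome_time_hours

    def test_outcomes_reproducible_given_seed(self):
        a = simulate_study_cohort(SimulationConfig(n=80, seed=31))[2]
        b = simulate_study_cohort(SimulationConfig(n=80, seed=31))[2]
        pd.testing.assert_frame_equal(a, b)


class TestDefaultMixShape:
    def test_default_mix_matches_documented_composition(self):
        assert sum(DEFAULT_MIX.values()) == pytest.approx(1.0)
        # expected detection fractions implied by the mix
        kdigo = 1.0 - DEFAULT_MIX["stable"]
        assert kdigo == pytest.approx(0.39, abs=1e-9)
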