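"""Motor metrics, learning curves and the permutation/mixed-model statistics."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from beevr.behavior import (
    choice_proportions,
    fit_mixed_models,
    interaction_permutation_test,
    motor_summary,
    motor_summary_table,
    tortuosity,
)
from beevr.errors import InputError
from beevr.protocol import TrialRecord


def _trial(t, x, y, latency=None, first_choice="CS_PLUS", phase="train"):
    return TrialRecord(
        index=1, phase=phase, cs_plus_side="LEFT", first_choice=first_choice,
        latency_s=latency, freeze_s=8.0 if latency else 0.0, reinforcement=None,
        t_s=np.asarray(t, float), x_cm=np.asarray(x, float), y_cm=np.asarray(y, float),
        heading_deg=np.zeros(len(t)),
    )


class TestTortuosity:
    def test_straight_path_is_one(self):
        assert tortuosity([0, 0, 0], [0, 5, 10]) == pytest.approx(1.0)

    def test_right_angle_3_4_path(self):
        # 3 cm leg then perpendicular 4 cm leg: net displacement 5 by Pythagoras
        assert tortuosity([0, 3, 3], [0, 0, 4]) == pytest.approx(1.4)

    def test_closed_loop_is_undefined(self):
        assert math.isnan(tortuosity([0, 1, 1, 0, 0], [0, 0, 1, 1, 0]))

    def test_single_sample_rejected(self):
        with pytest.raises(InputError):
            tortuosity([0], [0])

    @given(
        angle=st.floats(0, 2 * math.pi, allow_nan=False),
        dx=st.floats(-50, 50), dy=st.floats(-50, 50),
        scale=st.floats(0.1, 10),
    )
    @settings(derandomize=True, max_examples=50)
    def test_invariant_under_rigid_motion_and_scaling(self, angle, dx, dy, scale):
        x = np.array([0.0, 3.0, 3.0, 5.0])
        y = np.array([0.0, 0.0, 4.0, 4.0])
        base = tortuosity(x, y)
        c, s = math.cos(angle), math.sin(angle)
        xr = scale * (c * x - s * y) + dx
        yr = scale * (s * x + c * y) + dy
        assert tortuosity(xr, yr) == pytest.approx(base, rel=1e-9)


class TestMotorSummary:
    def test_single_segment(self):
        rec = _trial([0, 3], [0, 0], [0, 6], latency=3.0)
        m = motor_summary(rec)
        assert m.distance == pytest.approx(6.0)
        assert m.speed == pytest.approx(2.0)
        assert m.tortuosity == pytest.approx(1.0)

    def test_distances_add_over_concatenation(self):
        a = _trial([0, 1], [0, 1], [0, 1])
        # b's increments appended to a's endpoint form the concatenation
        b = _trial([0, 1, 2], [0, 1, 3], [0, 1, 0])
        ab = _trial([0, 1, 2, 3], [0, 1, 2, 4], [0, 1, 2, 1])
        da = motor_summary(a).distance
        db = motor_summary(b).distance
        assert motor_summary(ab).distance == pytest.approx(da + db)

    def test_speed_excludes_freeze(self):
        # 6 cm walked in a 3 s search phase; the 8 s freeze must not dilute speed
        rec = _trial([0, 3], [0, 0], [0, 6], latency=3.0)
        assert motor_summary(rec).speed == pytest.approx(2.0)

    def test_no_choice_uses_full_duration(self):
        # 4 cm walked over the full 4 s timeout window
        rec = _trial([0, 2, 4], [0, 2, 4], [0, 0, 0], latency=None, first_choice="NC")
        assert motor_summary(rec).speed == pytest.approx(1.0)

    def test_constant_velocity_agent_speed(self, world, protocol):
        from beevr.protocol import make_trial_stimuli, run_trial
        from conftest import BeelineAgent

        agent = BeelineAgent(target_index=0, speed=4.0, tick=world.tick)
        stimuli = make_trial_stimuli(world, "LEFT", "BLUE")
        rec = run_trial(agent.step, stimuli, world, protocol, np.random.default_rng(0))
        m = motor_summary(rec)
        assert m.speed == pytest.approx(4.0, rel=0.02)


def _trials_frame(choices_by_bee, phase="train"):
    rows = []
    for bee, choices in choices_by_bee.items():
        for i, c in enumerate(choices, start=1):
            rows.append(
                {"bee_id": bee, "trial": i, "phase": phase, "first_choice": c,
                 "cs_plus_side": "LEFT", "latency_s": 1.0, "freeze_s": 0.0, "iti_s": 60.0}
            )
    return pd.DataFrame(rows)


class TestChoiceProportions:
    def test_all_cs_plus_test_point(self):
        df = _trials_frame({f"b{i}": ["CS_PLUS"] for i in range(10)}, phase="test")
        cp = choice_proportions(df)
        row = cp.iloc[0]
        assert (row.p_cs_plus, row.p_cs_minus, row.p_nc) == (1.0, 0.0, 0.0)
        assert row.ci_low_cs_minus == 0.0

    def test_printed_non_learner_test_split(self):
        # 18 bees: 13 chose the CS- (72.22%), 5 made no choice (27.78%)
        df = _trials_frame(
            {f"b{i}": ["CS_MINUS"] for i in range(13)} | {f"n{i}": ["NC"] for i in range(5)},
            phase="test",
        )
        row = choice_proportions(df).iloc[0]
        assert row.p_cs_plus == 0.0
        assert 100 * row.p_cs_minus == pytest.approx(72.22, abs=0.01)
        assert 100 * row.p_nc == pytest.approx(27.78, abs=0.01)

    def test_proportions_sum_to_one_and_cis_bracket(self):
        rng = np.random.default_rng(0)
        df = _trials_frame(
            {f"b{i}": rng.choice(["CS_PLUS", "CS_MINUS", "NC"], size=10) for i in range(12)}
        )
        cp = choice_proportions(df)
        totals = cp.p_cs_plus + cp.p_cs_minus + cp.p_nc
        assert np.allclose(totals, 1.0)
        for key in ("cs_plus", "cs_minus", "nc"):
            assert (cp[f"ci_low_{key}"] <= cp[f"p_{key}"] + 1e-12).all()
            assert (cp[f"ci_high_{key}"] >= cp[f"p_{key}"] - 1e-12).all()

    def test_empty_group_rejected(self):
        with pytest.raises(InputError):
            choice_proportions(pd.DataFrame(columns=["phase", "trial", "first_choice"]))


class TestPermutationTest:
    def test_p_within_estimator_bounds(self):
        rng = np.random.default_rng(1)
        df = _trials_frame(
            {f"b{i}": rng.choice(["CS_PLUS", "CS_MINUS"], size=10) for i in range(8)}
        )
        p = interaction_permutation_test(df, "cs", n_perm=199, seed=0)
        assert 1 / 200 <= p <= 1.0

    def test_degenerate_all_identical_gives_one(self):
        df = _trials_frame({f"b{i}": ["NC"] * 10 for i in range(6)})
        assert interaction_permutation_test(df, "cs", n_perm=199, seed=0) == 1.0

    def test_strong_learning_detected(self):
        # every bee switches from CS- to CS+ halfway through training
        df = _trials_frame({f"b{i}": ["CS_MINUS"] * 5 + ["CS_PLUS"] * 5 for i in range(17)})
        assert interaction_permutation_test(df, "cs", n_perm=999, seed=0) <= 0.01

    def test_condition_factor_contrast(self):
        learners = {f"l{i}": ["CS_MINUS"] * 5 + ["CS_PLUS"] * 5 for i in range(10)}
        flat = {f"n{i}": ["CS_PLUS", "CS_MINUS"] * 5 for i in range(10)}
        df = _trials_frame(learners | flat)
        cats = pd.DataFrame(
            {"bee_id": list(learners) + list(flat),
             "category": ["LEARNER"] * 10 + ["NON_LEARNER"] * 10}
        )
        p = interaction_permutation_test(
            df, "condition", categories=cats, n_perm=999, seed=0
        )
        assert p <= 0.01

    def test_too_few_permutations_rejected(self):
        df = _trials_frame({"b": ["CS_PLUS"] * 10})
        with pytest.raises(InputError):
            interaction_permutation_test(df, "cs", n_perm=10)


class TestMixedModels:
    @pytest.fixture(scope="class")
    def fitted(self):
        rng = np.random.default_rng(7)
        bees = [f"b{i}" for i in range(16)]
        trials = _trials_frame(
            {b: rng.choice(["CS_PLUS", "CS_MINUS"], size=10) for b in bees}
        )
        motor_rows = []
        for b in bees:
            for t in range(1, 11):
                motor_rows.append(
                    {"bee_id": b, "trial": t, "phase": "train",
                     "distance_cm": rng.normal(100, 5),
                     "speed_cm_s": rng.normal(2.5, 0.2),
                     "tortuosity": 1 + abs(rng.normal(0, 0.1))}
                )
        motor = pd.DataFrame(motor_rows)
        cats = pd.DataFrame(
            {"bee_id": bees, "category": ["LEARNER"] * 8 + ["NON_LEARNER"] * 8}
        )
        return fit_mixed_models(trials, motor, cats)

    def test_schema(self, fitted):
        assert {"choice_glmm", "distance_lmm", "speed_lmm", "tortuosity_lmm"} <= set(fitted)
        for table in fitted.values():
            assert {"term", "estimate", "statistic", "p", "converged"} <= set(table.columns)

    def test_null_data_fixed_effects_near_zero(self, fitted):
        lmm = fitted["distance_lmm"]
        trial_term = lmm[lmm.term.str.contains("trial") & ~lmm.term.str.contains(":")]
        assert abs(float(trial_term.estimate.iloc[0])) < 1.0  # cm per trial, null data

    def test_identical_bees_have_tiny_random_variance(self, fitted):
        lmm = fitted["speed_lmm"]
        var = float(lmm.loc[lmm.term == "random_intercept_var", "estimate"].iloc[0])
        assert var < 0.05  # no bee-level structure was simulated


class TestMotorSummaryTable:
    def test_matches_per_trial_summary(self, world, protocol):
        from beevr.protocol import run_session, sessions_to_tables
        from beevr.synth import AgentParams, WalkingAgent

        agent = WalkingAgent(AgentParams(), tick=world.tick)
        s = run_session(agent, world, protocol, seed=9, bee_id="m1")
        trials, traj = sessions_to_tables([s])
        table = motor_summary_table(traj, trials)
        rec = s.trials[0]
        m = motor_summary(rec)
        row = table[(table.trial == 1)].iloc[0]
        assert row.distance_cm == pytest.approx(m.distance)
        assert row.speed_cm_s == pytest.approx(m.speed)
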