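from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from icage.engine import (
    Outcome,
    PrecueStream,
    TrialRecord,
    adjudicate_visit,
    classify_trial,
    draw_precue,
    run_session,
    trials_to_frame,
)
from icage.schedule import Phase, build_default_protocol, CornerAssignment

from conftest import make_dataset, make_roster


def oracle_classify(pokes, D, C):
    """Independent interval-membership oracle: evaluate every poke's
    interval independently, earliest decisive poke wins."""
    decisive = [(t, "PREMATURE") for t in pokes if 0 < t < D]
    decisive += [(t, "CORRECT") for t in pokes if D <= t < D + C]
    if not decisive:
        return "ABANDONED", None
    t, label = min(decisive)
    return label, t


class TestClassifyTrial:
    def test_correct_inside_cue(self):
        assert classify_trial([2.5], 2.0, 7.0) == (Outcome.CORRECT, 2.5)

    def test_cue_window_boundaries(self):
        assert classify_trial([8.95], 8.0, 1.0)[0] == Outcome.CORRECT
        assert classify_trial([9.05], 8.0, 1.0)[0] == Outcome.ABANDONED
        # LED on exactly at D: boundary poke is correct
        assert classify_trial([8.0], 8.0, 1.0)[0] == Outcome.CORRECT

    def test_first_poke_decides(self):
        assert classify_trial([1.0, 5.0], 4.0, 3.0) == (Outcome.PREMATURE, 1.0)

    def test_no_pokes_abandoned(self):
        assert classify_trial([], 2.0, 7.0) == (Outcome.ABANDONED, None)

    def test_late_pokes_ignored(self):
        assert classify_trial([9.5, 12.0], 2.0, 7.0) == (Outcome.ABANDONED, None)

    def test_rejects_bad_offsets(self):
        with pytest.raises(ValueError):
            classify_trial([-1.0], 2.0, 7.0)
        with pytest.raises(ValueError):
            classify_trial([5.0, 3.0], 2.0, 7.0)
        with pytest.raises(ValueError):
            classify_trial([1.0], 0.0, 7.0)

    @settings(max_examples=300, deadline=None)
    @given(
        d_i=st.integers(0, 2),
        c_i=st.integers(0, 2),
        pokes=st.lists(st.floats(0.001, 15.0, allow_nan=False), max_size=6),
    )
    def test_matches_oracle_fuzzed(self, d_i, c_i, pokes):
        D = [2.0, 4.0, 8.0][d_i]
        C = [7.0, 3.0, 1.0][c_i]
        pokes = sorted(pokes)
        outcome, t = classify_trial(pokes, D, C)
        exp_label, exp_t = oracle_classify(pokes, D, C)
        assert outcome.value == exp_label
        assert t == exp_t


class TestDrawPrecue:
    def test_singleton(self):
        rng = np.random.default_rng(0)
        assert all(draw_precue(rng, [2.0]) == 2.0 for _ in range(100))

    def test_uniformity_3se(self):
        rng = np.random.default_rng(1)
        n = 30_000
        draws = [draw_precue(rng, (2.0, 4.0, 8.0)) for _ in range(n)]
        se = np.sqrt((1 / 3) * (2 / 3) / n)
        for v in (2.0, 4.0, 8.0):
            assert abs(np.mean(np.array(draws) == v) - 1 / 3) < 3 * se

    def test_seeded_determinism(self):
        a = [draw_precue(np.random.default_rng(5), (2.0, 4.0, 8.0)) for _ in range(1)]
        b = [draw_precue(np.random.default_rng(5), (2.0, 4.0, 8.0)) for _ in range(1)]
        assert a == b

    def test_empty_set(self):
        with pytest.raises(ValueError):
            draw_precue(np.random.default_rng(0), [])


class TestPrecueStream:
    def test_counter_based_independence(self):
        s = PrecueStream(3)
        seq1 = [s.draw("m1", i, (2.0, 4.0, 8.0)) for i in range(50)]
        # draws depend only on (seed, animal, index): recompute out of order
        seq2 = [PrecueStream(3).draw("m1", i, (2.0, 4.0, 8.0)) for i in reversed(range(50))]
        assert seq1 == list(reversed(seq2))

    def test_uniformity(self):
        s = PrecueStream(11)
        n = 30_000
        draws = np.array([s.draw("m1", i, (2.0, 4.0, 8.0)) for i in range(n)])
        se = np.sqrt((1 / 3) * (2 / 3) / n)
        for v in (2.0, 4.0, 8.0):
            assert abs((draws == v).mean() - 1 / 3) < 3 * se

    def test_seed_and_animal_sensitivity(self):
        base = [PrecueStream(3).draw("m1", i, (2.0, 4.0, 8.0)) for i in range(100)]
        other_seed = [PrecueStream(4).draw("m1", i, (2.0, 4.0, 8.0)) for i in range(100)]
        other_animal = [PrecueStream(3).draw("m2", i, (2.0, 4.0, 8.0)) for i in range(100)]
        assert base != other_seed and base != other_animal


def _mini_session(phase_day, visits, pokes, assignment_corner=1):
    """Run a handful of events through run_session on the default protocol."""
    t_lo = (phase_day - 1) * 86400.0
    roster = make_roster({"NonTg": 1})
    ds = make_dataset(
        [(vid, "NonTg01", c, t_lo + s, t_lo + e) for vid, c, s, e in visits],
        pokes=[(vid, "left", t_lo + t) for vid, t in pokes],
        roster=roster,
    )
    protocol = build_default_protocol()
    # NonTg01's PP corner so that reversal (= RT/avoidance corner) is assignment_corner
    asg = CornerAssignment(pp_corner={"NonTg01": {1: 4, 2: 3, 3: 2, 4: 1}[assignment_corner]})
    return run_session(ds, protocol, asg, seed=0)


WATER_T = 13 * 3600.0  # clock 19:00 -> inside the 18:00-21:00 window


class TestAdjudication:
    def test_pp_assigned_poke_opens_door(self):
        protocol = build_default_protocol()
        asg = CornerAssignment(pp_corner={"NonTg01": 2})
        t_lo = 10 * 86400.0  # day 11: PP
        ds = make_dataset(
            [(1, "NonTg01", 2, t_lo + WATER_T, t_lo + WATER_T + 60)],
            pokes=[(1, "left", t_lo + WATER_T + 5)],
            licks=[(1, t_lo + WATER_T + 10, 12)],
            roster=make_roster({"NonTg": 1}),
        )
        trials, annot = run_session(ds, protocol, asg, seed=0)
        assert trials.empty
        assert annot.loc[0, "door_opened"]

    def test_pp_outside_window_no_door(self):
        protocol = build_default_protocol()
        asg = CornerAssignment(pp_corner={"NonTg01": 2})
        t_lo = 10 * 86400.0
        ds = make_dataset(
            [(1, "NonTg01", 2, t_lo + 3600.0, t_lo + 3700.0)],  # clock 07:00
            pokes=[(1, "left", t_lo + 3605.0)],
            roster=make_roster({"NonTg": 1}),
        )
        _, annot = run_session(ds, protocol, asg, seed=0)
        assert not annot.loc[0, "door_opened"]

    def test_rt_nonassigned_corner_no_trial(self):
        # day 23 = RT3; visit corner 3 but assigned corner 1
        trials, annot = _mini_session(
            23, [(1, 3, WATER_T, WATER_T + 60)], [(1, WATER_T + 2), (1, WATER_T + 5)],
            assignment_corner=1,
        )
        assert trials.empty
        assert not annot.loc[0, "trial_initiated"]

    def test_rt_trial_initiated_and_rewarded(self):
        # RT1 (day 17): fixed 2 s pre-cue, 7 s cue; second poke at +3 s -> correct
        trials, annot = _mini_session(
            17, [(1, 1, WATER_T, WATER_T + 60)], [(1, WATER_T + 1), (1, WATER_T + 4)],
            assignment_corner=1,
        )
        assert len(trials) == 1
        row = trials.iloc[0]
        assert row["outcome"] == "CORRECT"
        assert row["precue"] == 2.0 and row["cue"] == 7.0
        assert bool(row["reward"]) and annot.loc[0, "door_opened"]

    def test_rt_correct_outside_window_unrewarded(self):
        trials, annot = _mini_session(
            17, [(1, 1, 3600.0, 3660.0)], [(1, 3601.0), (1, 3604.0)],
            assignment_corner=1,
        )
        assert trials.iloc[0]["outcome"] == "CORRECT"
        assert not bool(trials.iloc[0]["reward"])
        assert not annot.loc[0, "door_opened"]

    def test_rt_premature(self):
        trials, _ = _mini_session(
            17, [(1, 1, WATER_T, WATER_T + 60)], [(1, WATER_T + 1), (1, WATER_T + 2)],
            assignment_corner=1,
        )
        assert trials.iloc[0]["outcome"] == "PREMATURE"
        assert not bool(trials.iloc[0]["reward"])

    def test_avoidance_puff_no_door(self):
        # day 29: poke at assigned corner -> puff, never a door
        trials, annot = _mini_session(
            29, [(1, 1, WATER_T, WATER_T + 60), (2, 2, WATER_T + 100, WATER_T + 160)],
            [(1, WATER_T + 2), (2, WATER_T + 102)],
            assignment_corner=1,
        )
        assert trials.empty
        assert annot["puff"].tolist() == [True, False]
        assert not annot["door_opened"].any()

    def test_free_phase_no_trials_door_open(self):
        trials, annot = _mini_session(2, [(1, 2, 1000.0, 1100.0)], [])
        assert trials.empty
        assert annot.loc[0, "door_opened"]

    def test_extinction_any_corner_door(self):
        trials, annot = _mini_session(
            32, [(1, 3, WATER_T, WATER_T + 60)], [(1, WATER_T + 3)], assignment_corner=1
        )
        assert trials.empty
        assert annot.loc[0, "door_opened"]


class TestRunSession:
    def test_empty_dataset(self, protocol):
        ds = make_dataset([(1, "NonTg01", 1, 10.0, 20.0)], roster=make_roster({"NonTg": 1}))
        ds.visits = ds.visits.iloc[0:0]
        trials, annot = run_session(ds, protocol, CornerAssignment(pp_corner={"NonTg01": 1}), 0)
        assert trials.empty and annot.empty

    def test_replay_reproduces_ground_truth(self, tiny_sim):
        trials, _ = run_session(
            tiny_sim.dataset, tiny_sim.config.protocol, tiny_sim.assignment, tiny_sim.config.seed
        )
        pd.testing.assert_frame_equal(
            trials.reset_index(drop=True), tiny_sim.trials.reset_index(drop=True)
        )

    def test_animal_independence(self, tiny_sim):
        """Dropping one animal's events leaves the others' trials unchanged."""
        ds = tiny_sim.dataset.copy()
        victim = ds.animals["animal_id"].iloc[0]
        keep = ds.visits["animal_id"] != victim
        kept_ids = set(ds.visits.loc[keep, "visit_id"])
        ds.visits = ds.visits[keep]
        ds.pokes = ds.pokes[ds.pokes["visit_id"].isin(kept_ids)]
        ds.licks = ds.licks[ds.licks["visit_id"].isin(kept_ids)]
        trials, _ = run_session(ds, tiny_sim.config.protocol, tiny_sim.assignment, tiny_sim.config.seed)
        expected = tiny_sim.trials[tiny_sim.trials["animal_id"] != victim].reset_index(drop=True)
        pd.testing.assert_frame_equal(trials.reset_index(drop=True), expected)

    def test_trial_record_invariants_on_replay(self, tiny_sim):
        t = tiny_sim.trials
        corr = t[t["outcome"] == "CORRECT"]
        assert ((corr["t_response"] >= corr["t_init"] + corr["precue"])
                & (corr["t_response"] < corr["t_init"] + corr["precue"] + corr["cue"])).all()
        prem = t[t["outcome"] == "PREMATURE"]
        assert ((prem["t_response"] > prem["t_init"])
                & (prem["t_response"] < prem["t_init"] + prem["precue"])
                & ~prem["reward"]).all()
        aband = t[t["outcome"] == "ABANDONED"]
        assert aband["t_response"].isna().all() and (~aband["reward"]).all()
        # reward implies correct
        assert (t.loc[t["reward"], "outcome"] == "CORRECT").all()

    def test_trial_record_type_invariants(self):
        with pytest.raises(AssertionError):
            TrialRecord("a", 1, 1, 0.0, 2.0, 7.0, Outcome.CORRECT, 1.0, True)
        with pytest.raises(AssertionError):
            TrialRecord("a", 1, 1, 0.0, 2.0, 7.0, Outcome.ABANDONED, 5.0, False)
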