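import numpy as np
import pytest

from sackcog.behavior import (
    AttemptLog,
    LogConsistencyError,
    MoveEvent,
    attempt_metrics,
    first_full_knapsack,
    read_event_logs,
    replay,
    score_dataset,
    write_event_logs,
)
from sackcog.instances import Instance, Item
from sackcog.simulate import CohortDesign, ConditionEffects, simulate_cohort


def make_log(events, submit_t=100.0, instance_id="worked-3", **kw):
    defaults = dict(participant_id="P01", session=1, condition="PLC",
                    instance_id=instance_id, attempt_no=1,
                    events=tuple(events), submit_t=submit_t)
    defaults.update(kw)
    return AttemptLog(**defaults)


class TestReplay:
    def test_single_add(self):
        inst = Instance("i", (Item(0, 2, 1), Item(1, 1, 1)), 2)
        log = make_log([MoveEvent(1.0, 0, "add")], instance_id="i")
        states = replay(log, inst)
        assert [s.selected for s in states] == [{0}]

    def test_toggle_sequence(self):
        inst = Instance("i", (Item(0, 2, 1), Item(1, 1, 1)), 2)
        log = make_log(
            [MoveEvent(1, 0, "add"), MoveEvent(2, 0, "remove"), MoveEvent(3, 1, "add")],
            instance_id="i",
        )
        assert [s.selected for s in replay(log, inst)] == [{0}, set(), {1}]

    def test_capacity_violation_identified(self, worked_instance):
        log = make_log([MoveEvent(1, 0, "add"), MoveEvent(2, 1, "add"),
                        MoveEvent(3, 2, "add")])
        with pytest.raises(LogConsistencyError, match="event 2"):
            replay(log, worked_instance)

    def test_double_add_rejected(self, worked_instance):
        log = make_log([MoveEvent(1, 0, "add"), MoveEvent(2, 0, "add")])
        with pytest.raises(LogConsistencyError, match="already-selected"):
            replay(log, worked_instance)

    def test_remove_unselected_rejected(self, worked_instance):
        log = make_log([MoveEvent(1, 0, "remove")])
        with pytest.raises(LogConsistencyError, match="unselected"):
            replay(log, worked_instance)


class TestFirstFull:
    def test_greedy_trajectory_full_at_two_items(self, worked_instance):
        # {0,1}: weight 30, remaining 20 < 30 (item 2) -> full
        log = make_log([MoveEvent(1, 0, "add"), MoveEvent(2, 1, "add")])
        states = replay(log, worked_instance)
        ff = first_full_knapsack(states, worked_instance)
        assert ff is not None and ff.selected == {0, 1}

    def test_absent_when_items_still_fit(self, worked_instance):
        log = make_log([MoveEvent(1, 0, "add")])
        states = replay(log, worked_instance)
        assert first_full_knapsack(states, worked_instance) is None

    def test_all_items_selected_is_full(self):
        inst = Instance("i", (Item(0, 1, 1), Item(1, 1, 1)), 5)
        log = make_log([MoveEvent(1, 0, "add"), MoveEvent(2, 1, "add")],
                       instance_id="i")
        states = replay(log, inst)
        ff = first_full_knapsack(states, inst)
        assert ff.selected == {0, 1}


class TestAttemptMetrics:
    def test_perfect_one_move_solve(self):
        inst = Instance("i", (Item(0, 10, 5), Item(1, 1, 5)), 5)
        log = make_log([MoveEvent(2.0, 0, "add")], submit_t=10.0, instance_id="i")
        m = attempt_metrics(log, inst)
        assert m.correct and m.value_fraction == 1.0
        assert m.productivity == 1.0
        assert m.n_moves == 1 and m.time_s == 10.0 and m.sec_per_move == 10.0

    def test_greedy_submission_on_worked_instance(self, worked_instance):
        log = make_log([MoveEvent(1, 0, "add"), MoveEvent(2, 1, "add")], submit_t=30.0)
        m = attempt_metrics(log, worked_instance)
        assert not m.correct
        assert m.value_fraction == pytest.approx(160 / 220)
        assert m.first_full_overlap == 1      # {0,1} ∩ {1,2}
        assert m.greedy_opt_overlap == 1
        assert m.sahni_k == 2

    def test_zero_moves_gives_absent_per_move_fields(self, worked_instance):
        log = make_log([], submit_t=5.0)
        m = attempt_metrics(log, worked_instance)
        assert m.n_moves == 0
        assert m.sec_per_move is None and m.productivity is None
        assert not m.correct

    def test_productivity_definition(self, worked_instance):
        # submitted greedy value in 4 moves (with a toggle): 160/220 / 4
        log = make_log(
            [MoveEvent(1, 0, "add"), MoveEvent(2, 0, "remove"),
             MoveEvent(3, 0, "add"), MoveEvent(4, 1, "add")],
            submit_t=20.0,
        )
        m = attempt_metrics(log, worked_instance)
        assert m.productivity == pytest.approx((160 / 220) / 4)
        assert m.productivity * m.n_moves == pytest.approx(m.value_fraction)


class TestScoreDataset:
    def test_row_per_valid_log_and_rejects_reported(self, worked_instance):
        good = make_log([MoveEvent(1, 0, "add")], submit_t=5.0)
        bad = make_log([MoveEvent(1, 0, "remove")], submit_t=5.0, attempt_no=2)
        metrics, rejects = score_dataset([good, bad], [worked_instance])
        assert len(metrics) == 1
        assert len(rejects) == 1
        assert "unselected" in rejects.iloc[0]["reason"]

    def test_unresolvable_instance_raises_with_offenders(self, worked_instance):
        log = make_log([MoveEvent(1, 0, "add")], instance_id="nope")
        with pytest.raises(KeyError, match="nope"):
            score_dataset([log], [worked_instance])

    def test_full_cohort_design_arithmetic(self, instance_bank):
        design = CohortDesign(n_participants=8, n_instances=8)
        logs = simulate_cohort(design, ConditionEffects.null(), instance_bank, seed=3)
        assert len(logs) == 8 * 4 * 8 * 2
        metrics, rejects = score_dataset(logs, instance_bank)
        assert len(metrics) == len(logs) and rejects.empty

    def test_scoring_is_pure(self, worked_instance):
        log = make_log([MoveEvent(1, 0, "add")], submit_t=5.0)
        m1, _ = score_dataset([log], [worked_instance])
        m2, _ = score_dataset([log], [worked_instance])
        assert m1.equals(m2)


class TestMetricInvariants:
    def test_identities_on_simulated_attempts(self, cohort_metrics):
        m = cohort_metrics.dropna(subset=["productivity"])
        # productivity x n_moves == value_fraction, exact by construction
        np.testing.assert_allclose(
            m["productivity"] * m["n_moves"], m["value_fraction"], rtol=0, atol=1e-12
        )
        ok = cohort_metrics["first_full_overlap"].dropna()
        assert (ok >= 0).all()
        assert (cohort_metrics["correct"] == (cohort_metrics["value_fraction"] == 1.0)).all()


class TestEventLogCSV:
    def test_round_trip(self, tmp_path, instance_bank):
        design = CohortDesign(n_participants=2, n_instances=8)
        logs = simulate_cohort(design, ConditionEffects(), instance_bank, seed=5)
        path = tmp_path / "logs.csv"
        write_event_logs(logs, path)
        back = read_event_logs(path)
        assert len(back) == len(logs)
        for a, b in zip(logs, back):
            assert a.participant_id == b.participant_id
            assert a.instance_id == b.instance_id
            assert a.censored == b.censored
            assert a.submit_t == pytest.approx(b.submit_t, abs=5e-4)
            assert len(a.events) == len(b.events)
            assert all(x.item_index == y.item_index and x.action == y.action
                       for x, y in zip(a.events, b.events))

    def test_strict_header(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("foo,bar\n1,2\n")
        with pytest.raises(ValueError, match="header"):
            read_event_logs(path)
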