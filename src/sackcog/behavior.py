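"""Replay of attempt event logs and computation of behavioral outcomes.

An attempt log is the click stream of one participant working on one
knapsack instance: timestamped add/remove events plus a submission time.
Replaying a log against its instance reconstructs the selection state after
every event; the derived outcomes are the ones analysed downstream:

``correct``            submitted value equals the optimal value (exact,
                       integer arithmetic)
``value_fraction``     submitted value / optimal value
``time_s``             seconds from instance onset to submission
``n_moves``            number of add/remove events (effort)
``sec_per_move``       time_s / n_moves (inverse speed)
``productivity``       value_fraction / n_moves — net value gained per move
                       as a fraction of the optimum (quality of effort)
``first_full_overlap`` items shared between the first *full* knapsack (no
                       remaining item fits) and the optimal knapsack
``greedy_opt_overlap`` items shared between the greedy and optimal knapsacks

Productivity is defined on the *net* final value rather than the mean of
signed per-move increments; because every attempt starts from an empty
selection the two differ only by path cancellations, and the net reading is
the one used here throughout.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .instances import DifficultyProfile, Instance, ItemSet
from .solvers import difficulty_profile_for, greedy

__all__ = [
    "MoveEvent",
    "AttemptLog",
    "AttemptMetrics",
    "LogConsistencyError",
    "replay",
    "first_full_knapsack",
    "attempt_metrics",
    "score_dataset",
    "read_event_logs",
    "write_event_logs",
    "TIME_LIMIT_S",
    "CONDITIONS",
]

TIME_LIMIT_S = 240.0
CONDITIONS = ("PLC", "MPH", "DEX", "MOD")


class LogConsistencyError(ValueError):
    """An event log cannot be replayed against its instance."""


@dataclass(frozen=True)
class MoveEvent:
    t: float  # seconds from attempt start
    item_index: int
    action: str  # "add" | "remove"

    def __post_init__(self) -> None:
        if self.action not in ("add", "remove"):
            raise ValueError(f"action must be 'add' or 'remove', got {self.action!r}")
        if self.t < 0:
            raise ValueError(f"event time must be >= 0, got {self.t}")


@dataclass(frozen=True)
class AttemptLog:
    participant_id: str
    session: int
    condition: str
    instance_id: str
    attempt_no: int
    events: tuple[MoveEvent, ...]
    submit_t: float | None
    censored: bool = False

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.session not in (1, 2, 3, 4):
            raise ValueError(f"session must be 1..4, got {self.session}")
        if self.attempt_no not in (1, 2):
            raise ValueError(f"attempt_no must be 1 or 2, got {self.attempt_no}")
        ts = [e.t for e in self.events]
        if any(b < a for a, b in zip(ts, ts[1:])):
            raise ValueError("event times must be non-decreasing")
        if self.submit_t is not None:
            if ts and self.submit_t < ts[-1]:
                raise ValueError("submit_t must be >= last event time")
            if self.submit_t > TIME_LIMIT_S:
                raise ValueError(f"submit_t exceeds the {TIME_LIMIT_S:.0f}-s limit")
        if self.censored and self.submit_t != TIME_LIMIT_S:
            raise ValueError("censored attempts must have submit_t at the time limit")

    @property
    def n_moves(self) -> int:
        return len(self.events)


@dataclass(frozen=True)
class AttemptMetrics:
    participant_id: str
    session: int
    condition: str
    instance_id: str
    attempt_no: int
    correct: bool
    value_fraction: float
    time_s: float
    n_moves: int
    sec_per_move: float | None
    productivity: float | None
    first_full_overlap: int | None
    greedy_opt_overlap: int
    sahni_k: int
    dp_complexity: int
    censored: bool


def replay(log: AttemptLog, instance: Instance) -> list[ItemSet]:
    """Apply the log's events in order; return the selection state after each.

    Raises :class:`LogConsistencyError` (identifying the offending event) on
    an add of a selected item, a remove of an unselected item, an unknown
    item index, or a capacity violation — the task interface blocks
    selections that would exceed the weight limit, so a violating log cannot
    have come from a real attempt.
    """
    by_idx = instance.items_by_index
    selected: set[int] = set()
    weight = 0
    states: list[ItemSet] = []
    for k, ev in enumerate(log.events):
        item = by_idx.get(ev.item_index)
        if item is None:
            raise LogConsistencyError(
                f"event {k}: unknown item index {ev.item_index} for instance "
                f"{instance.instance_id!r}"
            )
        if ev.action == "add":
            if ev.item_index in selected:
                raise LogConsistencyError(f"event {k}: add of already-selected item {ev.item_index}")
            if weight + item.weight > instance.capacity:
                raise LogConsistencyError(
                    f"event {k}: adding item {ev.item_index} would exceed capacity "
                    f"({weight} + {item.weight} > {instance.capacity})"
                )
            selected.add(ev.item_index)
            weight += item.weight
        else:
            if ev.item_index not in selected:
                raise LogConsistencyError(f"event {k}: remove of unselected item {ev.item_index}")
            selected.remove(ev.item_index)
            weight -= item.weight
        states.append(ItemSet.from_indices(instance, selected))
    return states


def _is_full(state: ItemSet, instance: Instance) -> bool:
    remaining = instance.capacity - state.total_weight
    return all(
        it.weight > remaining for it in instance.items if it.index not in state.selected
    )


def first_full_knapsack(states: Sequence[ItemSet], instance: Instance) -> ItemSet | None:
    """First state (in event order) at which no unselected item fits.

    Returns None when the attempt was submitted without ever reaching a full
    knapsack.
    """
    for state in states:
        if _is_full(state, instance):
            return state
    return None


def attempt_metrics(
    log: AttemptLog,
    instance: Instance,
    profile: DifficultyProfile | None = None,
) -> AttemptMetrics:
    """Score one attempt: replay it and derive every behavioral outcome.

    ``profile`` may carry precomputed difficulty metrics; when omitted they
    are computed (and cached) from the instance.  Censored attempts (time
    limit reached) are scored like submissions.
    """
    states = replay(log, instance)
    prof, solved = difficulty_profile_for(instance)
    if profile is None:
        profile = prof
    final = states[-1] if states else ItemSet.from_indices(instance, ())
    opt = solved.optimal_value
    value_fraction = final.total_value / opt if opt > 0 else (1.0 if final.total_value == 0 else 0.0)
    correct = final.total_value == opt
    n_moves = log.n_moves
    time_s = log.submit_t if log.submit_t is not None else TIME_LIMIT_S
    sec_per_move = time_s / n_moves if n_moves > 0 else None
    productivity = value_fraction / n_moves if n_moves > 0 else None
    first_full = first_full_knapsack(states, instance)
    opt_set = solved.optimal_set.selected
    first_full_overlap = (
        len(first_full.selected & opt_set) if first_full is not None else None
    )
    greedy_opt_overlap = len(greedy(instance).selected & opt_set)
    return AttemptMetrics(
        participant_id=log.participant_id,
        session=log.session,
        condition=log.condition,
        instance_id=log.instance_id,
        attempt_no=log.attempt_no,
        correct=correct,
        value_fraction=value_fraction,
        time_s=time_s,
        n_moves=n_moves,
        sec_per_move=sec_per_move,
        productivity=productivity,
        first_full_overlap=first_full_overlap,
        greedy_opt_overlap=greedy_opt_overlap,
        sahni_k=profile.sahni_k,
        dp_complexity=profile.dp_complexity,
        censored=log.censored,
    )


def score_dataset(
    logs: Iterable[AttemptLog],
    instances: Mapping[str, Instance] | Sequence[Instance],
    profiles: Mapping[str, DifficultyProfile] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Score a collection of attempt logs into an attempt-level table.

    Returns ``(metrics, rejects)``: one metrics row per valid log, and a
    report of logs that failed replay (never silently dropped).  A log whose
    ``instance_id`` cannot be resolved raises ``KeyError`` listing all
    offenders, since that indicates a wiring error rather than a bad log.
    """
    if not isinstance(instances, Mapping):
        instances = {inst.instance_id: inst for inst in instances}
    logs = list(logs)
    missing = sorted({lg.instance_id for lg in logs} - instances.keys())
    if missing:
        raise KeyError(f"unresolvable instance_ids in logs: {missing}")
    rows, rejects = [], []
    for k, lg in enumerate(logs):
        prof = profiles.get(lg.instance_id) if profiles else None
        try:
            m = attempt_metrics(lg, instances[lg.instance_id], prof)
        except LogConsistencyError as exc:
            rejects.append(
                {
                    "log_index": k,
                    "participant_id": lg.participant_id,
                    "instance_id": lg.instance_id,
                    "attempt_no": lg.attempt_no,
                    "reason": str(exc),
                }
            )
            continue
        rows.append(vars(m).copy())
    metrics = pd.DataFrame(rows)
    if not metrics.empty:
        metrics["drug"] = (metrics["condition"] != "PLC").astype(int)
    return metrics, pd.DataFrame(rejects)


# ---------------------------------------------------------------------------
# Event-log CSV (strict schema, trailing submit row per attempt)
# ---------------------------------------------------------------------------

_LOG_COLUMNS = [
    "participant_id", "session", "condition", "instance_id", "attempt_no",
    "event_no", "t", "item_index", "action",
]


def write_event_logs(logs: Sequence[AttemptLog], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(_LOG_COLUMNS)
        for lg in logs:
            head = [lg.participant_id, lg.session, lg.condition, lg.instance_id, lg.attempt_no]
            for k, ev in enumerate(lg.events):
                w.writerow(head + [k, f"{ev.t:.3f}", ev.item_index, ev.action])
            submit_t = lg.submit_t if lg.submit_t is not None else TIME_LIMIT_S
            action = "censor" if lg.censored else "submit"
            w.writerow(head + [len(lg.events), f"{submit_t:.3f}", "", action])


def read_event_logs(path: str | Path) -> list[AttemptLog]:
    path = Path(path)
    groups: dict[tuple, dict] = {}
    order: list[tuple] = []
    with path.open("r", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames != _LOG_COLUMNS:
            raise ValueError(
                f"{path}: expected header {_LOG_COLUMNS}, got {reader.fieldnames}"
            )
        for lineno, row in enumerate(reader, start=2):
            key = (
                row["participant_id"], int(row["session"]), row["condition"],
                row["instance_id"], int(row["attempt_no"]),
            )
            if key not in groups:
                groups[key] = {"events": [], "submit_t": None, "censored": False}
                order.append(key)
            g = groups[key]
            action = row["action"]
            if action in ("submit", "censor"):
                g["submit_t"] = float(row["t"])
                g["censored"] = action == "censor"
            elif action in ("add", "remove"):
                g["events"].append(
                    MoveEvent(t=float(row["t"]), item_index=int(row["item_index"]), action=action)
                )
            else:
                raise ValueError(f"{path}:{lineno}: unknown action {action!r}")
    out = []
    for key in order:
        pid, session, condition, iid, attempt_no = key
        g = groups[key]
        out.append(
            AttemptLog(
                participant_id=pid, session=session, condition=condition,
                instance_id=iid, attempt_no=attempt_no,
                events=tuple(g["events"]), submit_t=g["submit_t"],
                censored=g["censored"],
            )
        )
    return out
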