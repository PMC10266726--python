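"""Synthetic crossover cohorts: Latin-square design and stochastic agents.

No raw behavioral data accompany the trial this package models, so the
analysis pipeline is exercised on simulated cohorts.  The generative model
is an explicitly assumption-bearing stand-in, pinned to two observations
about human knapsack solving: first full knapsacks resemble the greedy
solution, and drug conditions raise persistence (time, moves) while making
item choices more random.

The agent is a softmax-on-ratio local searcher.  While some unselected item
still fits it adds item *i* with probability proportional to
``exp((v_i/w_i)/T)``; at a full knapsack it either starts another
improvement episode (removing an item with probability proportional to
``exp(-(v_i/w_i)/T)``) or submits.  The submission hazard per full state is
``1/persistence``, so ``persistence`` is the expected number of improvement
episodes.  As the temperature T tends to 0 with persistence 1 the agent
reproduces the greedy trajectory exactly.  Participant ability enters as a
log-scale offset on temperature (higher ability -> lower effective
temperature), the simplest mechanism that produces participant-level
productivity random effects.  Inter-event intervals are exponential with
rate ``move_rate``; attempts are censored at the 4-minute task limit.

Default condition effects encode the directions reported for the trial:
active drugs raise persistence (more time and moves), raise temperature
(more random moves, lower productivity and first-full-knapsack quality), and
nudge move rate up slightly (speed was at most weakly affected).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .behavior import TIME_LIMIT_S, AttemptLog, CONDITIONS, MoveEvent
from .instances import Instance

__all__ = [
    "AgentParams",
    "ConditionEffects",
    "CohortDesign",
    "LATIN_SQUARE",
    "latin_square_assignment",
    "simulate_attempt",
    "simulate_cohort",
]

# Balanced 4x4 Latin square (Williams design: each condition once per row and
# column, and each ordered pair of conditions appears once).
LATIN_SQUARE: tuple[tuple[str, ...], ...] = (
    ("PLC", "MPH", "MOD", "DEX"),
    ("MPH", "DEX", "PLC", "MOD"),
    ("DEX", "MOD", "MPH", "PLC"),
    ("MOD", "PLC", "DEX", "MPH"),
)


@dataclass(frozen=True)
class AgentParams:
    """Latent parameters of one simulated participant under one condition."""

    ability: float = 0.0       # additive log-temperature offset; higher = better
    temperature: float = 0.10  # softmax noise of move choice (ratio units)
    persistence: float = 4.0   # expected number of improvement episodes
    move_rate: float = 0.3     # moves per second

    def __post_init__(self) -> None:
        if self.temperature <= 0 or self.move_rate <= 0:
            raise ValueError("temperature and move_rate must be > 0")
        if self.persistence < 1:
            raise ValueError("persistence must be >= 1")

    @property
    def effective_temperature(self) -> float:
        """Temperature after the ability offset: ``T * exp(-ability)``."""
        return self.temperature * math.exp(-self.ability)

    @property
    def effective_persistence(self) -> float:
        """Persistence after the ability offset.

        Less able participants wander through more improvement episodes for
        the same value gained: ``1 + (persistence - 1) * exp(-ability)``,
        floored at one episode.  Together with the temperature offset this is
        the source of participant-level productivity heterogeneity.
        """
        return 1.0 + (self.persistence - 1.0) * math.exp(-self.ability)


@dataclass(frozen=True)
class ConditionEffects:
    """Per-condition multipliers on the agent parameters; PLC is the
    all-ones reference."""

    temperature: dict[str, float] = field(
        default_factory=lambda: {"PLC": 1.0, "MPH": 1.8, "DEX": 1.8, "MOD": 1.4}
    )
    persistence: dict[str, float] = field(
        default_factory=lambda: {"PLC": 1.0, "MPH": 2.0, "DEX": 1.9, "MOD": 1.35}
    )
    move_rate: dict[str, float] = field(
        default_factory=lambda: {"PLC": 1.0, "MPH": 1.1, "DEX": 1.1, "MOD": 1.05}
    )

    def __post_init__(self) -> None:
        for name, mult in (("temperature", self.temperature),
                           ("persistence", self.persistence),
                           ("move_rate", self.move_rate)):
            missing = set(CONDITIONS) - mult.keys()
            if missing:
                raise ValueError(f"{name} multipliers missing conditions {sorted(missing)}")
            if not math.isclose(mult["PLC"], 1.0):
                raise ValueError(f"{name}: PLC multiplier must be 1 (reference condition)")

    @classmethod
    def null(cls) -> "ConditionEffects":
        ones = {c: 1.0 for c in CONDITIONS}
        return cls(temperature=dict(ones), persistence=dict(ones), move_rate=dict(ones))

    def apply(self, base: AgentParams, condition: str) -> AgentParams:
        """Condition-adjusted parameters for one session.

        The temperature multiplier both scales the noise level and damps the
        participant's ability offset by the same factor: injected randomness
        dilutes the influence of individual strategy quality.  This is what
        makes participant-level productivity differences shrink under the
        active conditions, as observed in the trial.
        """
        t_mult = self.temperature[condition]
        return replace(
            base,
            temperature=base.temperature * t_mult,
            ability=base.ability / t_mult,
            persistence=base.persistence * self.persistence[condition],
            move_rate=base.move_rate * self.move_rate[condition],
        )


@dataclass(frozen=True)
class CohortDesign:
    n_participants: int = 40
    n_instances: int = 8
    attempts_per_instance: int = 2
    conditions: tuple[str, ...] = CONDITIONS
    latin_square: tuple[tuple[str, ...], ...] = LATIN_SQUARE

    def __post_init__(self) -> None:
        for r, row in enumerate(self.latin_square):
            if sorted(row) != sorted(self.conditions):
                raise ValueError(f"latin square row {r} is not a permutation of conditions")
        for c in range(len(self.conditions)):
            col = [row[c] for row in self.latin_square]
            if sorted(col) != sorted(self.conditions):
                raise ValueError(f"latin square column {c} is not a permutation of conditions")

    @property
    def n_attempts(self) -> int:
        return (self.n_participants * len(self.conditions)
                * self.n_instances * self.attempts_per_instance)


def latin_square_assignment(design: CohortDesign, seed: int) -> list[tuple[str, ...]]:
    """Randomize participants to the rows of the Latin square.

    When ``n_participants`` is divisible by 4 each sequence is used exactly
    n/4 times; otherwise the remainder is assigned round-robin.  The
    assignment is a deterministic function of the seed.
    """
    rng = np.random.default_rng(seed)
    n = design.n_participants
    rows = list(design.latin_square)
    base, rem = divmod(n, len(rows))
    pool = []
    for r in range(len(rows)):
        pool.extend([r] * base)
    pool.extend(range(rem))  # round-robin remainder
    perm = rng.permutation(len(pool))
    return [rows[pool[i]] for i in perm]


def _softmax_pick(rng: np.random.Generator, indices: list[int], scores: list[float],
                  temperature: float) -> int:
    z = np.asarray(scores, dtype=float) / temperature
    z -= z.max()
    p = np.exp(z)
    p /= p.sum()
    return indices[int(rng.choice(len(indices), p=p))]


def simulate_attempt(
    instance: Instance,
    params: AgentParams,
    rng: np.random.Generator,
    participant_id: str = "sim",
    session: int = 1,
    condition: str = "PLC",
    attempt_no: int = 1,
) -> AttemptLog:
    """Simulate one attempt; the returned log always passes replay.

    The agent respects the capacity constraint by construction (it only ever
    adds items that fit, mirroring the task interface).  Event times
    accumulate exponential(rate=move_rate) gaps; the log is truncated and
    flagged censored if the 4-minute limit is reached.
    """
    temperature = params.effective_temperature
    submit_hazard = 1.0 / params.effective_persistence
    by_idx = instance.items_by_index
    # tiny value/weight/index tiebreak so the zero-temperature limit follows
    # the greedy order deterministically
    n = instance.n_items
    tie = {
        i: 1e-9 * by_idx[i].value - 1e-12 * by_idx[i].weight - 1e-15 * i
        for i in range(n)
    }
    selected: set[int] = set()
    weight = 0
    events: list[MoveEvent] = []
    t = 0.0
    censored = False
    submit_t: float | None = None
    while True:
        fitting = [i for i in range(n) if i not in selected
                   and by_idx[i].weight <= instance.capacity - weight]
        if fitting:
            scores = [by_idx[i].ratio + tie[i] for i in fitting]
            pick = _softmax_pick(rng, fitting, scores, temperature)
            action = "add"
        else:
            # full knapsack: submit with the per-episode hazard, else improve
            if rng.random() < submit_hazard or not selected:
                gap = rng.exponential(1.0 / params.move_rate)
                submit_t = t + gap
                break
            scores = [-(by_idx[i].ratio + tie[i]) for i in selected]
            pick = _softmax_pick(rng, sorted(selected),
                                 [-(by_idx[i].ratio + tie[i]) for i in sorted(selected)],
                                 temperature)
            action = "remove"
        gap = rng.exponential(1.0 / params.move_rate)
        t += gap
        if t > TIME_LIMIT_S:
            censored = True
            submit_t = TIME_LIMIT_S
            break
        events.append(MoveEvent(t=t, item_index=pick, action=action))
        if action == "add":
            selected.add(pick)
            weight += by_idx[pick].weight
        else:
            selected.remove(pick)
            weight -= by_idx[pick].weight
    if not censored:
        submit_t = min(submit_t, TIME_LIMIT_S)
        if submit_t >= TIME_LIMIT_S:
            censored = True
            submit_t = TIME_LIMIT_S
    return AttemptLog(
        participant_id=participant_id, session=session, condition=condition,
        instance_id=instance.instance_id, attempt_no=attempt_no,
        events=tuple(events), submit_t=submit_t, censored=censored,
    )


def simulate_cohort(
    design: CohortDesign,
    effects: ConditionEffects,
    instance_bank: Sequence[Instance],
    seed: int,
    ability_sd: float = 1.0,
    base_params: AgentParams = AgentParams(),
) -> list[AttemptLog]:
    """Simulate a full crossover cohort.

    Participant abilities are drawn Normal(0, ability_sd^2) and enter all
    four of that participant's sessions; condition multipliers are applied
    per session.  Every attempt uses an independent named random sub-stream
    (spawned from the cohort seed), so the log list is reproducible and
    independent of generation order.
    """
    if len(instance_bank) != design.n_instances:
        raise ValueError(
            f"instance bank has {len(instance_bank)} instances, design wants "
            f"{design.n_instances}"
        )
    root = np.random.SeedSequence(seed)
    ability_rng = np.random.default_rng(root.spawn(1)[0])
    abilities = ability_rng.normal(0.0, ability_sd, size=design.n_participants)
    orders = latin_square_assignment(design, seed=int(root.entropy) % (2**31))
    logs: list[AttemptLog] = []
    for p in range(design.n_participants):
        pid = f"P{p + 1:02d}"
        base = replace(base_params, ability=float(abilities[p]))
        for session, condition in enumerate(orders[p], start=1):
            params = effects.apply(base, condition)
            for j, inst in enumerate(instance_bank):
                for attempt_no in (1, 2):
                    child = np.random.SeedSequence(
                        entropy=root.entropy,
                        spawn_key=(1 + p, session, j, attempt_no),
                    )
                    rng = np.random.default_rng(child)
                    logs.append(
                        simulate_attempt(
                            inst, params, rng,
                            participant_id=pid, session=session,
                            condition=condition, attempt_no=attempt_no,
                        )
                    )
    return logs
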