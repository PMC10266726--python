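"""Knapsack instances: domain types, validation, I/O and random generation.

A 0-1 knapsack instance is a set of items, each with a strictly positive
integer value and weight, plus an integer capacity.  Integer arithmetic is
used throughout so that optimality checks are exact.  Instances are limited
to 64 items; exact enumeration oracles used in the test-suite require
``n <= 20``.
"""

from __future__ import annotations

import csv
import io
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Item",
    "Instance",
    "ItemSet",
    "DifficultyProfile",
    "InstanceValidationError",
    "SchemaError",
    "read_instances",
    "write_instances",
    "read_instances_csv",
    "write_instances_csv",
    "generate_instance",
    "generate_instance_bank",
    "load_trial_difficulty_profiles",
]

MAX_ITEMS = 64


class InstanceValidationError(ValueError):
    """An instance or item violates a structural invariant."""


class SchemaError(ValueError):
    """An instance file does not conform to the expected schema."""


@dataclass(frozen=True)
class Item:
    """A single knapsack item: 0-based index, positive value and weight."""

    index: int
    value: int
    weight: int

    def __post_init__(self) -> None:
        if self.value < 1 or self.weight < 1:
            raise InstanceValidationError(
                f"item {self.index}: value and weight must be >= 1 "
                f"(got value={self.value}, weight={self.weight})"
            )
        if self.index < 0:
            raise InstanceValidationError(f"item index must be >= 0, got {self.index}")

    @property
    def ratio(self) -> float:
        return self.value / self.weight


@dataclass(frozen=True)
class Instance:
    """A 0-1 knapsack problem: ordered items plus an integer capacity.

    ``trivial`` is True when every item fits simultaneously (capacity >= total
    weight); such instances are flagged rather than rejected.
    """

    instance_id: str
    items: tuple[Item, ...]
    capacity: int

    def __post_init__(self) -> None:
        n = len(self.items)
        if not 1 <= n <= MAX_ITEMS:
            raise InstanceValidationError(
                f"instance {self.instance_id!r}: need 1..{MAX_ITEMS} items, got {n}"
            )
        indices = [it.index for it in self.items]
        if sorted(indices) != list(range(n)):
            raise InstanceValidationError(
                f"instance {self.instance_id!r}: item indices must be a permutation "
                f"of 0..{n - 1}, got {indices}"
            )
        if self.capacity < 0:
            raise InstanceValidationError(
                f"instance {self.instance_id!r}: capacity must be >= 0"
            )

    @property
    def n_items(self) -> int:
        return len(self.items)

    @property
    def total_weight(self) -> int:
        return sum(it.weight for it in self.items)

    @property
    def trivial(self) -> bool:
        """All items fit at once; the instance poses no selection problem."""
        return self.capacity >= self.total_weight

    @property
    def min_weight(self) -> int:
        return min(it.weight for it in self.items)

    def item(self, index: int) -> Item:
        it = self.items_by_index.get(index)
        if it is None:
            raise KeyError(f"instance {self.instance_id!r} has no item {index}")
        return it

    @property
    def items_by_index(self) -> dict[int, Item]:
        return {it.index: it for it in self.items}

    def values_weights(self) -> tuple[np.ndarray, np.ndarray]:
        """Arrays of values and weights ordered by item index."""
        order = sorted(self.items, key=lambda it: it.index)
        v = np.array([it.value for it in order], dtype=np.int64)
        w = np.array([it.weight for it in order], dtype=np.int64)
        return v, w


@dataclass(frozen=True)
class ItemSet:
    """A feasible selection of items from one instance.

    Totals are stored redundantly for convenience but always recomputed from
    the item indices at construction, so they cannot drift.
    """

    instance_id: str
    selected: frozenset[int]
    total_value: int
    total_weight: int

    @classmethod
    def from_indices(cls, instance: Instance, indices: Iterable[int]) -> "ItemSet":
        sel = frozenset(int(i) for i in indices)
        by_idx = instance.items_by_index
        unknown = sel - by_idx.keys()
        if unknown:
            raise InstanceValidationError(
                f"instance {instance.instance_id!r}: unknown item indices {sorted(unknown)}"
            )
        tv = sum(by_idx[i].value for i in sel)
        tw = sum(by_idx[i].weight for i in sel)
        return cls(instance.instance_id, sel, tv, tw)

    def is_feasible(self, instance: Instance) -> bool:
        return self.total_weight <= instance.capacity

    def __len__(self) -> int:
        return len(self.selected)


@dataclass(frozen=True)
class DifficultyProfile:
    """Per-instance difficulty metrics.

    ``sahni_k`` and ``dp_complexity`` are computable by this package;
    ``minizinc_props`` (constraint-solver propagation count) is external
    metadata, only ever read from files.
    """

    instance_id: str
    sahni_k: int
    dp_complexity: int
    minizinc_props: int | None = None
    n_items: int | None = None

    def __post_init__(self) -> None:
        if self.sahni_k < 0 or self.dp_complexity < 0:
            raise InstanceValidationError(
                f"profile {self.instance_id!r}: metrics must be non-negative"
            )


# ---------------------------------------------------------------------------
# JSON format
# ---------------------------------------------------------------------------

def _instance_to_dict(inst: Instance) -> dict:
    order = sorted(inst.items, key=lambda it: it.index)
    return {
        "id": inst.instance_id,
        "capacity": inst.capacity,
        "items": [{"value": it.value, "weight": it.weight} for it in order],
    }


def _instance_from_dict(rec: dict, where: str) -> Instance:
    for key in ("id", "capacity", "items"):
        if key not in rec:
            raise SchemaError(f"{where}: missing field {key!r}")
    items = []
    for i, item_rec in enumerate(rec["items"]):
        for key in ("value", "weight"):
            if key not in item_rec:
                raise SchemaError(f"{where}, item {i}: missing field {key!r}")
        try:
            items.append(Item(index=i, value=int(item_rec["value"]),
                              weight=int(item_rec["weight"])))
        except InstanceValidationError as exc:
            raise InstanceValidationError(f"{where}, item {i}: {exc}") from exc
    return Instance(str(rec["id"]), tuple(items), int(rec["capacity"]))


def read_instances(path: str | Path) -> list[Instance]:
    """Read instances from a JSON file; item order is preserved exactly.

    Raises :class:`SchemaError` for malformed records (naming the offending
    record/field) and a duplicate-identifier error for repeated ids.
    """
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise SchemaError(f"{path}: not valid JSON ({exc})") from exc
    if not isinstance(doc, dict) or "instances" not in doc:
        raise SchemaError(f"{path}: top level must be an object with key 'instances'")
    out: list[Instance] = []
    seen: set[str] = set()
    for k, rec in enumerate(doc["instances"]):
        inst = _instance_from_dict(rec, f"{path}: instance record {k}")
        if inst.instance_id in seen:
            raise SchemaError(
                f"{path}: duplicate instance_id {inst.instance_id!r} (record {k})"
            )
        seen.add(inst.instance_id)
        out.append(inst)
    return out


def write_instances(instances: Sequence[Instance], path: str | Path) -> None:
    """Write instances to JSON; ``read_instances`` round-trips losslessly."""
    path = Path(path)
    doc = {"instances": [_instance_to_dict(inst) for inst in instances]}
    with path.open("w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=1)
        fh.write("\n")


# ---------------------------------------------------------------------------
# Flat CSV dialect: a capacity table followed by one row per item
# ---------------------------------------------------------------------------

def write_instances_csv(instances: Sequence[Instance], path: str | Path) -> None:
    """Flat CSV dialect: capacity rows, then one row per item."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["record", "instance_id", "item_index", "value", "weight", "capacity"])
        for inst in instances:
            w.writerow(["capacity", inst.instance_id, "", "", "", inst.capacity])
        for inst in instances:
            for it in sorted(inst.items, key=lambda x: x.index):
                w.writerow(["item", inst.instance_id, it.index, it.value, it.weight, ""])


def read_instances_csv(path: str | Path) -> list[Instance]:
    path = Path(path)
    capacities: dict[str, int] = {}
    items: dict[str, list[Item]] = {}
    order: list[str] = []
    with path.open("r", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"record", "instance_id", "item_index", "value", "weight", "capacity"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise SchemaError(f"{path}: header must contain {sorted(required)}")
        for lineno, row in enumerate(reader, start=2):
            kind = row["record"]
            iid = row["instance_id"]
            if kind == "capacity":
                if iid in capacities:
                    raise SchemaError(f"{path}:{lineno}: duplicate instance_id {iid!r}")
                capacities[iid] = int(row["capacity"])
                order.append(iid)
            elif kind == "item":
                try:
                    item = Item(index=int(row["item_index"]), value=int(row["value"]),
                                weight=int(row["weight"]))
                except (ValueError, InstanceValidationError) as exc:
                    raise SchemaError(f"{path}:{lineno}: {exc}") from exc
                items.setdefault(iid, []).append(item)
            else:
                raise SchemaError(f"{path}:{lineno}: unknown record type {kind!r}")
    out = []
    for iid in order:
        if iid not in items:
            raise SchemaError(f"{path}: instance {iid!r} has a capacity row but no items")
        out.append(Instance(iid, tuple(items[iid]), capacities[iid]))
    return out


# ---------------------------------------------------------------------------
# Random generation
# ---------------------------------------------------------------------------

_GENERATE_RETRIES = 20


def generate_instance(
    n: int,
    value_range: tuple[int, int] = (1, 100),
    weight_range: tuple[int, int] = (1, 100),
    capacity_fraction: float = 0.5,
    seed: int | np.random.Generator = 0,
    instance_id: str | None = None,
) -> Instance:
    """Generate a random instance with uniform integer values and weights.

    Capacity is ``capacity_fraction`` of the total weight, rounded half up so
    generation is bit-reproducible across platforms.  If no item fits within
    the capacity the draw is retried a bounded number of times before a
    ``ValueError`` is raised.
    """
    if n < 2:
        raise ValueError(f"need n >= 2 items, got {n}")
    if not (0.0 < capacity_fraction < 1.0):
        raise ValueError(f"capacity_fraction must be in (0, 1), got {capacity_fraction}")
    vlo, vhi = value_range
    wlo, whi = weight_range
    if vlo > vhi or wlo > whi or vlo < 1 or wlo < 1:
        raise ValueError("value_range and weight_range must be nonempty with lo >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    for _ in range(_GENERATE_RETRIES):
        values = rng.integers(vlo, vhi + 1, size=n)
        weights = rng.integers(wlo, whi + 1, size=n)
        total_w = int(weights.sum())
        # round half up, not banker's rounding
        capacity = int(np.floor(capacity_fraction * total_w + 0.5))
        if capacity >= int(weights.min()):
            iid = instance_id if instance_id is not None else f"gen-{n}"
            items = tuple(
                Item(index=i, value=int(values[i]), weight=int(weights[i]))
                for i in range(n)
            )
            return Instance(iid, items, capacity)
    raise ValueError(
        "could not generate a feasible instance (no item fits the capacity) "
        f"after {_GENERATE_RETRIES} attempts; relax capacity_fraction or weight_range"
    )


def generate_instance_bank(
    n_instances: int,
    seed: int,
    n_items: Sequence[int] = (10, 12),
    min_distinct_sahni: int | None = None,
    **kwargs,
) -> list[Instance]:
    """Generate a bank of instances, alternating item counts as in the task
    battery (10- and 12-item problems).

    ``min_distinct_sahni`` optionally enforces a difficulty spread: the bank
    is redrawn (bounded retries) until at least that many distinct Sahni-k
    values occur, mirroring a task battery whose instances span a range of
    difficulty.  A bank with constant difficulty would also make
    difficulty regressors collinear downstream.
    """
    rng = np.random.default_rng(seed)
    for _ in range(50):
        bank = []
        for k in range(n_instances):
            n = int(n_items[k % len(n_items)])
            bank.append(
                generate_instance(n, seed=rng, instance_id=f"inst-{k + 1:02d}", **kwargs)
            )
        if min_distinct_sahni is None:
            return bank
        from .solvers import difficulty_profile_for

        ks = {difficulty_profile_for(inst)[0].sahni_k for inst in bank}
        if len(ks) >= min_distinct_sahni:
            return bank
    raise ValueError(
        f"could not generate a bank with {min_distinct_sahni} distinct "
        "Sahni-k values; widen the instance parameters"
    )


def generate_matched_bank(
    targets: Sequence[tuple[int, int]],
    seed: int,
    max_tries: int = 5000,
    **kwargs,
) -> list[Instance]:
    """Generate a bank whose per-instance (item count, Sahni-k) match the
    given targets, by rejection sampling.

    ``targets`` is a list of (n_items, sahni_k) pairs — e.g. the difficulty
    profile of the trial battery from :func:`load_trial_difficulty_profiles`.  Useful
    when a simulated cohort should face the same difficulty mix as the
    original task battery.
    """
    from .solvers import SahniKNotFoundError
    from .solvers import sahni_k as _sahni_k
    from .solvers import solve_dp

    rng = np.random.default_rng(seed)
    bank: list[Instance] = []
    for idx, (n, k_target) in enumerate(targets):
        for _ in range(max_tries):
            inst = generate_instance(
                n, seed=rng, instance_id=f"inst-{idx + 1:02d}", **kwargs
            )
            opt = solve_dp(inst).optimal_value
            try:
                k = _sahni_k(inst, k_max=k_target, optimal_value=opt)
            except SahniKNotFoundError:
                continue
            if k == k_target:
                bank.append(inst)
                break
        else:
            raise ValueError(
                f"could not generate an instance with n={n}, Sahni-k={k_target} "
                f"in {max_tries} tries"
            )
    return bank


# ---------------------------------------------------------------------------
# Packaged difficulty-metadata fixture (eight trial instances)
# ---------------------------------------------------------------------------

def load_trial_difficulty_profiles() -> list[DifficultyProfile]:
    """Difficulty metadata of the eight knapsack instances used in the trial.

    The original item lists are not bundled; only per-instance difficulty
    metrics are (Sahni-k, DC complexity, and the MiniZinc propagation count
    reported for the published instances).
    """
    text = resources.files("sackcog.data").joinpath("trial_difficulty.csv").read_text()
    reader = csv.DictReader(io.StringIO(text))
    out = []
    for row in reader:
        out.append(
            DifficultyProfile(
                instance_id=row["instance_id"],
                n_items=int(row["n_items"]),
                sahni_k=int(row["sahni_k"]),
                dp_complexity=int(row["dc_complexity"]),
                minizinc_props=int(row["minizinc_props"]),
            )
        )
    return out
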