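"""Exact and heuristic 0-1 knapsack solvers and instance-difficulty metrics.

Two difficulty metrics are computed here:

* **Sahni-k** — the smallest number of items that must be placed in the
  knapsack before greedy completion (by decreasing value/weight ratio)
  attains the optimal value.  Sahni-k = 0 means the pure greedy algorithm is
  optimal ("easy" instances); difficulty increases with k.
* **DP complexity** — the amount of distinct work the dynamic-programming
  solution performs, measured as the number of non-dominated reachable
  (weight, value) states summed across item stages.  This is a documented
  variant of the dynamic-programming difficulty family; it is deterministic
  and monotone under item addition, but it is not claimed to be numerically
  identical to other published DP-based indices.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .instances import Instance, ItemSet

__all__ = [
    "SolverResult",
    "solve_bruteforce",
    "solve_dp",
    "greedy",
    "sahni_k",
    "dp_complexity",
    "difficulty_profile_for",
    "SahniKNotFoundError",
]

_BRUTEFORCE_MAX_N = 20
_DP_WORK_BOUND = 50_000_000  # (n+1) * (capacity+1) cells


class SahniKNotFoundError(RuntimeError):
    """No prefix of size <= k_max reaches the optimum under greedy completion."""


@dataclass(frozen=True)
class SolverResult:
    """Result of an exact solver run.

    ``optimal_set`` is the lexicographically smallest optimal index set (as a
    sorted tuple), which pins down a deterministic representative when the
    instance has multiple optima.  ``n_optima`` counts all distinct optimal
    sets.  ``states_visited`` is a solver-specific work counter.
    """

    optimal_value: int
    optimal_set: ItemSet
    n_optima: int
    states_visited: int


def _greedy_item_order(instance: Instance) -> list[int]:
    # decreasing value/weight; ties: higher value, then lower weight, then lower index
    items = sorted(
        instance.items,
        key=lambda it: (-it.value / it.weight, -it.value, it.weight, it.index),
    )
    return [it.index for it in items]


def solve_bruteforce(instance: Instance) -> SolverResult:
    """Enumerate all 2^n subsets (n <= 20); exact value, set and optimum count.

    The representative optimal set is the lexicographically smallest sorted
    index tuple among all optima.  Used as the oracle that other solvers are
    checked against.
    """
    n = instance.n_items
    if n > _BRUTEFORCE_MAX_N:
        raise ValueError(f"brute force limited to n <= {_BRUTEFORCE_MAX_N}, got {n}")
    v, w = instance.values_weights()
    masks = np.arange(1 << n, dtype=np.uint32)
    bits = (masks[:, None] >> np.arange(n, dtype=np.uint32)) & 1  # (2^n, n)
    tot_w = bits @ w
    tot_v = bits @ v
    feasible = tot_w <= instance.capacity
    best = int(tot_v[feasible].max())
    opt_masks = masks[feasible & (tot_v == best)]
    sets = [tuple(i for i in range(n) if m >> i & 1) for m in opt_masks]
    chosen = min(sets)
    return SolverResult(
        optimal_value=best,
        optimal_set=ItemSet.from_indices(instance, chosen),
        n_optima=len(sets),
        states_visited=1 << n,
    )


def _suffix_dp_table(v: np.ndarray, w: np.ndarray, capacity: int) -> np.ndarray:
    """best[i, c] = max value achievable with items i..n-1 under capacity c."""
    n = len(v)
    best = np.zeros((n + 1, capacity + 1), dtype=np.int64)
    for i in range(n - 1, -1, -1):
        best[i] = best[i + 1]
        wi = int(w[i])
        if wi <= capacity:
            take = best[i + 1, : capacity - wi + 1] + v[i]
            np.maximum(best[i, wi:], take, out=best[i, wi:])
    return best


def solve_dp(instance: Instance) -> SolverResult:
    """Classic 0-1 knapsack dynamic program over capacities 0..capacity.

    The backtrace includes the earliest-index item whenever an optimal
    completion through it exists, which yields the same lexicographically
    smallest optimal set as :func:`solve_bruteforce`.  ``n_optima`` counts
    distinct optimal subsets via a companion counting recursion, and
    ``states_visited`` is the number of (item, capacity) table cells.
    """
    n = instance.n_items
    capacity = instance.capacity
    if (n + 1) * (capacity + 1) > _DP_WORK_BOUND:
        raise ValueError(
            f"DP work bound exceeded: (n+1)*(capacity+1) = {(n + 1) * (capacity + 1)}"
        )
    v, w = instance.values_weights()
    best = _suffix_dp_table(v, w, capacity)
    optimal_value = int(best[0, capacity])

    # counting recursion over the same suffix structure (float to avoid overflow
    # is unnecessary: n <= 64 keeps counts < 2^64 only for pathological ties;
    # python ints via object dtype would be slow, int64 suffices in practice)
    count = np.zeros((n + 1, capacity + 1), dtype=np.int64)
    count[n] = 1
    for i in range(n - 1, -1, -1):
        wi = int(w[i])
        skip_ok = best[i] == best[i + 1]
        count[i][skip_ok] = count[i + 1][skip_ok]
        if wi <= capacity:
            cs = np.arange(wi, capacity + 1)
            take_ok = best[i, cs] == best[i + 1, cs - wi] + v[i]
            count[i, cs[take_ok]] += count[i + 1, cs[take_ok] - wi]

    # earliest-inclusion backtrace -> lexicographically smallest optimal set
    chosen: list[int] = []
    c = capacity
    need = optimal_value
    for i in range(n):
        wi = int(w[i])
        if wi <= c and v[i] + best[i + 1, c - wi] == need:
            chosen.append(i)
            c -= wi
            need -= int(v[i])
    return SolverResult(
        optimal_value=optimal_value,
        optimal_set=ItemSet.from_indices(instance, chosen),
        n_optima=int(count[0, capacity]),
        states_visited=n * (capacity + 1),
    )


def greedy(instance: Instance, prefix: frozenset[int] | set[int] = frozenset()) -> ItemSet:
    """Greedy completion: scan remaining items by decreasing value/weight
    ratio, adding each item that still fits (items that are too heavy are
    skipped, and scanning continues).

    Ratio ties are broken toward higher value, then lower weight, then lower
    index, so the result is deterministic.  ``prefix`` is a feasible set of
    item indices fixed in the knapsack before greedy takes over.
    """
    start = ItemSet.from_indices(instance, prefix)
    if start.total_weight > instance.capacity:
        raise ValueError(
            f"infeasible prefix: weight {start.total_weight} exceeds capacity "
            f"{instance.capacity}"
        )
    selected = set(start.selected)
    remaining = instance.capacity - start.total_weight
    by_idx = instance.items_by_index
    for idx in _greedy_item_order(instance):
        if idx in selected:
            continue
        if by_idx[idx].weight <= remaining:
            selected.add(idx)
            remaining -= by_idx[idx].weight
    return ItemSet.from_indices(instance, selected)


def sahni_k(
    instance: Instance,
    k_max: int | None = None,
    optimal_value: int | None = None,
) -> int:
    """Smallest k such that some feasible k-item prefix, completed by greedy,
    attains the optimal value.

    Success is judged on the optimal *value*, not the optimal set, because an
    instance may have several optima.  Prefixes of exactly size k are
    enumerated in lexicographic order, k increasing from 0, short-circuiting
    on the first success — which makes the returned k minimal.  k = 0 tests
    the pure greedy algorithm.
    """
    from itertools import combinations

    n = instance.n_items
    if k_max is None:
        k_max = n
    if k_max < 0:
        raise ValueError(f"k_max must be >= 0, got {k_max}")
    if optimal_value is None:
        optimal_value = solve_dp(instance).optimal_value
    by_idx = instance.items_by_index
    for k in range(min(k_max, n) + 1):
        for prefix in combinations(range(n), k):
            if sum(by_idx[i].weight for i in prefix) > instance.capacity:
                continue
            if greedy(instance, frozenset(prefix)).total_value == optimal_value:
                return k
    raise SahniKNotFoundError(
        f"no prefix of size <= {k_max} attains the optimum on "
        f"instance {instance.instance_id!r}"
    )


def dp_complexity(instance: Instance) -> int:
    """Number of non-dominated reachable (weight, value) states, summed over
    item stages of the dynamic program.

    After each item is considered, the reachable states are the feasible
    (total weight, total value) pairs of subsets of the items so far; a state
    is pruned when another state has no more weight and no less value.  A
    single fitting item therefore contributes the two states {empty, taken};
    identical items merge states, so duplication lowers the count.  The total
    is deterministic and non-decreasing when an item is appended.
    """
    v, w = instance.values_weights()
    capacity = instance.capacity
    # states kept as dict weight -> best value at that weight, then pruned to
    # the Pareto frontier (strictly increasing value with weight)
    states: dict[int, int] = {0: 0}
    total = 0
    for vi, wi in zip(v.tolist(), w.tolist()):
        merged = dict(states)
        for sw, sv in states.items():
            nw, nv = sw + wi, sv + vi
            if nw <= capacity and merged.get(nw, -1) < nv:
                merged[nw] = nv
        # dominance pruning: keep states whose value strictly exceeds every
        # lighter state's value
        pruned: dict[int, int] = {}
        best_v = -1
        for sw in sorted(merged):
            if merged[sw] > best_v:
                pruned[sw] = merged[sw]
                best_v = merged[sw]
        states = pruned
        total += len(states)
    return total


@lru_cache(maxsize=None)
def _cached_profile(instance: Instance):
    from .instances import DifficultyProfile

    res = solve_dp(instance)
    return (
        DifficultyProfile(
            instance_id=instance.instance_id,
            sahni_k=sahni_k(instance, optimal_value=res.optimal_value),
            dp_complexity=dp_complexity(instance),
            n_items=instance.n_items,
        ),
        res,
    )


def difficulty_profile_for(instance: Instance):
    """Compute (DifficultyProfile, SolverResult) for an instance, cached."""
    return _cached_profile(instance)
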