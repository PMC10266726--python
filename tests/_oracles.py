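"""Independent brute-force oracles shared by the unit and acceptance suites."""

from itertools import combinations

def oracle_greedy(instance, prefix=frozenset()):
    """Independent greedy: sort once, add what fits; used only as oracle."""
    items = sorted(
        instance.items,
        key=lambda it: (-it.value / it.weight, -it.value, it.weight, it.index),
    )
    sel = set(prefix)
    remaining = instance.capacity - sum(instance.item(i).weight for i in prefix)
    for it in items:
        if it.index not in sel and it.weight <= remaining:
            sel.add(it.index)
            remaining -= it.weight
    return sel


def oracle_sahni_k(instance, optimal_value):
    """Exhaustive minimal-prefix search over every size, no short-circuit
    order tricks: returns min k such that ANY feasible k-prefix completes to
    the optimum."""
    n = instance.n_items
    by_idx = instance.items_by_index
    for k in range(n + 1):
        for prefix in combinations(range(n), k):
            w = sum(by_idx[i].weight for i in prefix)
            if w > instance.capacity:
                continue
            sel = oracle_greedy(instance, frozenset(prefix))
            if sum(by_idx[i].value for i in sel) == optimal_value:
                return k
    raise AssertionError("unreachable: full optimal prefix always succeeds")


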