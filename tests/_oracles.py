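"""Brute-force enumeration oracles, independent of the package code paths."""

from itertools import combinations


def hypergeom_tail_enum(N: int, K: int, n: int, k: int) -> float:
    """P[X >= k] by enumerating every size-n draw from an N-item universe.

    The first K items are the successes; the tail is the fraction of
    draws containing at least k of them.
    """
    successes = set(range(K))
    total = 0
    hits = 0
    for draw in combinations(range(N), n):
        total += 1
        if len(successes.intersection(draw)) >= k:
            hits += 1
    return hits / total if total else 1.0


def jaccard_enum(a: set, b: set, universe: set) -> float:
    """|a∩b|/|a∪b| by counting element membership one item at a time."""
    inter = 0
    union = 0
    for item in universe:
        in_a = item in a
        in_b = item in b
        if in_a and in_b:
            inter += 1
        if in_a or in_b:
            union += 1
    return inter / union if union else 0.0
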