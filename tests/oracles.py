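"""Independent oracles used by the tests.

These deliberately re-derive expectations by brute force and never import
the implementation paths they check (beyond shared constants re-stated
here).
"""

from itertools import combinations

ORACLE_PAIR_WEIGHTS = {
    ("G", "C"): 3.0,
    ("C", "G"): 3.0,
    ("A", "U"): 2.0,
    ("U", "A"): 2.0,
    ("G", "U"): 1.0,
    ("U", "G"): 1.0,
}
ORACLE_STACK = 1.0
ORACLE_MIN_HAIRPIN = 3

CANONICAL = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}


def enumerate_structures(seq: str):
    """All non-crossing canonical structures of a short sequence (1-based pairs)."""
    n = len(seq)

    def rec(positions):
        if not positions:
            yield frozenset()
            return
        i = positions[0]
        rest = positions[1:]
        # i unpaired
        yield from rec(rest)
        # i paired with some j
        for j in rest:
            if j - i - 1 < ORACLE_MIN_HAIRPIN:
                continue
            if (seq[i - 1], seq[j - 1]) not in ORACLE_PAIR_WEIGHTS:
                continue
            inside = tuple(p for p in rest if i < p < j)
            outside = tuple(p for p in rest if p > j)
            for s_in in rec(inside):
                for s_out in rec(outside):
                    yield s_in | s_out | {(i, j)}

    yield from rec(tuple(range(1, n + 1)))


def oracle_score(seq: str, pairs) -> float:
    total = 0.0
    pairset = set(pairs)
    for i, j in pairset:
        total += ORACLE_PAIR_WEIGHTS[(seq[i - 1], seq[j - 1])]
        if (i + 1, j - 1) in pairset:
            total += ORACLE_STACK
    return total


def oracle_best(seq: str):
    """(best score, set of optimal structures) by exhaustive enumeration."""
    best = 0.0
    optima = [frozenset()]
    for s in enumerate_structures(seq):
        sc = oracle_score(seq, s)
        if sc > best + 1e-9:
            best = sc
            optima = [s]
        elif abs(sc - best) <= 1e-9 and s not in optima:
            optima.append(s)
    return best, optima


def brute_force_covarying(rows, column_pairs):
    """Count column pairs with >= 2 distinct canonical realizations.

    ``rows`` are gapped strings; ``column_pairs`` are 0-based column tuples.
    Re-counts over every (pair, row) combination from scratch.
    """
    count = 0
    for ci, cj in column_pairs:
        seen = set()
        for row in rows:
            a, b = row[ci], row[cj]
            if a != "-" and b != "-" and (a, b) in CANONICAL:
                seen.add((a, b))
        if len(seen) >= 2:
            count += 1
    return count


def greedy_tier_coloring(helix_spans):
    """Independent greedy interval-graph coloring of crossing helices.

    ``helix_spans`` are (outer_i, outer_j) outermost pairs sorted 5'->3';
    returns the number of tiers the greedy lowest-available rule needs.
    """

    def crosses(a, b):
        return (a[0] < b[0] < a[1] < b[1]) or (b[0] < a[0] < b[1] < a[1])

    tiers = []
    assignment = {}
    for k, span in enumerate(sorted(helix_spans)):
        t = 0
        while any(crosses(span, s) for s, tt in assignment.items() if tt == t):
            t += 1
        assignment[span] = t
        tiers.append(t)
    return max(tiers) + 1 if tiers else 0
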