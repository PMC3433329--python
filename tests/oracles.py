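"""Independent brute-force oracles used only by the tests.

Everything here is written as plainly as possible (character loops,
union-find) and stays independent of the package's vectorised
implementations.
"""

import math

BASES = set("ACGT")
TRANSITIONS = {frozenset("AG"), frozenset("CT")}


def naive_pair_counts(seq_a: str, seq_b: str):
    n_sites = ts = tv = 0
    for a, b in zip(seq_a, seq_b):
        if a not in BASES or b not in BASES:
            continue
        n_sites += 1
        if a != b:
            if frozenset((a, b)) in TRANSITIONS:
                ts += 1
            else:
                tv += 1
    return n_sites, ts, tv


def naive_k2p(seq_a: str, seq_b: str):
    n, ts, tv = naive_pair_counts(seq_a, seq_b)
    if n == 0:
        return math.nan
    p, q = ts / n, tv / n
    w1, w2 = 1 - 2 * p - q, 1 - 2 * q
    if w1 <= 0 or w2 <= 0:
        return math.nan
    return -0.5 * math.log(w1 * math.sqrt(w2))


def naive_distance_matrix(seqs: list[str], min_overlap: int = 0):
    """Dict of (i, j) -> distance or None (undefined)."""
    out = {}
    for i in range(len(seqs)):
        for j in range(i + 1, len(seqs)):
            n, _, _ = naive_pair_counts(seqs[i], seqs[j])
            d = naive_k2p(seqs[i], seqs[j])
            out[(i, j)] = None if (n < min_overlap or math.isnan(d)) else d
    return out


MISSING = {"N", "?"}


def naive_collapse(seqs: list[str], gap_is_state: bool):
    """Connected components of the zero-mismatch link relation, via
    union-find over an explicit all-pairs link matrix."""

    def column_conflict(x, y):
        if not gap_is_state:
            return x in BASES and y in BASES and x != y
        resolved = BASES | {"-"}
        if x in resolved and y in resolved and x != y:
            return True
        # fifth-state gaps also mismatch missing data
        return {x, y} & {"-"} and {x, y} & MISSING

    def linked(a, b):
        return not any(column_conflict(x, y) for x, y in zip(a, b))

    parent = list(range(len(seqs)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(seqs)):
        for j in range(i + 1, len(seqs)):
            if linked(seqs[i], seqs[j]):
                parent[find(i)] = find(j)
    groups = {}
    for i in range(len(seqs)):
        groups.setdefault(find(i), set()).add(i)
    return {frozenset(g) for g in groups.values()}


def naive_mean_sd_max(values):
    n = len(values)
    mean = sum(values) / n
    sd = math.sqrt(sum((v - mean) ** 2 for v in values) / (n - 1)) if n > 1 else 0.0
    return mean, sd, max(values)
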