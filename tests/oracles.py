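"""Independent brute-force oracles used by the test suite.

These deliberately re-derive the energy of a pairing/structure from its
definition (enumeration plus a standalone scorer) rather than calling the
dynamic programs they check.
"""

from __future__ import annotations

from mirserca.duplex_thermo import LOOP_CAP
from mirserca.flank_fold import FOLD_LOOP_CAP, MIN_HAIRPIN
from mirserca.model_io import ALLOWED_PAIRS, NNParameterTable

INF = float("inf")


def duplex_brute(m: str, w: str, params: NNParameterTable, cap: int = LOOP_CAP) -> float:
    """Minimum duplex energy by exhaustive enumeration of all legal chains."""
    M, W = len(m), len(w)
    pairs = [
        (i, j)
        for i in range(1, M + 1)
        for j in range(1, W + 1)
        if (m[i - 1], w[j - 1]) in ALLOWED_PAIRS
    ]
    best = 0.0

    def extend(chain, energy):
        nonlocal best
        i0, j0 = chain[-1]
        total = params.duplex_init + energy
        if total < best:
            best = total
        for i, j in pairs:
            ga, gb = i - i0 - 1, j0 - j - 1
            if ga < 0 or gb < 0 or ga > cap or gb > cap:
                continue
            if ga == 0 and gb == 0:
                link = params.stack_energy(
                    (m[i0 - 1], w[j0 - 1]), (m[i - 1], w[j - 1])
                )
            elif ga == 0 or gb == 0:
                link = params.bulge(ga + gb)
            else:
                link = params.internal(ga + gb)
            extend(chain + [(i, j)], energy + link)

    for p in pairs:
        extend([p], 0.0)
    return best


def score_structure(seq: str, pairs, params: NNParameterTable) -> float:
    """Score a set of non-crossing pairs loop by loop; INF if illegal."""
    pairs = sorted(pairs)
    children_of: dict = {}
    stack: list = []
    for i, j in pairs:
        while stack and not (stack[-1][0] < i and j < stack[-1][1]):
            stack.pop()
        if stack:
            children_of.setdefault(stack[-1], []).append((i, j))
        stack.append((i, j))
        children_of.setdefault((i, j), [])

    total = 0.0
    for p in pairs:
        i, j = p
        kids = children_of[p]
        if not kids:
            if j - i - 1 < MIN_HAIRPIN:
                return INF
            total += params.hairpin(j - i - 1)
        elif len(kids) == 1:
            k, l = kids[0]
            ga, gb = k - i - 1, j - l - 1
            if ga == 0 and gb == 0:
                total += params.stack_energy(
                    (seq[i - 1], seq[j - 1]), (seq[k - 1], seq[l - 1])
                )
            elif ga > FOLD_LOOP_CAP or gb > FOLD_LOOP_CAP:
                return INF
            elif ga == 0 or gb == 0:
                total += params.bulge(ga + gb)
            else:
                total += params.internal(ga + gb)
        else:
            unpaired = (j - i - 1) - sum(l - k + 1 for k, l in kids)
            total += (
                params.mb_offset
                + params.mb_per_branch * (len(kids) + 1)
                + params.mb_per_unpaired * unpaired
            )
    return total


def fold_brute(seq: str, params: NNParameterTable) -> float:
    """Minimum folding energy by enumerating every non-crossing pair set."""
    n = len(seq)
    cand = [
        (i, j)
        for i in range(1, n + 1)
        for j in range(i + MIN_HAIRPIN + 1, n + 1)
        if (seq[i - 1], seq[j - 1]) in ALLOWED_PAIRS
    ]
    best = 0.0

    def compatible(chosen, i, j):
        for a, b in chosen:
            if i in (a, b) or j in (a, b):
                return False
            if a < i < b < j or i < a < j < b:
                return False
        return True

    def rec(chosen, remaining):
        nonlocal best
        if chosen:
            e = score_structure(seq, chosen, params)
            if e < best:
                best = e
        for idx, (i, j) in enumerate(remaining):
            if compatible(chosen, i, j):
                rec(chosen + [(i, j)], remaining[idx + 1 :])

    rec([], cand)
    return best


def merge_brute(intervals):
    """Transitive overlap closure of 1-based inclusive intervals.

    Returns a list of frozensets of interval indices (the clusters).
    """
    n = len(intervals)
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a in range(n):
        for b in range(a + 1, n):
            (s1, e1), (s2, e2) = intervals[a], intervals[b]
            if s1 <= e2 and s2 <= e1:
                parent[find(a)] = find(b)
    clusters: dict = {}
    for i in range(n):
        clusters.setdefault(find(i), set()).add(i)
    return sorted(
        (frozenset(v) for v in clusters.values()), key=lambda s: min(s)
    )
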