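"""Independent brute-force oracle for BHV geodesic distances.

Enumerates every (P1)-valid ordered partition pair of the disjoint edge
sets and minimizes the path-length formula directly.  Written against
the geodesic *characterization*, not the GTP refinement algorithm, so it
can serve as an independent check on small trees (5-7 leaves).
"""

import itertools
import math

from treelens.tree import splits_compatible


def _ordered_set_partitions(items):
    """All ordered partitions of ``items`` into nonempty blocks."""
    items = list(items)
    if not items:
        yield []
        return
    n = len(items)
    for k in range(1, n + 1):
        for assignment in itertools.product(range(k), repeat=n):
            if set(assignment) != set(range(k)):
                continue  # some block empty / not surjective in order
            blocks = [[] for _ in range(k)]
            for item, b in zip(items, assignment):
                blocks[b].append(item)
            yield blocks


def brute_force_bhv(t1, t2):
    """Minimum path length over all valid supports (plus common edges)."""
    s1, s2 = t1.internal_edges, t2.internal_edges
    common_sq = 0.0
    A, B = {}, {}
    for s, l in s1.items():
        if s in s2:
            common_sq += (l - s2[s]) ** 2
        elif all(splits_compatible(s, t) for t in s2):
            common_sq += l ** 2
        else:
            A[s] = l
    for s, l in s2.items():
        if s in s1:
            continue
        if all(splits_compatible(s, t) for t in s1):
            common_sq += l ** 2
        else:
            B[s] = l

    if not A and not B:
        return math.sqrt(common_sq)

    def norm(block):
        return math.sqrt(sum(A.get(s, B.get(s)) ** 2 for s in block))

    best = math.inf
    for partsA in _ordered_set_partitions(list(A)):
        for partsB in _ordered_set_partitions(list(B)):
            if len(partsA) != len(partsB):
                continue
            # (P1): B_i compatible with A_j for all i < j
            ok = all(splits_compatible(b, a)
                     for i in range(len(partsA))
                     for j in range(i + 1, len(partsA))
                     for b in partsB[i] for a in partsA[j])
            if not ok:
                continue
            # (P2): non-decreasing drop/grow ratios; a support with
            # inverted ratios is not an achievable path length (the
            # true minimum in that path space merges the blocks)
            ratios = [norm(pa) / norm(pb)
                      for pa, pb in zip(partsA, partsB)]
            if any(r1 > r2 * (1 + 1e-12) + 1e-300
                   for r1, r2 in zip(ratios, ratios[1:])):
                continue
            sq = sum((norm(pa) + norm(pb)) ** 2
                     for pa, pb in zip(partsA, partsB))
            best = min(best, sq)
    return math.sqrt(best + common_sq)
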