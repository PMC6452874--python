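"""Independent brute-force oracles shared across test modules."""

import itertools


def brute_force_rank_sum_p(a, b):
    """Two-sided rank-sum p by enumerating every assignment of the pooled
    values to the two groups, computing U from pairwise wins directly
    (ties count 1/2) — no ranks, no shared code with the implementation."""
    pooled = list(a) + list(b)
    n1 = len(a)

    def u_stat(group_a, group_b):
        return sum(1.0 if x > y else 0.5 if x == y else 0.0
                   for x in group_a for y in group_b)

    mu = n1 * len(b) / 2.0
    obs = abs(u_stat(a, b) - mu)
    hits = total = 0
    for idx in itertools.combinations(range(len(pooled)), n1):
        ga = [pooled[i] for i in idx]
        gb = [pooled[i] for i in range(len(pooled)) if i not in idx]
        total += 1
        if abs(u_stat(ga, gb) - mu) >= obs - 1e-9:
            hits += 1
    return hits / total
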