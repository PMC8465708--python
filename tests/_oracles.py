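"""Independent oracles used by the tests.

These deliberately re-derive expected results by brute force or from an
alternative formulation (integer arithmetic, exhaustive enumeration), so
they share no code path with the implementations they check.
"""

from __future__ import annotations

import math
from itertools import combinations

from hdcminer.operon_mining import HDCA_ROLES, Role


def brute_force_cluster_sets(genes, roles, max_intervening):
    """All maximal clusters on one contig, by subset enumeration.

    A valid subset of role-bearing genes must (a) have every pair of
    consecutive members at most ``max_intervening`` genes apart, (b)
    contain a histidine decarboxylase and an antiporter themselves at
    most ``max_intervening`` genes apart.  Returns the set of maximal
    valid subsets, each as a frozenset of gene ordinals.
    """
    role_genes = [
        g
        for g in genes
        if g.protein_id in roles and roles[g.protein_id].role is not Role.OTHER
    ]
    valid = []
    for r in range(2, len(role_genes) + 1):
        for subset in combinations(role_genes, r):
            ords = [g.ordinal for g in subset]
            if any(b - a - 1 > max_intervening for a, b in zip(ords, ords[1:])):
                continue
            rs = [roles[g.protein_id].role for g in subset]
            hdca = [o for o, role in zip(ords, rs) if role in HDCA_ROLES]
            anti = [o for o, role in zip(ords, rs) if role is Role.ANTIPORTER]
            if not hdca or not anti:
                continue
            if not any(abs(a - b) - 1 <= max_intervening for a in hdca for b in anti):
                continue
            valid.append(frozenset(ords))
    return {s for s in valid if not any(s < t for t in valid)}


def ztest_oracle(x1, n1, x2, n2):
    """Continuity-corrected two-proportion z via integer arithmetic.

    Derived from the Yates-corrected chi-square identity for a 2x2
    table: z = sign(x1 n2 - x2 n1) * max(|x1 n2 - x2 n1| - N/2, 0)
    / (n1 n2 sqrt(pi(1-pi)(1/n1+1/n2))).
    """
    total = x1 + x2
    n = n1 + n2
    if total == 0 or total == n:
        return 0.0
    d_int = x1 * n2 - x2 * n1  # n1*n2*(p1-p2)
    num = max(abs(d_int) - n / 2, 0.0)
    pi = total / n
    se = math.sqrt(pi * (1 - pi) * (1 / n1 + 1 / n2))
    return math.copysign(num, d_int) / (n1 * n2 * se) if num else 0.0


def ranksum_exact_p(x, y):
    """One-sided rank-sum p by exhaustive enumeration (tie-free input)."""
    combined = sorted(x + y)
    assert len(set(combined)) == len(combined), "ties not supported"
    ranks = {v: i + 1 for i, v in enumerate(combined)}
    w_obs = sum(ranks[v] for v in x)
    n, n1 = len(combined), len(x)
    total = math.comb(n, n1)
    count = sum(1 for c in combinations(range(1, n + 1), n1) if sum(c) >= w_obs)
    return count / total
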