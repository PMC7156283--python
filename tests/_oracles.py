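"""Independent brute-force oracles used by the tests.

Each oracle recomputes a statistic from first principles (enumeration or a
double loop), deliberately sharing no code with the implementation paths it
checks.
"""

from __future__ import annotations

import itertools
from math import comb

import numpy as np


def exact_ranksum_p(x, y) -> float:
    """Two-sided rank-sum p by full enumeration (tie-free data only).

    Enumerates every assignment of the pooled ranks to the first group and
    counts assignments whose rank-sum is at least as far from its mean as
    the observed one.
    """
    x, y = list(x), list(y)
    pooled = x + y
    assert len(set(pooled)) == len(pooled), "oracle requires tie-free data"
    ranks = {v: r for r, v in enumerate(sorted(pooled), start=1)}
    n1 = len(x)
    w_obs = sum(ranks[v] for v in x)
    mean_w = n1 * (len(pooled) + 1) / 2
    extreme = 0
    total = 0
    for subset in itertools.combinations(sorted(pooled), n1):
        w = sum(ranks[v] for v in subset)
        total += 1
        if abs(w - mean_w) >= abs(w_obs - mean_w) - 1e-12:
            extreme += 1
    return extreme / total


def fisher_p_enumeration(table) -> float:
    """Two-sided Fisher exact p by hypergeometric enumeration.

    With margins fixed, sums the point probabilities of every table at most
    as probable as the observed one.
    """
    (a, b), (c, d) = table
    r1, c1, n = a + b, a + c, a + b + c + d

    def point(k: int) -> float:
        return comb(c1, k) * comb(n - c1, r1 - k) / comb(n, r1)

    p_obs = point(a)
    lo, hi = max(0, r1 - (n - c1)), min(r1, c1)
    return sum(point(k) for k in range(lo, hi + 1) if point(k) <= p_obs * (1 + 1e-9))


def axis_pairs_bruteforce(cells) -> dict[tuple[str, str], int]:
    """Shared-state-pair counts by a double loop over all cell pairs.

    ``cells``: DataFrame with columns clonotype_id, state; only clonotypes
    with >= 2 cells contribute.
    """
    counts: dict[tuple[str, str], int] = {}
    recs = list(cells[["clonotype_id", "state"]].itertuples(index=False))
    for i in range(len(recs)):
        for j in range(i + 1, len(recs)):
            if recs[i].clonotype_id == recs[j].clonotype_id:
                key = tuple(sorted((recs[i].state, recs[j].state)))
                counts[key] = counts.get(key, 0) + 1
    return counts


def nb_mixture_mean_molecules(lib_size_mean: float) -> float:
    """Expected molecules per cell: state profiles are normalized to sum 1,
    so the mean equals the lognormal library-size mean regardless of state."""
    return lib_size_mean
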