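"""Shared label-permutation machinery.

All permutation p-values in the package use the add-one convention
``p = (b + 1) / (m + 1)`` where b counts permuted statistics >= the observed
one and m is the number of permutations evaluated.  When the number of
*distinct* group labelings is small (<= ``exhaustive_limit``) the full set is
enumerated — including the observed labeling — instead of sampling.
"""

from __future__ import annotations

from math import factorial
from typing import Iterator, Sequence

import numpy as np

EXHAUSTIVE_LIMIT = 10_000


def n_distinct_labelings(labels: Sequence) -> int:
    """Multinomial coefficient n! / prod(n_g!) of distinct label orderings."""
    labels = list(labels)
    n = len(labels)
    out = factorial(n)
    for g in set(labels):
        out //= factorial(labels.count(g))
    return out


def _multiset_permutations(items: list) -> Iterator[list]:
    """Distinct permutations of a multiset (Knuth-style recursion)."""
    counts = {}
    for x in items:
        counts[x] = counts.get(x, 0) + 1
    keys = sorted(counts, key=str)
    current = [None] * len(items)

    def rec(pos: int):
        if pos == len(items):
            yield list(current)
            return
        for k in keys:
            if counts[k] > 0:
                counts[k] -= 1
                current[pos] = k
                yield from rec(pos + 1)
                counts[k] += 1

    yield from rec(0)


def iter_labelings(
    labels: Sequence,
    n_perm: int,
    seed: int | None,
    exhaustive_limit: int = EXHAUSTIVE_LIMIT,
) -> tuple[Iterator[list], int, bool]:
    """Yield labelings to evaluate plus their count and an exhaustive flag.

    Exhaustive mode enumerates every distinct labeling (the observed one
    included); sampled mode draws ``n_perm`` uniform shuffles with the given
    seed.
    """
    labels = list(labels)
    total = n_distinct_labelings(labels)
    if total <= exhaustive_limit:
        return _multiset_permutations(labels), total, True
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)

    def sampler():
        arr = np.asarray(labels, dtype=object)
        for _ in range(n_perm):
            yield list(rng.permutation(arr))

    return sampler(), n_perm, False


def add_one_p(n_ge: int, n_perm: int) -> float:
    return (n_ge + 1) / (n_perm + 1)
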