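"""Independent brute-force oracles used by the tests.

These deliberately avoid the package's own code paths: entropies are
recomputed from first principles and matrix spaces are enumerated
exhaustively, so agreement with the package is a genuine cross-check.
"""

from __future__ import annotations

import math
from itertools import product

import numpy as np


def compositions(total: int, bounds: tuple[int, ...]):
    """All ways to split ``total`` into parts no larger than ``bounds``."""
    if not bounds:
        if total == 0:
            yield ()
        return
    for v in range(min(total, bounds[0]), -1, -1):
        for rest in compositions(total - v, bounds[1:]):
            yield (v,) + rest


def integer_matrices_with_margins(r, c):
    """Enumerate all non-negative integer matrices with margins (r, c)."""
    r = list(r)
    c = np.asarray(c, dtype=int)

    def rec(i, remaining):
        if i == len(r):
            yield []
            return
        for row in compositions(r[i], tuple(int(x) for x in remaining)):
            for rest in rec(i + 1, remaining - np.array(row)):
                yield [list(row)] + rest

    for rows in rec(0, c.copy()):
        yield np.array(rows, dtype=int)


def binary_matrices_with_margins(r, c):
    """Enumerate all 0/1 matrices with margins (r, c)."""
    r = list(r)
    c = np.asarray(c, dtype=int)
    ncol = len(c)

    def rec(i, remaining):
        if i == len(r):
            yield []
            return
        for row in product((0, 1), repeat=ncol):
            if sum(row) != r[i]:
                continue
            rem = remaining - np.array(row)
            if (rem < 0).any():
                continue
            for rest in rec(i + 1, rem):
                yield [list(row)] + rest

    for rows in rec(0, c.copy()):
        yield np.array(rows, dtype=int)


def shannon(a: np.ndarray) -> float:
    """Shannon entropy of the cell frequencies, written independently."""
    flat = [x for x in np.asarray(a).ravel() if x > 0]
    total = sum(flat)
    return -sum((x / total) * math.log(x / total) for x in flat)


def h2_prime_exact(a: np.ndarray) -> float:
    """H2' with extremes from exhaustive enumeration of the margin class."""
    a = np.asarray(a, dtype=int)
    r, c = a.sum(axis=1), a.sum(axis=0)
    entropies = [
        shannon(m) for m in integer_matrices_with_margins(r.tolist(), c.tolist())
    ]
    h_min, h_max = min(entropies), max(entropies)
    if h_max - h_min < 1e-12:
        return 0.0
    return (h_max - shannon(a)) / (h_max - h_min)


def h2_extremes_exact(r, c) -> tuple[float, float]:
    entropies = [shannon(m) for m in integer_matrices_with_margins(list(r), list(c))]
    return min(entropies), max(entropies)


def d_raw_oracle(profile: np.ndarray, availability: np.ndarray) -> float:
    """Direct Kullback-Leibler summation for one species."""
    total = profile.sum()
    d = 0.0
    for p_ij, q_j in zip(profile, availability):
        if p_ij > 0:
            p = p_ij / total
            d += p * math.log(p / q_j)
    return d
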