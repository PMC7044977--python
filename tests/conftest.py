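"""Shared fixtures and independent brute-force oracles.

The oracles enumerate subject pairs directly and never touch the package's
cell-sum counting path, so they can arbitrate it.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest


def pair_counts_bruteforce(y: np.ndarray, g: np.ndarray) -> tuple[int, int, int]:
    """(C, D, ties) by enumerating all n(n-1)/2 subject pairs."""
    y = np.asarray(y)
    g = np.asarray(g)
    C = D = ties = 0
    n = y.size
    for i, j in itertools.combinations(range(n), 2):
        dy = y[i] - y[j]
        dg = g[i] - g[j]
        if dy == 0 or dg == 0:
            ties += 1
        elif (dy > 0) == (dg > 0):
            C += 1
        else:
            D += 1
    return C, D, ties


def gamma_bruteforce(y: np.ndarray, g: np.ndarray) -> float:
    """Gamma via pair enumeration; 0.0 when every pair is tied."""
    C, D, _ = pair_counts_bruteforce(y, g)
    return (C - D) / (C + D) if C + D else 0.0


def table_to_subjects(counts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Expand a contingency table into per-subject (row, col) code vectors."""
    counts = np.asarray(counts)
    ys, gs = [], []
    for (i, j), c in np.ndenumerate(counts):
        ys.extend([i] * int(c))
        gs.extend([j] * int(c))
    return np.asarray(ys), np.asarray(gs)


def random_table(rng: np.random.Generator, max_n: int = 60, max_dim: int = 5) -> np.ndarray:
    """A random sparse-ish contingency table with n <= max_n subjects."""
    I = rng.integers(1, max_dim + 1)
    J = rng.integers(1, max_dim + 1)
    n = rng.integers(1, max_n + 1)
    cells = rng.integers(0, I * J, size=n)
    return np.bincount(cells, minlength=I * J).reshape(I, J)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260929)
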