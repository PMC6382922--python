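"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own code paths: partition optima are
found by exhaustive enumeration, BH by the textbook step-up recipe.
"""

from __future__ import annotations

import numpy as np


def set_partitions(n: int) -> np.ndarray:
    """All partitions of ``range(n)`` as restricted-growth label arrays."""
    out: list[list[int]] = []

    def grow(labels: list[int], next_label: int):
        if len(labels) == n:
            out.append(labels.copy())
            return
        for lab in range(next_label + 1):
            labels.append(lab)
            grow(labels, max(next_label, lab + 1))
            labels.pop()

    grow([0], 1)
    return np.array(out, dtype=np.int64)


_MASK_CACHE: dict[int, np.ndarray] = {}


def partition_masks(n: int) -> np.ndarray:
    """(n_partitions, n, n) boolean same-module masks, cached per n."""
    if n not in _MASK_CACHE:
        parts = set_partitions(n)
        _MASK_CACHE[n] = parts[:, :, None] == parts[:, None, :]
    return _MASK_CACHE[n]


def exhaustive_best_objective(b: np.ndarray) -> float:
    """Max over all partitions of the ordered same-module sum of B."""
    n = b.shape[0]
    masks = partition_masks(n)
    vals = np.einsum("pij,ij->p", masks, b)
    return float(vals.max())


def bh_stepup(pvals) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values by the textbook recipe."""
    p = np.asarray(pvals, float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj
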