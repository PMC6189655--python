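"""Independent brute-force oracles used only by the tests.

Everything here is written with explicit Python loops straight from the
definitions, deliberately sharing no code with the package internals.
Grids are lists of per-item lists of category codes (None = missing).
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def ac1_oracle(grid, categories):
    """Gwet AC1 by direct summation of the defining formulas."""
    pa_terms = []
    pi_rows = []
    for row in grid:
        present = [v for v in row if v is not None]
        r_i = len(present)
        if r_i >= 1:
            pi_rows.append([present.count(q) / r_i for q in categories])
        if r_i >= 2:
            num = sum(present.count(q) * (present.count(q) - 1) for q in categories)
            pa_terms.append(num / (r_i * (r_i - 1)))
    if not pa_terms:
        raise ValueError("no usable item")
    pa = sum(pa_terms) / len(pa_terms)
    q_count = len(categories)
    pi = [sum(col) / len(pi_rows) for col in zip(*pi_rows)]
    pe = sum(p * (1 - p) for p in pi) / (q_count - 1) if q_count >= 2 else 0.0
    return (pa - pe) / (1 - pe)


def percent_oracle(grid):
    """Observed agreement: concordant rater pairs per item, averaged."""
    terms = []
    for row in grid:
        present = [v for v in row if v is not None]
        if len(present) < 2:
            continue
        pairs = list(itertools.combinations(present, 2))
        terms.append(sum(1 for a, b in pairs if a == b) / len(pairs))
    return sum(terms) / len(terms)


def jackknife_sd_oracle(grid, categories):
    """Delete-one-usable-item jackknife SD of AC1, looped explicitly."""
    usable_idx = [
        i for i, row in enumerate(grid) if sum(v is not None for v in row) >= 2
    ]
    values = []
    for i in usable_idx:
        reduced = [row for j, row in enumerate(grid) if j != i]
        values.append(ac1_oracle(reduced, categories))
    n = len(values)
    mean = sum(values) / n
    return math.sqrt((n - 1) / n * sum((v - mean) ** 2 for v in values))


def cohen_kappa_oracle(a, b):
    """Two-rater Cohen kappa on complete binary vectors."""
    n = len(a)
    po = sum(1 for x, y in zip(a, b) if x == y) / n
    cats = sorted(set(a) | set(b))
    pe = sum((a.count(c) / n) * (b.count(c) / n) for c in cats)
    return (po - pe) / (1 - pe)


def rank_permutation_test(x, y, n_perm=2000, seed=0):
    """Two-sided permutation test on the difference of mean ranks."""
    rng = np.random.default_rng(seed)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])

    def stat(values):
        order = values.argsort().argsort() + 1  # ranks, ties ignored (continuous data)
        return abs(order[: x.size].mean() - order[x.size :].mean())

    observed = stat(pooled)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        if stat(perm) >= observed - 1e-12:
            hits += 1
    return (hits + 1) / (n_perm + 1)


def random_grid(rng, n_items, n_raters, categories=("0", "1"), missing_prob=0.15):
    """A random grid guaranteed to contain one item with >= 2 ratings."""
    while True:
        grid = []
        for _ in range(n_items):
            row = [
                None if rng.random() < missing_prob else categories[rng.integers(len(categories))]
                for _ in range(n_raters)
            ]
            grid.append(row)
        if any(sum(v is not None for v in row) >= 2 for row in grid):
            return grid
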