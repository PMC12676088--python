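"""Independent brute-force oracles used to validate the fast implementations.

Everything here is deliberately literal and slow: pairwise loops for
nestedness, exhaustive set-partition enumeration for modularity, nested
bisection for the two-class null-model equations.  None of it shares code
with the package paths it checks.
"""

from __future__ import annotations

import itertools
from fractions import Fraction

import numpy as np
from scipy.optimize import brentq


def nodf_oracle(entries: np.ndarray) -> float:
    """Literal pairwise NODF: loop over row pairs and column pairs."""
    entries = np.asarray(entries)

    def layer_terms(mat):
        n = mat.shape[0]
        terms = []
        for i, j in itertools.combinations(range(n), 2):
            fi, fj = int(mat[i].sum()), int(mat[j].sum())
            if fi == fj or min(fi, fj) == 0:
                terms.append(0.0)
            else:
                lower, higher = (i, j) if fi < fj else (j, i)
                overlap = int((mat[lower] & mat[higher]).sum())
                terms.append(100.0 * overlap / int(mat[lower].sum()))
        return terms

    terms = layer_terms(entries) + layer_terms(entries.T)
    return sum(terms) / len(terms)


def barber_q_oracle(entries: np.ndarray, row_modules, col_modules) -> Fraction:
    """Barber Q as an exact rational, straight from the definition."""
    entries = np.asarray(entries, dtype=np.int64)
    k = entries.sum(axis=1)
    d = entries.sum(axis=0)
    e = int(entries.sum())
    q = Fraction(0)
    for i in range(entries.shape[0]):
        for j in range(entries.shape[1]):
            if row_modules[i] == col_modules[j]:
                q += Fraction(int(entries[i, j]), e) - Fraction(int(k[i]) * int(d[j]), e * e)
    return q


def set_partitions(items):
    """All set partitions of ``items`` (restricted-growth enumeration)."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for partition in set_partitions(rest):
        for i, block in enumerate(partition):
            yield partition[:i] + [[first] + block] + partition[i + 1 :]
        yield [[first]] + partition


def exhaustive_max_q(entries: np.ndarray) -> float:
    """Maximum Barber Q over every partition of all (row + column) nodes."""
    entries = np.asarray(entries, dtype=np.int64)
    n_r, n_c = entries.shape
    nodes = [("r", i) for i in range(n_r)] + [("c", j) for j in range(n_c)]
    best = Fraction(-10)
    for partition in set_partitions(nodes):
        rows = [0] * n_r
        cols = [0] * n_c
        for m, block in enumerate(partition):
            for layer, idx in block:
                if layer == "r":
                    rows[idx] = m
                else:
                    cols[idx] = m
        q = barber_q_oracle(entries, rows, cols)
        if q > best:
            best = q
    return float(best)


def bicm_two_class_oracle() -> tuple[float, float]:
    """Solve the two-unknown null-model system of the 3x3 degree sequence
    k = d = [2, 1, 1] by nested bisection.

    With one multiplier ``a`` for the degree-2 class and ``b`` for the
    degree-1 class (rows and columns share classes by symmetry), the
    expected-degree equations are

        a*a/(1+a*a) + 2*a*b/(1+a*b) = 2
        a*b/(1+a*b) + 2*b*b/(1+b*b) = 1
    """

    def eq2_solve_b(a: float) -> float:
        f = lambda b: a * b / (1 + a * b) + 2 * b * b / (1 + b * b) - 1.0  # noqa: E731
        return brentq(f, 1e-12, 1e8, xtol=1e-15, rtol=1e-15)

    def eq1(a: float) -> float:
        b = eq2_solve_b(a)
        return a * a / (1 + a * a) + 2 * a * b / (1 + a * b) - 2.0

    a = brentq(eq1, 1e-6, 1e8, xtol=1e-14, rtol=1e-15)
    return a, eq2_solve_b(a)
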