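"""Independent brute-force oracles used by the test suite.

These deliberately avoid the code paths they check: OLS by the closed-form
sums-of-squares formulae, elementary modes by exhaustive subset-rank
search, Pearson/slope by their definitional formulae.
"""

from __future__ import annotations

import math
from fractions import Fraction
from itertools import combinations


def ols_closed_form(x, y):
    """(slope, intercept) by the textbook sums formulae."""
    n = len(x)
    sx = sum(x)
    sy = sum(y)
    sxx = sum(v * v for v in x)
    sxy = sum(a * b for a, b in zip(x, y))
    slope = (n * sxy - sx * sy) / (n * sxx - sx * sx)
    intercept = (sy - slope * sx) / n
    return slope, intercept


def pearson_and_slope(x, y):
    """(r, slope of y on x) from definitional sums."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    return sxy / math.sqrt(sxx * syy), sxy / sxx


def _exact_nullspace(rows, cols_idx):
    """Nullspace basis of the submatrix with the given columns (Fractions)."""
    sub = [[row[j] for j in cols_idx] for row in rows]
    sub = [r for r in sub if any(v != 0 for v in r)]
    n = len(cols_idx)
    A = [r[:] for r in sub]
    pivots = []
    r = 0
    for c in range(n):
        piv = next((i for i in range(r, len(A)) if A[i][c] != 0), None)
        if piv is None:
            continue
        A[r], A[piv] = A[piv], A[r]
        inv = A[r][c]
        A[r] = [v / inv for v in A[r]]
        for i in range(len(A)):
            if i != r and A[i][c] != 0:
                f = A[i][c]
                A[i] = [v - f * w for v, w in zip(A[i], A[r])]
        pivots.append(c)
        r += 1
    free = [c for c in range(n) if c not in pivots]
    basis = []
    for fc in free:
        v = [Fraction(0)] * n
        v[fc] = Fraction(1)
        for i, pc in enumerate(pivots):
            v[pc] = -A[i][fc]
        basis.append(v)
    return basis


def _canonical(vec, irreversible):
    """Reduce an integer vector to canonical scale and sign, or None."""
    lcm = 1
    for v in vec:
        lcm = lcm * v.denominator // math.gcd(lcm, v.denominator)
    ints = [int(v * lcm) for v in vec]
    g = 0
    for v in ints:
        g = math.gcd(g, abs(v))
    ints = [v // g for v in ints]
    neg = [i for i, v in enumerate(ints) if v < 0 and irreversible[i]]
    pos = [i for i, v in enumerate(ints) if v > 0 and irreversible[i]]
    if neg and pos:
        return None  # sign-infeasible
    if neg:
        ints = [-v for v in ints]
    elif not pos:
        # fully reversible support: canonical sign = first nonzero positive
        first = next(v for v in ints if v != 0)
        if first < 0:
            ints = [-v for v in ints]
    return tuple(ints)


def brute_force_efms(network):
    """All elementary modes by subset-rank search (networks of <= ~12 reactions).

    A support J carries an elementary mode iff the stoichiometric submatrix
    S[:, J] has nullity exactly 1, the kernel vector is nonzero on all of J,
    and its sign can be chosen to satisfy every irreversibility in J.
    """
    S, _, _ = network.stoichiometric_matrix_exact()
    n = len(network.reactions)
    irrev = [not r.reversible for r in network.reactions]
    found = {}
    for size in range(1, n + 1):
        for J in combinations(range(n), size):
            basis = _exact_nullspace(S, list(J))
            if len(basis) != 1:
                continue
            k = basis[0]
            if any(v == 0 for v in k):
                continue  # true support is smaller
            full = [Fraction(0)] * n
            for j, v in zip(J, k):
                full[j] = v
            canon = _canonical(full, irrev)
            if canon is not None:
                found[canon] = full
    return sorted(found)
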