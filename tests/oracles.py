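"""Independent brute-force oracles used by the test suite.

These deliberately avoid the code paths they check: dense-matrix likelihood
instead of the spectral shortcut, exact rational arithmetic instead of scipy
distribution tails, literal set enumeration instead of the adjacency-based
module detector, and exhaustive rank permutations instead of the t
approximation.
"""

from fractions import Fraction
from itertools import permutations
from math import comb

import numpy as np
from scipy.optimize import minimize_scalar


def brute_force_reml_h(y, K, reml=True):
    """Variance-fraction estimate by direct dense-covariance likelihood.

    Builds Sigma(h) = h K + (1-h) I explicitly, evaluates the (restricted)
    log-likelihood with slogdet/solve, scans the same grid and refines.
    Scale is profiled analytically, matching the model definition.
    """
    y = np.asarray(y, dtype=float)
    y = y / y.std(ddof=1)
    n = y.size
    X = np.ones((n, 1))
    I = np.eye(n)

    def negll(h):
        sigma = h * K + (1.0 - h) * I
        sign, logdet = np.linalg.slogdet(sigma)
        si_y = np.linalg.solve(sigma, y)
        si_x = np.linalg.solve(sigma, X[:, 0])
        a = X[:, 0] @ si_x
        b = X[:, 0] @ si_y
        quad = y @ si_y - b * b / a
        if reml:
            dof = n - 1
            return 0.5 * (logdet + np.log(a) + dof * np.log(quad / dof))
        return 0.5 * (logdet + n * np.log(quad / n))

    grid = np.append(np.arange(0.0, 1.0, 0.01), 1.0 - 1e-6)
    vals = np.array([negll(h) for h in grid])
    i = int(np.argmin(vals))
    lo, hi = grid[max(i - 1, 0)], grid[min(i + 1, len(grid) - 1)]
    best_h, best_v = float(grid[i]), float(vals[i])
    if hi > lo:
        res = minimize_scalar(negll, bounds=(lo, hi), method="bounded",
                              options={"xatol": 1e-8})
        if res.success and res.fun < best_v:
            best_h, best_v = float(np.clip(res.x, 0.0, 1.0 - 1e-6)), float(res.fun)
    if best_v > vals[0] - 1e-9:
        best_h = 0.0
    return best_h


def exact_binomial_upper_tail(m, n, q):
    """P(X >= m), X ~ Binomial(n, q), in exact rational arithmetic.

    q is taken as the exact rational value of the float supplied.
    """
    qf = Fraction(*float(q).as_integer_ratio())
    total = Fraction(0)
    for k in range(m, n + 1):
        total += comb(n, k) * qf**k * (1 - qf) ** (n - k)
    return float(total)


def exact_hypergeom_upper_tail(k, set_size, module_size, universe_size):
    """P(X >= k) for the hypergeometric overlap, exact rational arithmetic."""
    total = Fraction(0)
    denom = comb(universe_size, module_size)
    for j in range(k, min(set_size, module_size) + 1):
        total += Fraction(
            comb(set_size, j) * comb(universe_size - set_size, module_size - j), denom
        )
    return float(total)


def exhaustive_spearman_pvalue(x, y):
    """Two-sided permutation p-value of |rho| by full enumeration (n <= 8)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size

    def rho(a, b):
        ra = np.argsort(np.argsort(a)).astype(float)
        rb = np.argsort(np.argsort(b)).astype(float)
        ra -= ra.mean()
        rb -= rb.mean()
        return float(ra @ rb / np.sqrt((ra @ ra) * (rb @ rb)))

    observed = abs(rho(x, y))
    count = 0
    total = 0
    for perm in permutations(range(n)):
        total += 1
        if abs(rho(x, y[list(perm)])) >= observed - 1e-12:
            count += 1
    return count / total


def enumerate_gene_modules(edges, source_tissue, target_tissue, min_size=10, ratio=0.1):
    """Literal re-implementation of the asymmetry rules by set enumeration.

    Works directly off the edge record list; returns
    {source gene: sorted member list} for modules passing both checks.
    """
    pairs = set()
    for rec in edges.records:
        if rec.tissue_a == source_tissue:
            pairs.add((rec.gene_a, rec.gene_b))
        else:
            pairs.add((rec.gene_b, rec.gene_a))
    sources = {s for s, _ in pairs}
    targets = {t for _, t in pairs}
    out = {}
    for s in sources:
        M = {t for (ss, t) in pairs if ss == s}
        m = len(M)
        if m < min_size:
            continue
        back_total = sum(len({a for (a, tt) in pairs if tt == j}) for j in M)
        am = back_total / m
        if not am < ratio * m:
            continue
        universe_b = set(edges.genes_b if source_tissue == edges.tissue_a else edges.genes_a)
        if s in (universe_b or targets):
            reverse = len({a for (a, tt) in pairs if tt == s})
            if not reverse < ratio * m:
                continue
        out[s] = sorted(M)
    return out
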