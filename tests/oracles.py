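"""Independent oracles used by the test suite.

These implement the same quantities as the package by different routes
(recursion instead of the tabular method, closed forms instead of library
fits, exhaustive enumeration instead of randomized search) and are kept
deliberately simple and slow.
"""

from __future__ import annotations

import itertools
from functools import lru_cache

import numpy as np


def kinship_recursive(parents: dict[str, tuple[str | None, str | None]]):
    """Pairwise coancestry by direct recursion over the pedigree.

    ``parents`` maps each id to its (sire, dam), with None for unknown.
    Returns a function f(i, j) giving the coancestry coefficient; the
    additive relationship is 2 f(i, j).
    """
    order = {}  # id -> depth, to recurse on the younger individual

    def depth(i: str) -> int:
        if i not in order:
            s, d = parents[i]
            order[i] = 1 + max(
                depth(s) if s else 0, depth(d) if d else 0
            )
        return order[i]

    @lru_cache(maxsize=None)
    def f(i: str, j: str) -> float:
        if i == j:
            s, d = parents[i]
            if s is None or d is None:
                return 0.5
            return 0.5 * (1.0 + f(*sorted((s, d))))
        # recurse through the parents of the later-born individual
        a, b = (i, j) if depth(i) >= depth(j) else (j, i)
        s, d = parents[a]
        fs = f(*sorted((s, b))) if s is not None else 0.0
        fd = f(*sorted((d, b))) if d is not None else 0.0
        return 0.5 * (fs + fd)

    return f


def relationship_matrix_recursive(parents: dict, ids: list[str]) -> np.ndarray:
    f = kinship_recursive(parents)
    n = len(ids)
    A = np.zeros((n, n))
    for a in range(n):
        for b in range(a, n):
            A[a, b] = A[b, a] = 2.0 * f(*sorted((ids[a], ids[b])))
    return A


def random_pedigree(rng: np.random.Generator, max_n: int = 12) -> dict:
    """A random valid pedigree: id -> (sire, dam), parents born earlier."""
    n = int(rng.integers(2, max_n + 1))
    parents: dict[str, tuple[str | None, str | None]] = {}
    ids = [f"I{k}" for k in range(n)]
    for k, iid in enumerate(ids):
        if k < 2 or rng.random() < 0.3:
            parents[iid] = (None, None)
        else:
            s, d = rng.choice(k, size=2, replace=True)
            sire = ids[int(s)]
            dam = ids[int(d)] if d != s else None
            if rng.random() < 0.1:
                sire = None
            parents[iid] = (sire, dam)
    return parents


def ols_closed_form(x, y, through_origin: bool = False):
    """Slope, intercept, and slope SE of simple OLS, via the textbook formulas."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if through_origin:
        slope = float(np.sum(x * y) / np.sum(x * x))
        resid = y - slope * x
        se = float(np.sqrt(np.sum(resid**2) / (n - 1) / np.sum(x * x)))
        return slope, 0.0, se
    xbar, ybar = x.mean(), y.mean()
    sxx = np.sum((x - xbar) ** 2)
    slope = float(np.sum((x - xbar) * (y - ybar)) / sxx)
    intercept = float(ybar - slope * xbar)
    resid = y - intercept - slope * x
    se = float(np.sqrt(np.sum(resid**2) / max(n - 2, 1) / sxx))
    return slope, intercept, se


def enumerate_cross_plans(n: int, k: int):
    """All simple graphs on n nodes where every node has degree k.

    When n*k is odd, exact k-regularity is impossible; plans where exactly
    one node has degree k-1 are enumerated instead ("up to k").
    """
    all_edges = list(itertools.combinations(range(n), 2))
    m, odd = divmod(n * k, 2)
    plans = []
    for subset in itertools.combinations(all_edges, m):
        deg = [0] * n
        for a, b in subset:
            deg[a] += 1
            deg[b] += 1
        if odd == 0:
            if all(d == k for d in deg):
                plans.append(subset)
        else:
            short = [d for d in deg if d != k]
            if len(short) == 1 and short[0] == k - 1:
                plans.append(subset)
    return plans


def best_plan_objective(n: int, k: int, Avals: np.ndarray) -> float:
    """Exhaustive minimum of the mean-relatedness objective."""
    best = np.inf
    for plan in enumerate_cross_plans(n, k):
        obj = float(np.mean([Avals[a, b] for a, b in plan]))
        best = min(best, obj)
    return best


def bh_stepup(raw):
    """Hand evaluation of the Benjamini-Hochberg step-up adjustment."""
    p = np.asarray(raw, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, m * p[idx] / rank)
        adj[idx] = running
    return adj
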