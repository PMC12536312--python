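"""Minimum-kinship cross assignment.

Each selected parent is to take part in ``k`` crosses with distinct partners
(the species is self-incompatible, so selfing is forbidden).  Among all such
assignments the designer searches for the one minimizing the mean additive
relationship over the assigned pairs: random feasible plans are constructed
repeatedly from a seeded stream and the best is kept, optionally refined by a
strictly-improving pairwise-exchange local search.

A plan is a simple k-regular graph on the parents (complete graph when
``k = n - 1``); when ``n * k`` is odd or a parent cannot reach ``k`` distinct
partners the plan carries "up to k" crosses with the shortfall minimized and
reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .pedigree import RelationshipMatrix

__all__ = ["CrossPlan", "FeasibilityError", "random_feasible_plan", "minimize_relatedness"]


class FeasibilityError(ValueError):
    """No cross plan satisfies the pairing constraints."""


@dataclass(frozen=True)
class CrossPlan:
    """An assignment of mating pairs with its relatedness objective."""

    crosses: tuple[tuple[str, str], ...]  # unordered pairs, each sorted
    per_parent_count: dict[str, int]
    objective: float | None  # mean A_ij over crosses; None if no A supplied
    seed: int
    restarts_used: int = 1
    shortfall: dict[str, int] = field(default_factory=dict)  # parent -> k - degree
    candidate_objectives: tuple[float, ...] = ()  # audit trail, one per restart

    def __post_init__(self) -> None:
        for a, b in self.crosses:
            if a == b:
                raise ValueError(f"self-cross {a} x {b} is not allowed")
        if len(set(self.crosses)) != len(self.crosses):
            raise ValueError("duplicate cross pairs in plan")


def _edge_set_stats(edges: list[tuple[int, int]], n: int) -> np.ndarray:
    deg = np.zeros(n, dtype=int)
    for a, b in edges:
        deg[a] += 1
        deg[b] += 1
    return deg


def _random_regular_edges(
    n: int, k: int, rng: np.random.Generator, max_tries: int = 200
) -> list[tuple[int, int]]:
    """Seeded construction of a (near-)k-regular simple graph on n nodes.

    Stub pairing with swap repair; if n*k is odd one random node gets k-1.
    Returns edges as sorted index pairs.
    """
    if k == n - 1:  # only feasible plan is the complete graph
        return [(a, b) for a in range(n) for b in range(a + 1, n)]
    degrees = np.full(n, k, dtype=int)
    if (n * k) % 2 == 1:
        degrees[rng.integers(n)] -= 1
    for _ in range(max_tries):
        stubs = np.repeat(np.arange(n), degrees)
        rng.shuffle(stubs)
        pairs = [tuple(sorted(p)) for p in zip(stubs[0::2], stubs[1::2])]
        # split into valid edges and violations (self-loops, repeated pairs)
        good: set[tuple[int, int]] = set()
        bad: list[tuple[int, int]] = []
        for p in pairs:
            if p[0] == p[1] or p in good:
                bad.append(p)
            else:
                good.add(p)
        # swap repair: replace a bad edge and a random good edge by a rewiring
        repair_budget = 50 * (len(bad) + 1)
        good_list = list(good)
        while bad and repair_budget > 0 and good_list:
            repair_budget -= 1
            a, b = bad[-1]
            c, d = good_list[rng.integers(len(good_list))]
            for x, y in (((a, c), (b, d)), ((a, d), (b, c))):
                e1, e2 = tuple(sorted(x)), tuple(sorted(y))
                if (
                    e1[0] != e1[1] and e2[0] != e2[1]
                    and e1 != e2 and e1 not in good and e2 not in good
                ):
                    bad.pop()
                    good.discard((c, d))
                    good_list = list(good | {e1, e2})
                    good |= {e1, e2}
                    break
        if not bad:
            return sorted(good)
    raise FeasibilityError(
        f"could not construct a simple {k}-regular pairing on {n} parents"
    )


def random_feasible_plan(
    parents: Sequence[str],
    k: int,
    rng_seed: int | np.random.Generator = 0,
    *,
    A: RelationshipMatrix | None = None,
) -> CrossPlan:
    """A seeded random cross plan with each parent in (up to) k crosses."""
    parents = [str(p) for p in parents]
    n = len(parents)
    if n < 2:
        raise FeasibilityError("need at least 2 parents (no self-crosses)")
    if k < 1:
        raise FeasibilityError("k must be at least 1")
    if k > n - 1:
        raise FeasibilityError(
            f"k={k} infeasible with {n} parents and distinct partners; "
            f"maximum k is {n - 1}"
        )
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    seed = int(rng_seed) if not isinstance(rng_seed, np.random.Generator) else -1
    edges = _random_regular_edges(n, k, rng)
    crosses = tuple(
        (parents[a], parents[b]) if parents[a] <= parents[b] else (parents[b], parents[a])
        for a, b in edges
    )
    deg = _edge_set_stats(edges, n)
    shortfall = {parents[i]: k - int(deg[i]) for i in range(n) if deg[i] < k}
    objective = _objective(crosses, A) if A is not None else None
    return CrossPlan(
        crosses=crosses,
        per_parent_count={parents[i]: int(deg[i]) for i in range(n)},
        objective=objective,
        seed=seed,
        shortfall=shortfall,
    )


def _objective(
    crosses: Sequence[tuple[str, str]], A: RelationshipMatrix, kind: str = "mean"
) -> float:
    vals = [A.loc(a, b) for a, b in crosses]
    if kind == "mean":
        return float(np.mean(vals))
    if kind == "sum":
        return float(np.sum(vals))
    if kind == "max":
        return float(np.max(vals))
    raise ValueError(f"unknown objective {kind!r}")


def _local_search(
    edges: list[tuple[int, int]],
    Avals: np.ndarray,
    swaps: int,
    rng: np.random.Generator,
) -> list[tuple[int, int]]:
    """Strictly-improving 2-edge exchanges preserving all degrees."""
    edge_set = set(edges)
    edges = list(edges)
    m = len(edges)
    for _ in range(swaps):
        i, j = rng.integers(m), rng.integers(m)
        if i == j:
            continue
        a, b = edges[i]
        c, d = edges[j]
        if len({a, b, c, d}) < 4:
            continue
        current = Avals[a, b] + Avals[c, d]
        best_delta = 0.0
        best = None
        for x, y in (((a, c), (b, d)), ((a, d), (b, c))):
            e1, e2 = tuple(sorted(x)), tuple(sorted(y))
            if e1 in edge_set or e2 in edge_set:
                continue
            delta = Avals[e1[0], e1[1]] + Avals[e2[0], e2[1]] - current
            if delta < best_delta - 1e-15:
                best_delta = delta
                best = (e1, e2)
        if best is not None:
            edge_set.discard(edges[i])
            edge_set.discard(edges[j])
            edges[i], edges[j] = best
            edge_set |= set(best)
    return edges


def minimize_relatedness(
    parents: Sequence[str],
    A: RelationshipMatrix,
    k: int,
    *,
    restarts: int = 100,
    swaps: int = 0,
    rng_seed: int = 0,
    objective: str = "mean",
) -> CrossPlan:
    """Best cross plan over seeded random restarts (plus optional local search).

    Deterministic given ``rng_seed``.  The returned plan's
    ``candidate_objectives`` records the objective of every restart's
    candidate, so the result is auditable as the best retained candidate.
    """
    parents = [str(p) for p in parents]
    if restarts < 1:
        raise ValueError("restarts must be >= 1")
    n = len(parents)
    if n < 2:
        raise FeasibilityError("need at least 2 parents (no self-crosses)")
    if k > n - 1:
        raise FeasibilityError(
            f"k={k} infeasible with {n} parents; maximum k is {n - 1}"
        )
    sub = A.submatrix(parents)
    Avals = sub.values
    rng = np.random.default_rng(rng_seed)
    best_edges: list[tuple[int, int]] | None = None
    best_obj = np.inf
    trail = []
    for _ in range(restarts):
        edges = _random_regular_edges(n, k, rng)
        if swaps > 0:
            edges = _local_search(edges, Avals, swaps, rng)
        vals = np.array([Avals[a, b] for a, b in edges])
        obj = {"mean": vals.mean(), "sum": vals.sum(), "max": vals.max()}[objective]
        trail.append(float(obj))
        if obj < best_obj:
            best_obj = float(obj)
            best_edges = edges
    assert best_edges is not None
    crosses = tuple(
        (parents[a], parents[b]) if parents[a] <= parents[b] else (parents[b], parents[a])
        for a, b in best_edges
    )
    deg = _edge_set_stats(best_edges, n)
    return CrossPlan(
        crosses=crosses,
        per_parent_count={parents[i]: int(deg[i]) for i in range(n)},
        objective=best_obj,
        seed=int(rng_seed),
        restarts_used=restarts,
        shortfall={parents[i]: k - int(deg[i]) for i in range(n) if deg[i] < k},
        candidate_objectives=tuple(trail),
    )
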