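"""Exhaustive enumeration of generic response graphs up to isomorphism.

A generic ``n x m`` response graph is exactly a choice of a strict
best-to-worst order over rows for each column (player 1) and over columns
for each row (player 2) — ``(n!)^m * (m!)^n`` labeled graphs in total
(16 at 2x2, 288 at 2x3, 9,216 at 2x4, 46,656 at 3x3).  Graphs are identified
up to row permutations, column permutations and — when the grid is square or
when comparing ``n x m`` with ``m x n`` — a swap of the two players, which
is exactly isomorphism of the unlabeled response graphs.

Canonicalization minimizes a fixed serialization of the arc signs over the
full symmetry group (at most ``n! * m! * 2`` elements; 72 at 3x3), applied
to all graphs at once with precomputed index/flip tables, so the complete
3x3 census runs in seconds.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Callable, Iterable, Iterator, Sequence, Union

import networkx as nx
import numpy as np

from .games_core import Profile
from .response_graph import ResponseGraph, comparable_pairs
from . import classification, structure

DEFAULT_BUDGET = 10 ** 6


@dataclass(frozen=True)
class CanonicalCode:
    """Isomorphism-class fingerprint of a response graph.

    ``dims`` is normalized to ``n_rows <= n_cols``; ``code`` is the
    lexicographically minimal sign serialization over the symmetry group.
    Two graphs get equal codes iff they are related by strategy relabeling
    and possibly a player swap.
    """

    code: bytes
    dims: tuple


@dataclass(frozen=True)
class PreferenceProfile:
    """Strict preference orders: one row order per column, one column order
    per row; in bijection with generic response graphs of the given shape."""

    col_orders: tuple   # m tuples, each a permutation of range(n), best first
    row_orders: tuple   # n tuples, each a permutation of range(m), best first


# ---------------------------------------------------------------------------
# symmetry-group tables
# ---------------------------------------------------------------------------

def _pair_index(n: int, m: int) -> dict:
    return {k: i for i, k in enumerate(comparable_pairs(n, m))}


@lru_cache(maxsize=None)
def _group_tables(n: int, m: int):
    """Index permutation P and flip mask F for every symmetry of the grid.

    For group element g, the transformed sign vector is
    ``where(F, -v[P], v[P])`` in the pair order of the *target* shape
    (``(m, n)`` swapped elements land back on ``(n, m)`` only when n == m,
    so swaps are only generated for square grids).
    """
    src_pairs = list(comparable_pairs(n, m))
    src_index = {k: i for i, k in enumerate(src_pairs)}
    tgt_pairs = src_pairs
    P, F = [], []
    swaps = (False, True) if n == m else (False,)
    for swap in swaps:
        for sigma in itertools.permutations(range(n)):
            for tau in itertools.permutations(range(m)):
                fwd = {}
                for r in range(n):
                    for c in range(m):
                        p = Profile(r, c)
                        q = (Profile(sigma[c], tau[r]) if swap
                             else Profile(sigma[r], tau[c]))
                        fwd[p] = q
                inv = {q: p for p, q in fwd.items()}
                perm = np.empty(len(tgt_pairs), dtype=np.int64)
                flip = np.zeros(len(tgt_pairs), dtype=bool)
                for k, (a, b) in enumerate(tgt_pairs):
                    pa, pb = inv[a], inv[b]
                    if pa <= pb:
                        perm[k] = src_index[(pa, pb)]
                    else:
                        perm[k] = src_index[(pb, pa)]
                        flip[k] = True
                P.append(perm)
                F.append(flip)
    return np.array(P), np.array(F)


def _canonical_vectors(vecs: np.ndarray, n: int, m: int) -> np.ndarray:
    """Row-wise canonical sign vectors under the grid symmetry group.

    ``vecs`` has shape (N, n_pairs) with entries in {-1, 0, 1}.  Rows are
    compared lexicographically after packing each candidate into a single
    integer (3 symbols per position), which keeps the whole minimization in
    numpy.
    """
    if n > m:
        raise ValueError("normalize to n <= m before canonicalizing")
    P, F = _group_tables(n, m)
    npairs = vecs.shape[1]
    # pack trits into int64 chunks (<= 39 trits per chunk keeps values exact)
    chunk = 39
    bounds = list(range(0, npairs, chunk)) + [npairs]

    def pack(cand):
        cols = []
        for lo, hi in zip(bounds, bounds[1:]):
            powers = 3 ** np.arange(hi - lo - 1, -1, -1, dtype=np.int64)
            cols.append((cand[:, lo:hi] + 1).astype(np.int64) @ powers)
        return np.stack(cols, axis=1)

    best_key = None
    best_vec = None
    for Pg, Fg in zip(P, F):
        cand = vecs[:, Pg] * np.where(Fg, -1, 1)
        key = pack(cand)
        if best_key is None:
            best_key, best_vec = key, cand
            continue
        decided = np.zeros(key.shape[0], dtype=bool)
        better = np.zeros(key.shape[0], dtype=bool)
        for j in range(key.shape[1]):
            lt = key[:, j] < best_key[:, j]
            gt = key[:, j] > best_key[:, j]
            better |= lt & ~decided
            decided |= lt | gt
        if better.any():
            best_key[better] = key[better]
            best_vec[better] = cand[better]
    return best_vec


def canonical_code(rg: ResponseGraph) -> CanonicalCode:
    """Canonical fingerprint of a response graph up to preference equivalence."""
    if rg.n_rows > rg.n_cols:
        rg = rg.transpose()
    vec = rg.sign_vector().astype(np.int8)[None, :]
    best = _canonical_vectors(vec, rg.n_rows, rg.n_cols)[0]
    return CanonicalCode(bytes((best + 1).astype(np.uint8)),
                         (rg.n_rows, rg.n_cols))


# ---------------------------------------------------------------------------
# enumeration of generic graphs
# ---------------------------------------------------------------------------

def n_generic_graphs(n: int, m: int) -> int:
    """Number of labeled generic graphs: (n!)^m * (m!)^n."""
    return math.factorial(n) ** m * math.factorial(m) ** n


def _check_budget(n: int, m: int, budget: int):
    total = n_generic_graphs(n, m)
    if total > budget:
        raise ValueError(
            f"enumeration of {n}x{m} needs {total} graphs, over the "
            f"budget of {budget}")
    return total


def _sign_matrix(n: int, m: int) -> np.ndarray:
    """All labeled generic sign vectors, shape ((n!)^m (m!)^n, n_pairs).

    Pair order follows :func:`comparable_pairs`: player-1 pairs by column,
    then player-2 pairs by row.  Built from per-line rank tables: the sign of
    pair ((r1,c),(r2,c)) is +1 iff the column order ranks r2 above r1.
    """
    perms_n = list(itertools.permutations(range(n)))
    perms_m = list(itertools.permutations(range(m)))
    row_pairs = list(itertools.combinations(range(n), 2))
    col_pairs = list(itertools.combinations(range(m), 2))

    def line_signs(perms, pairs):
        out = np.empty((len(perms), len(pairs)), dtype=np.int8)
        for i, perm in enumerate(perms):
            rank = {s: k for k, s in enumerate(perm)}   # 0 = best
            for j, (a, b) in enumerate(pairs):
                out[i, j] = 1 if rank[b] < rank[a] else -1
        return out

    s1 = line_signs(perms_n, row_pairs)     # per column choice
    s2 = line_signs(perms_m, col_pairs)     # per row choice
    # every combination of m column-orders: block of player-1 signs
    combos1 = np.stack([np.concatenate([s1[i] for i in idx])
                        for idx in itertools.product(range(len(perms_n)),
                                                     repeat=m)])
    combos2 = np.stack([np.concatenate([s2[i] for i in idx])
                        for idx in itertools.product(range(len(perms_m)),
                                                     repeat=n)])
    n1, n2 = combos1.shape[0], combos2.shape[0]
    left = np.repeat(combos1, n2, axis=0)
    right = np.tile(combos2, (n1, 1))
    return np.concatenate([left, right], axis=1)


def enumerate_generic_graphs(n: int, m: int,
                             budget: int = DEFAULT_BUDGET) -> Iterator[ResponseGraph]:
    """Yield every labeled generic ``n x m`` response graph exactly once."""
    if n < 1 or m < 1:
        raise ValueError("dimensions must be positive")
    _check_budget(n, m, budget)
    for vec in _sign_matrix(n, m):
        yield ResponseGraph.from_sign_vector(n, m, vec)


def _no_dominated_mask(vecs: np.ndarray, n: int, m: int) -> np.ndarray:
    """Boolean mask of graphs in which no strategy is strictly dominated."""
    row_pairs = list(itertools.combinations(range(n), 2))
    col_pairs = list(itertools.combinations(range(m), 2))
    np1 = len(row_pairs)
    # player-1 signs per (column, row-pair); +1 means the higher row wins
    p1 = vecs[:, :m * np1].reshape(-1, m, np1)
    p2 = vecs[:, m * np1:].reshape(-1, n, len(col_pairs))
    ok = np.ones(vecs.shape[0], dtype=bool)
    for j in range(np1):
        s = p1[:, :, j]
        ok &= ~np.all(s == 1, axis=1) & ~np.all(s == -1, axis=1)
    for j in range(len(col_pairs)):
        s = p2[:, :, j]
        ok &= ~np.all(s == 1, axis=1) & ~np.all(s == -1, axis=1)
    return ok


# ---------------------------------------------------------------------------
# classes and predicates
# ---------------------------------------------------------------------------

@lru_cache(maxsize=None)
def generic_classes(n: int, m: int, budget: int = DEFAULT_BUDGET) -> tuple:
    """One canonical representative per isomorphism class of generic graphs.

    Returns a tuple of :class:`ResponseGraph`, ordered by canonical code.
    """
    if n > m:
        n, m = m, n
    _check_budget(n, m, budget)
    vecs = _sign_matrix(n, m)
    canon = _canonical_vectors(vecs, n, m)
    uniq = np.unique(canon, axis=0)
    return tuple(ResponseGraph.from_sign_vector(n, m, v) for v in uniq)


def _predicate(name_or_fn) -> Callable[[ResponseGraph], bool]:
    if callable(name_or_fn):
        return name_or_fn
    name = str(name_or_fn)
    if name.startswith("directed_") and name.endswith("_cycle"):
        k = int(name.split("_")[1])
        return lambda rg: structure.has_directed_cycle_of_length(rg, k)
    try:
        return _PREDICATES[name]
    except KeyError:
        raise ValueError(f"unknown predicate {name!r}; known: "
                         f"{sorted(_PREDICATES)} or directed_<k>_cycle") from None


_PREDICATES: dict = {
    "no_dominated_strategy": lambda rg: not structure.dominated_strategies(rg),
    "preference_potential": classification.is_preference_potential,
    "preference_zero_sum": classification.is_preference_zero_sum,
    "neither": lambda rg: (not classification.is_preference_potential(rg)
                           and not classification.is_preference_zero_sum(rg)),
    "contains_MP": lambda rg: bool(structure.find_pattern_subgames(rg, "MP")),
    "contains_CO": lambda rg: bool(structure.find_pattern_subgames(rg, "CO")),
    "has_pure_nash": lambda rg: bool(structure.pure_nash(rg)),
    "strongly_connected": lambda rg: nx.is_strongly_connected(rg.to_networkx()),
    "dominance_solvable": structure.is_dominance_solvable,
}


def directed_k_cycle(k: int) -> Callable[[ResponseGraph], bool]:
    """Predicate factory: graph has a simple directed cycle of length k."""
    return lambda rg: structure.has_directed_cycle_of_length(rg, k)


def find_classes(n: int, m: int,
                 predicates: Sequence = (),
                 budget: int = DEFAULT_BUDGET) -> list:
    """Canonical representatives of the classes satisfying every predicate."""
    preds = [_predicate(p) for p in predicates]
    return [rg for rg in generic_classes(n, m, budget)
            if all(p(rg) for p in preds)]


def count_classes(n: int, m: int,
                  predicates: Sequence = (),
                  budget: int = DEFAULT_BUDGET) -> int:
    """Number of isomorphism classes satisfying the predicate conjunction."""
    return len(find_classes(n, m, predicates, budget))


def census(n: int, m: int, budget: int = DEFAULT_BUDGET) -> dict:
    """The class census of generic non-dominated ``n x m`` graphs.

    Splits the non-dominated classes into preference-zero-sum,
    preference-potential and neither (the three are disjoint on non-dominated
    graphs: a graph in both classes is dominance-solvable, hence dominated).
    """
    reps = find_classes(n, m, ["no_dominated_strategy"], budget)
    zs = pot = neither = 0
    for rg in reps:
        z = classification.is_preference_zero_sum(rg)
        p = classification.is_preference_potential(rg)
        if z and p:
            raise AssertionError(
                "non-dominated class in both preference classes")
        zs += z
        pot += p
        neither += (not z) and (not p)
    return {"dims": (min(n, m), max(n, m)),
            "total_classes": count_classes(n, m, (), budget),
            "non_dominated": len(reps),
            "preference_zero_sum": zs,
            "preference_potential": pot,
            "neither": neither}


def preference_profile(rg: ResponseGraph) -> PreferenceProfile:
    """The strict preference orders encoded by a generic response graph."""
    if not rg.is_generic:
        raise ValueError("preference orders require a generic graph")
    col_orders = []
    for c in range(rg.n_cols):
        # best first: a row beaten by nobody in this column sorts first
        rows = sorted(range(rg.n_rows),
                      key=lambda r: -sum(rg.sign(Profile(r2, c), Profile(r, c)) > 0
                                         for r2 in range(rg.n_rows) if r2 != r))
        col_orders.append(tuple(rows))
    row_orders = []
    for r in range(rg.n_rows):
        cols = sorted(range(rg.n_cols),
                      key=lambda c: -sum(rg.sign(Profile(r, c2), Profile(r, c)) > 0
                                         for c2 in range(rg.n_cols) if c2 != c))
        row_orders.append(tuple(cols))
    return PreferenceProfile(tuple(col_orders), tuple(row_orders))
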