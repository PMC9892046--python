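"""Potential / zero-sum classification of games and response graphs.

Two levels of classification are provided.

*Preference level* (graph only): a game is preference-potential iff no cycle
of its response graph contains a strict arc — for generic graphs, iff the
graph is acyclic.  It is preference-zero-sum iff its reflection (reverse all
player-2 arcs) is preference-potential.  This duality is the heart of the
module: acyclicity is the graph property underlying both classes.

*Strategic level* (payoffs matter): a game is strategically-potential iff its
payoff differences are the differences of a single potential function phi,
which holds iff every 2x2 plaquette of payoff differences closes up to zero.
Strategically-zero-sum is the reflected condition.

Constructive witnesses are produced in both directions, and a linear-
feasibility oracle (solving the strict-inequality system with unit margins)
provides an independent route to the preference-level verdicts.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Optional, Union

import networkx as nx
import numpy as np

from .games_core import Game, Profile, is_generic, reflect_game
from .response_graph import (ResponseGraph, build_response_graph,
                             comparable_pairs)
from . import structure


@dataclass(frozen=True)
class PotentialFunction:
    """A potential witness: phi on the profile grid.

    For a strategic witness, ``phi(p) - phi(q) = u_i(p) - u_i(q)`` on every
    i-comparable pair; for a preference witness only the sign pattern (and
    ties) must agree with the arcs.
    """

    values: np.ndarray

    def __call__(self, p) -> float:
        p = Profile(*p)
        return float(self.values[p.row, p.col])

    def as_dict(self) -> dict:
        return {Profile(r, c): float(self.values[r, c])
                for r in range(self.values.shape[0])
                for c in range(self.values.shape[1])}


# ---------------------------------------------------------------------------
# preference level
# ---------------------------------------------------------------------------

def is_preference_potential(rg: ResponseGraph) -> bool:
    """True iff no cycle of the response graph contains a strict arc.

    A strict arc lies on a cycle iff its endpoints share a strongly connected
    component (ties give two-way connectivity), so it suffices to check that
    every SCC is internally tie-only.  For generic graphs this reduces to
    acyclicity.
    """
    g = rg.to_networkx()
    comp_of = {}
    for i, comp in enumerate(nx.strongly_connected_components(g)):
        for v in comp:
            comp_of[v] = i
    return all(comp_of[src] != comp_of[dst] for src, dst in rg.strict_arcs())


def is_preference_zero_sum(rg: ResponseGraph) -> bool:
    """True iff the reflection in player 2 is preference-potential."""
    return is_preference_potential(rg.reflect(2))


# ---------------------------------------------------------------------------
# strategic level
# ---------------------------------------------------------------------------

def _tolerance(game: Game) -> float:
    scale = max(1.0, float(np.abs(game.u1).max()), float(np.abs(game.u2).max()))
    return 1e-9 * scale


def is_strategically_potential(game: Game):
    """Exact-potential test; returns ``(verdict, PotentialFunction | None)``.

    phi is accumulated from profile (0, 0): down column 0 via player 1's
    differences, then along each row via player 2's.  The candidate is then
    verified against every comparable pair, which is equivalent to the
    rectangle (plaquette) condition since row/column cycles telescope.
    Exact for integer payoffs; floats use a relative 1e-9 tolerance.
    """
    n, m = game.shape
    phi = np.zeros((n, m))
    for r in range(1, n):
        phi[r, 0] = phi[r - 1, 0] + game.u1[r, 0] - game.u1[r - 1, 0]
    for r in range(n):
        for c in range(1, m):
            phi[r, c] = phi[r, c - 1] + game.u2[r, c] - game.u2[r, c - 1]
    tol = _tolerance(game)
    for p, q in comparable_pairs(n, m):
        mover = 1 if p.col == q.col else 2
        u = game.u1 if mover == 1 else game.u2
        diff = (phi[q.row, q.col] - phi[p.row, p.col]) - (u[q.row, q.col] - u[p.row, p.col])
        if abs(diff) > tol:
            return False, None
    return True, PotentialFunction(phi)


def is_strategically_zero_sum(game: Game) -> bool:
    """True iff the reflected game (u1, -u2) is strategically-potential."""
    ok, _ = is_strategically_potential(reflect_game(game, 2))
    return ok


# ---------------------------------------------------------------------------
# constructive preference witnesses
# ---------------------------------------------------------------------------

def _layer_potential(rg: ResponseGraph) -> np.ndarray:
    """Integer phi: longest-path layer of each tie-condensed component.

    Valid only when the graph is preference-potential; then every strict arc
    crosses components and gains at least one layer, while tied profiles
    share a component and a layer.
    """
    g = rg.to_networkx()
    cond = nx.condensation(g)
    layer = {n: 0 for n in nx.topological_sort(cond)}
    for n in nx.topological_sort(cond):
        for succ in cond.successors(n):
            layer[succ] = max(layer[succ], layer[n] + 1)
    phi = np.zeros(rg.shape)
    for n in cond.nodes:
        for p in cond.nodes[n]["members"]:
            phi[p.row, p.col] = layer[n]
    return phi


def realize_preference_witness(rg: ResponseGraph,
                               target: str) -> Optional[Game]:
    """A concrete potential (u1 = u2 = phi) or zero-sum (u2 = -u1) game
    whose response graph equals ``rg``, or None when no such game exists.

    Witness payoffs are small integers (topological layer indices), so the
    output is exact and human-readable.  Witness existence coincides with the
    preference-level verdict, which makes this the constructive oracle for
    :func:`is_preference_potential` / :func:`is_preference_zero_sum`.
    """
    if target == "potential":
        if not is_preference_potential(rg):
            return None
        phi = _layer_potential(rg)
        game = Game(phi, phi)
    elif target == "zero_sum":
        refl = rg.reflect(2)
        if not is_preference_potential(refl):
            return None
        phi = _layer_potential(refl)
        game = Game(phi, -phi)
    else:
        raise ValueError(f"target must be 'potential' or 'zero_sum', got {target!r}")
    assert build_response_graph(game) == ResponseGraph(
        rg.n_rows, rg.n_cols, {k: rg.sign(*k) for k in rg.pairs()})
    return game


# ---------------------------------------------------------------------------
# linear-feasibility oracle
# ---------------------------------------------------------------------------

def feasible_preference_class(rg: ResponseGraph, target: str) -> bool:
    """Independent LP oracle for the preference-level classes.

    Searches for a potential phi (or a zero-sum u1) realizing every strict
    arc with margin >= 1 and every tie as an exact equality, via
    ``scipy.optimize.linprog``.  Feasibility of this system is equivalent to
    the corresponding preference-class membership.
    """
    from scipy.optimize import linprog

    if target == "zero_sum":
        rg = rg.reflect(2)
    elif target != "potential":
        raise ValueError(f"unknown target {target!r}")
    n, m = rg.shape
    nv = n * m

    def vid(p):
        return p.row * m + p.col

    A_ub, b_ub, A_eq, b_eq = [], [], [], []
    for p, q in rg.pairs():
        s = rg.sign(p, q)
        row = np.zeros(nv)
        if s == 0:
            row[vid(p)], row[vid(q)] = 1.0, -1.0
            A_eq.append(row)
            b_eq.append(0.0)
        else:
            lo, hi = (p, q) if s > 0 else (q, p)   # strict arc lo -> hi
            row[vid(lo)], row[vid(hi)] = 1.0, -1.0  # phi(lo) - phi(hi) <= -1
            A_ub.append(row)
            b_ub.append(-1.0)
    res = linprog(c=np.zeros(nv),
                  A_ub=np.array(A_ub) if A_ub else None,
                  b_ub=np.array(b_ub) if b_ub else None,
                  A_eq=np.array(A_eq) if A_eq else None,
                  b_eq=np.array(b_eq) if b_eq else None,
                  bounds=[(None, None)] * nv, method="highs")
    return res.status == 0


# ---------------------------------------------------------------------------
# aggregate report
# ---------------------------------------------------------------------------

@dataclass
class ClassificationReport:
    """Bundle of classification verdicts for a game or response graph.

    Strategic flags are None when only a graph was supplied (they depend on
    cardinal payoffs).  Invariants: each strategic flag implies the
    corresponding preference flag; a generic graph in both preference
    classes is dominance-solvable.
    """

    generic: bool
    preference_potential: bool
    preference_zero_sum: bool
    dominance_solvable: bool
    strategically_potential: Optional[bool] = None
    strategically_zero_sum: Optional[bool] = None
    potential_witness: Optional[Game] = None
    zero_sum_witness: Optional[Game] = None

    def to_dict(self) -> dict:
        from .games_core import game_to_dict

        d = {"generic": self.generic,
             "preference_potential": self.preference_potential,
             "preference_zero_sum": self.preference_zero_sum,
             "dominance_solvable": self.dominance_solvable,
             "strategically_potential": self.strategically_potential,
             "strategically_zero_sum": self.strategically_zero_sum}
        if self.potential_witness is not None:
            d["potential_witness"] = game_to_dict(self.potential_witness)
        if self.zero_sum_witness is not None:
            d["zero_sum_witness"] = game_to_dict(self.zero_sum_witness)
        return d


def classification_report(obj: Union[Game, ResponseGraph],
                          witnesses: bool = False) -> ClassificationReport:
    """Run the full preference (and, for a Game, strategic) classification."""
    if isinstance(obj, Game):
        rg = build_response_graph(obj)
        strat_pot, _ = is_strategically_potential(obj)
        strat_zs = is_strategically_zero_sum(obj)
        generic = is_generic(obj)
    else:
        rg = obj
        strat_pot = strat_zs = None
        generic = rg.is_generic
    rep = ClassificationReport(
        generic=generic,
        preference_potential=is_preference_potential(rg),
        preference_zero_sum=is_preference_zero_sum(rg),
        dominance_solvable=structure.is_dominance_solvable(rg),
        strategically_potential=strat_pot,
        strategically_zero_sum=strat_zs)
    if witnesses:
        rep.potential_witness = realize_preference_witness(rg, "potential")
        rep.zero_sum_witness = realize_preference_witness(rg, "zero_sum")
    return rep
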