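"""Structural analysis of response graphs.

Sink strongly connected components, pure Nash profiles, strict and iterated
dominance, near-subgames, the four-pattern taxonomy of 2x2 graphs
(MP / CO / SD / DD and their weak forms), and executable checkers for the
sink-uniqueness and survivor-coverage theorems.

All dominance here is strict, pure-strategy dominance: a tie against any
opposing strategy blocks domination.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional

import networkx as nx

from .games_core import Profile
from .response_graph import ResponseGraph, comparable_pairs, induced_2x2

PATTERN_LABELS = ("MP", "CO", "SD", "DD")


@dataclass(frozen=True)
class Pattern:
    """A 2x2 response-graph class, possibly matched only as a weak form.

    ``label`` is one of MP (directed 4-cycle), CO (two sinks / two sources),
    SD (one dominated strategy) or DD (two dominated strategies).  ``weak``
    marks a match obtained by orienting undirected edges.
    """

    label: str
    weak: bool = False


@dataclass(frozen=True)
class EliminationTrace:
    """Record of one run of iterated elimination of dominated strategies."""

    steps: tuple            # of (player, eliminated index, dominator index)
    surviving_rows: frozenset
    surviving_cols: frozenset

    @property
    def survivors(self):
        return (self.surviving_rows, self.surviving_cols)


# ---------------------------------------------------------------------------
# sink components and pure Nash
# ---------------------------------------------------------------------------

def sink_components(rg: ResponseGraph) -> list:
    """Strongly connected components with no outgoing arcs, as profile sets.

    Ties count as two-way connectivity.  Sorted by smallest member for
    deterministic output.
    """
    g = rg.to_networkx()
    cond = nx.condensation(g)
    sinks = [frozenset(cond.nodes[n]["members"])
             for n in cond.nodes if cond.out_degree(n) == 0]
    return sorted(sinks, key=lambda s: sorted(s))


def pure_nash(rg: ResponseGraph) -> set:
    """Profiles receiving an arc from every comparable profile (ties qualify)."""
    out = set()
    for p in rg.profiles():
        if all(rg.has_arc(q, p) for q in _comparable_to(rg, p)):
            out.add(p)
    return out


def _comparable_to(rg: ResponseGraph, p: Profile):
    for r in range(rg.n_rows):
        if r != p.row:
            yield Profile(r, p.col)
    for c in range(rg.n_cols):
        if c != p.col:
            yield Profile(p.row, c)


# ---------------------------------------------------------------------------
# dominance
# ---------------------------------------------------------------------------

def dominated_strategies(rg: ResponseGraph, rows=None, cols=None) -> list:
    """All (player, dominated strategy, dominator) triples.

    ``rows`` / ``cols`` restrict the game to a subgrid (used during iterated
    elimination).  Strategy ``t`` is dominated by ``s`` for player ``i`` iff
    against every opposing strategy the arc between the two i-comparable
    profiles points strictly toward ``s``'s profile.
    """
    rows = sorted(rows) if rows is not None else list(range(rg.n_rows))
    cols = sorted(cols) if cols is not None else list(range(rg.n_cols))
    out = []
    for t, s in itertools.permutations(rows, 2):
        if all(rg.sign(Profile(t, c), Profile(s, c)) > 0 for c in cols):
            out.append((1, t, s))
    for t, s in itertools.permutations(cols, 2):
        if all(rg.sign(Profile(r, t), Profile(r, s)) > 0 for r in rows):
            out.append((2, t, s))
    return out


def iterated_elimination(rg: ResponseGraph,
                         choose: Optional[Callable] = None) -> EliminationTrace:
    """Repeatedly delete a strictly dominated strategy until none remains.

    ``choose`` picks one candidate from the current ``dominated_strategies``
    list (default: lowest player, then lowest strategy index).  The surviving
    sets do not depend on the deletion order; that invariance is exercised by
    the test suite rather than assumed.
    """
    rows = set(range(rg.n_rows))
    cols = set(range(rg.n_cols))
    steps = []
    while True:
        cands = dominated_strategies(rg, rows, cols)
        if not cands:
            break
        step = choose(cands) if choose is not None else min(cands)
        player, t, _s = step
        (rows if player == 1 else cols).discard(t)
        steps.append(tuple(step))
    return EliminationTrace(tuple(steps), frozenset(rows), frozenset(cols))


def is_dominance_solvable(rg: ResponseGraph) -> bool:
    """True iff iterated elimination leaves a single profile."""
    tr = iterated_elimination(rg)
    return len(tr.surviving_rows) == 1 and len(tr.surviving_cols) == 1


# ---------------------------------------------------------------------------
# near-subgames
# ---------------------------------------------------------------------------

def is_near_subgame(rg: ResponseGraph, X: Iterable) -> bool:
    """Closure test: for every two members, at least one cross profile is in X.

    A full rectangle (subgame) contains both cross profiles, so every subgame
    is a near-subgame; the converse fails.
    """
    X = {Profile(*x) for x in X}
    if not X:
        raise ValueError("X must be nonempty")
    for (s1, s2), (t1, t2) in itertools.combinations(X, 2):
        if Profile(s1, t2) not in X and Profile(t1, s2) not in X:
            return False
    return True


# ---------------------------------------------------------------------------
# 2x2 taxonomy
# ---------------------------------------------------------------------------

def _classify_generic_2x2(rg: ResponseGraph) -> str:
    # A generic 2x2 graph is MP iff its four strict arcs form a cycle;
    # otherwise the number of dominated strategies separates CO / SD / DD.
    if not nx.is_directed_acyclic_graph(rg.strict_digraph()):
        return "MP"
    return {0: "CO", 1: "SD", 2: "DD"}[len(dominated_strategies(rg))]


def classify_2x2(rg: ResponseGraph) -> set:
    """Classify a 2x2 response graph into the MP/CO/SD/DD taxonomy.

    Generic input yields a single strict :class:`Pattern`.  Input with ties
    yields every label achievable by orienting its undirected edges, each
    marked ``weak`` (a weak form in the orientation sense).
    """
    if rg.shape != (2, 2):
        raise ValueError(f"classify_2x2 needs a 2x2 graph, got {rg.shape}")
    if rg.is_generic:
        return {Pattern(_classify_generic_2x2(rg), weak=False)}
    ties = list(rg.ties())
    vec = rg.sign_vector()
    pairs = list(rg.pairs())
    idx = [pairs.index(t) for t in ties]
    out = set()
    for orient in itertools.product((-1, 1), repeat=len(idx)):
        v = vec.copy()
        for i, s in zip(idx, orient):
            v[i] = s
        g = ResponseGraph.from_sign_vector(2, 2, v)
        out.add(Pattern(_classify_generic_2x2(g), weak=True))
    return out


def matches_pattern(rg2x2: ResponseGraph, label: str,
                    allow_weak: bool = False) -> bool:
    """Does a 2x2 graph match the label, strictly or (optionally) weakly?"""
    if label not in PATTERN_LABELS:
        raise ValueError(f"unknown pattern label {label!r}")
    pats = classify_2x2(rg2x2)
    if Pattern(label, weak=False) in pats:
        return True
    return allow_weak and Pattern(label, weak=True) in pats


def find_pattern_subgames(rg: ResponseGraph, label: str,
                          allow_weak: bool = False) -> list:
    """All 2x2 rectangles whose induced graph matches the label.

    Any occurrence of a 2x2 response graph inside a larger one sits on a full
    rectangle of the grid, so scanning rectangles is a complete search.
    Returns ``[(row_pair, col_pair), ...]``.
    """
    out = []
    for rows in itertools.combinations(range(rg.n_rows), 2):
        for cols in itertools.combinations(range(rg.n_cols), 2):
            if matches_pattern(induced_2x2(rg, rows, cols), label, allow_weak):
                out.append((rows, cols))
    return out


def pattern_census(rg: ResponseGraph, allow_weak: bool = False) -> dict:
    """Count matching rectangles for each of the four 2x2 patterns."""
    return {lab: len(find_pattern_subgames(rg, lab, allow_weak))
            for lab in PATTERN_LABELS}


# ---------------------------------------------------------------------------
# theorem checkers
# ---------------------------------------------------------------------------

def check_survivors_in_mp_or_co(rg: ResponseGraph) -> dict:
    """Survivor-coverage check: in a non-dominance-solvable game, every
    strategy surviving iterated dominance sits in some 2x2 rectangle that is
    a weak form of Matching Pennies or Coordination.

    Returns an evidence report; ``ok`` holds on every response graph (it is a
    theorem), so the checker doubles as a property test.
    """
    tr = iterated_elimination(rg)
    solvable = len(tr.surviving_rows) == 1 and len(tr.surviving_cols) == 1
    report = {"dominance_solvable": solvable,
              "survivors": (sorted(tr.surviving_rows), sorted(tr.surviving_cols)),
              "uncovered": []}
    if solvable:
        report["ok"] = True
        return report
    rects = (find_pattern_subgames(rg, "MP", allow_weak=True)
             + find_pattern_subgames(rg, "CO", allow_weak=True))
    covered_rows = {r for rows, _ in rects for r in rows}
    covered_cols = {c for _, cols in rects for c in cols}
    for r in sorted(tr.surviving_rows):
        if r not in covered_rows:
            report["uncovered"].append((1, r))
    for c in sorted(tr.surviving_cols):
        if c not in covered_cols:
            report["uncovered"].append((2, c))
    report["ok"] = not report["uncovered"]
    return report


def check_sink_uniqueness_without_co(rg: ResponseGraph) -> dict:
    """Sink-uniqueness check: a generic graph containing no strict CO
    rectangle has exactly one sink component, whose profile set is a
    near-subgame.

    The precondition (genericity, absence of strict CO) is reported rather
    than raised; ``ok`` asserts the conclusion whenever it applies.
    """
    generic = rg.is_generic
    has_co = bool(find_pattern_subgames(rg, "CO", allow_weak=False))
    report = {"generic": generic, "contains_co": has_co,
              "applicable": generic and not has_co}
    sinks = sink_components(rg)
    report["n_sink_components"] = len(sinks)
    union = frozenset().union(*sinks)
    report["sink_profiles"] = sorted(union)
    report["near_subgame"] = is_near_subgame(rg, union)
    if report["applicable"]:
        report["ok"] = len(sinks) == 1 and report["near_subgame"]
    else:
        report["ok"] = None
    return report


# ---------------------------------------------------------------------------
# directed cycle lengths (used by the enumeration predicates)
# ---------------------------------------------------------------------------

def has_directed_cycle_of_length(rg: ResponseGraph, k: int) -> bool:
    """Is there a simple directed cycle of exactly ``k`` strict arcs?"""
    for cyc in nx.simple_cycles(rg.strict_digraph(), length_bound=k):
        if len(cyc) == k:
            return True
    return False
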