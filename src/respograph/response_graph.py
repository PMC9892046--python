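"""Response graphs of two-player games.

The response graph has one node per strategy profile and an arc between each
pair of *comparable* profiles (profiles differing in exactly one player's
strategy), directed toward the profile the moving player weakly prefers.  A
payoff tie produces arcs both ways — an undirected edge.  The weighted
variant labels each arc with the mover's (non-negative) payoff gain.

Internally a graph stores one *sign* per comparable pair ``(p, q)`` with
``p < q`` in lexicographic order:

* ``+1`` — strict arc ``p -> q``
* ``-1`` — strict arc ``q -> p``
* ``0``  — tie (undirected edge)

Weighted graphs additionally store the absolute payoff difference per pair.
Graph equality is labelled-node equality; isomorphism lives in
:mod:`respograph.enumeration`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import networkx as nx
import numpy as np

from .games_core import Game, Profile


@dataclass(frozen=True)
class Arc:
    src: Profile
    dst: Profile
    mover: int          # 1 if the profiles differ in the row, else 2
    strict: bool
    weight: Optional[float] = None


def comparable_pairs(n_rows: int, n_cols: int):
    """All comparable pairs of an n x m grid, in a fixed canonical order.

    Player-1 pairs (same column, ordered rows) come first, then player-2
    pairs (same row, ordered columns).  Enumeration and canonical codes rely
    on this order.
    """
    for c in range(n_cols):
        for r1 in range(n_rows):
            for r2 in range(r1 + 1, n_rows):
                yield (Profile(r1, c), Profile(r2, c))
    for r in range(n_rows):
        for c1 in range(n_cols):
            for c2 in range(c1 + 1, n_cols):
                yield (Profile(r, c1), Profile(r, c2))


def pair_mover(p: Profile, q: Profile) -> int:
    """Which player moves between two comparable profiles (1 or 2)."""
    if p[1] == q[1] and p[0] != q[0]:
        return 1
    if p[0] == q[0] and p[1] != q[1]:
        return 2
    raise ValueError(f"profiles {p} and {q} are not comparable")


def _key(p: Profile, q: Profile):
    return (p, q) if p <= q else (q, p)


class ResponseGraph:
    """The (optionally weighted) response graph of an ``n x m`` game."""

    def __init__(self, n_rows: int, n_cols: int, signs: dict,
                 weights: Optional[dict] = None):
        self.n_rows = int(n_rows)
        self.n_cols = int(n_cols)
        expected = set(comparable_pairs(self.n_rows, self.n_cols))
        if set(signs) != expected:
            raise ValueError("signs must cover exactly the comparable pairs")
        self._signs = {k: int(v) for k, v in signs.items()}
        if any(v not in (-1, 0, 1) for v in self._signs.values()):
            raise ValueError("signs must be -1, 0 or +1")
        if weights is not None:
            if set(weights) != expected:
                raise ValueError("weights must cover the comparable pairs")
            for k, w in weights.items():
                if w < 0:
                    raise ValueError("arc weights must be non-negative")
                if (w == 0) != (self._signs[k] == 0):
                    raise ValueError("zero weight must coincide with a tie")
            self._weights = {k: float(v) for k, v in weights.items()}
        else:
            self._weights = None

    # -- construction ------------------------------------------------------

    @classmethod
    def from_game(cls, game: Game, weighted: bool = False) -> "ResponseGraph":
        signs, weights = {}, {}
        for p, q in comparable_pairs(game.n_rows, game.n_cols):
            mover = pair_mover(p, q)
            d = game.payoff(mover, q) - game.payoff(mover, p)
            signs[(p, q)] = int(np.sign(d))
            weights[(p, q)] = abs(d)
        return cls(game.n_rows, game.n_cols, signs,
                   weights if weighted else None)

    @classmethod
    def from_sign_vector(cls, n_rows: int, n_cols: int,
                         vec: Sequence[int]) -> "ResponseGraph":
        """Build from a sign sequence in :func:`comparable_pairs` order."""
        pairs = list(comparable_pairs(n_rows, n_cols))
        if len(vec) != len(pairs):
            raise ValueError("sign vector has wrong length")
        return cls(n_rows, n_cols, dict(zip(pairs, (int(v) for v in vec))))

    # -- basic queries -----------------------------------------------------

    @property
    def shape(self):
        return (self.n_rows, self.n_cols)

    @property
    def weighted(self) -> bool:
        return self._weights is not None

    @property
    def is_generic(self) -> bool:
        """No undirected edges: every comparable pair strictly oriented."""
        return all(s != 0 for s in self._signs.values())

    def profiles(self):
        for r in range(self.n_rows):
            for c in range(self.n_cols):
                yield Profile(r, c)

    def pairs(self):
        return comparable_pairs(self.n_rows, self.n_cols)

    def sign(self, p: Profile, q: Profile) -> int:
        """+1 if a strict arc p -> q, -1 if strict q -> p, 0 if tied."""
        p, q = Profile(*p), Profile(*q)
        s = self._signs[_key(p, q)]
        return s if p <= q else -s

    def has_arc(self, src: Profile, dst: Profile) -> bool:
        """True iff the graph has the arc src -> dst (ties count both ways)."""
        return self.sign(src, dst) >= 0

    def weight(self, p: Profile, q: Profile) -> float:
        if not self.weighted:
            raise ValueError("graph is unweighted")
        return self._weights[_key(Profile(*p), Profile(*q))]

    def arcs(self) -> list:
        """All arcs as :class:`Arc` records (a tie yields two opposite arcs)."""
        out = []
        for (p, q), s in self._signs.items():
            mover = pair_mover(p, q)
            w = self._weights[(p, q)] if self.weighted else None
            if s >= 0:
                out.append(Arc(p, q, mover, s > 0, w))
            if s <= 0:
                out.append(Arc(q, p, mover, s < 0, w))
        return out

    def strict_arcs(self):
        """Iterate (src, dst) over strictly oriented arcs only."""
        for (p, q), s in self._signs.items():
            if s > 0:
                yield (p, q)
            elif s < 0:
                yield (q, p)

    def ties(self):
        """Iterate over undirected edges as canonical pairs."""
        for k, s in self._signs.items():
            if s == 0:
                yield k

    def sign_vector(self) -> np.ndarray:
        """Signs in :func:`comparable_pairs` order, as an int8 array."""
        return np.array([self._signs[k] for k in self.pairs()], dtype=np.int8)

    # -- transforms --------------------------------------------------------

    def reflect(self, player: int = 2) -> "ResponseGraph":
        """Reverse all of one player's arcs (graph-level payoff reflection)."""
        if player not in (1, 2):
            raise ValueError(f"player must be 1 or 2, got {player!r}")
        signs = {k: (-s if pair_mover(*k) == player else s)
                 for k, s in self._signs.items()}
        return ResponseGraph(self.n_rows, self.n_cols, signs, self._weights)

    def reverse(self) -> "ResponseGraph":
        """Reverse every arc (graph-level reversal of both payoffs)."""
        return ResponseGraph(self.n_rows, self.n_cols,
                             {k: -s for k, s in self._signs.items()},
                             self._weights)

    def transpose(self) -> "ResponseGraph":
        """Swap the players: the graph of the transposed game."""
        signs = {}
        weights = {} if self.weighted else None
        for (p, q), s in self._signs.items():
            tp, tq = Profile(p[1], p[0]), Profile(q[1], q[0])
            k = _key(tp, tq)
            signs[k] = s if k == (tp, tq) else -s
            if weights is not None:
                weights[k] = self._weights[(p, q)]
        return ResponseGraph(self.n_cols, self.n_rows, signs, weights)

    def subgraph(self, rows: Sequence[int], cols: Sequence[int]) -> "ResponseGraph":
        """Induced response graph on a sub-rectangle, re-indexed compactly."""
        rows, cols = list(rows), list(cols)
        if len(set(rows)) != len(rows) or len(set(cols)) != len(cols):
            raise ValueError("duplicate indices")
        rmap = {r: i for i, r in enumerate(rows)}
        cmap = {c: j for j, c in enumerate(cols)}
        signs = {}
        weights = {} if self.weighted else None
        for (p, q) in comparable_pairs(len(rows), len(cols)):
            op = Profile(rows[p[0]], cols[p[1]])
            oq = Profile(rows[q[0]], cols[q[1]])
            signs[(p, q)] = self.sign(op, oq)
            if weights is not None:
                weights[(p, q)] = self.weight(op, oq)
        del rmap, cmap
        return ResponseGraph(len(rows), len(cols), signs, weights)

    # -- interop -----------------------------------------------------------

    def to_networkx(self) -> nx.DiGraph:
        """Directed graph with ties expanded to arcs both ways."""
        g = nx.DiGraph()
        g.add_nodes_from(self.profiles())
        for a in self.arcs():
            g.add_edge(a.src, a.dst, mover=a.mover, strict=a.strict,
                       **({"weight": a.weight} if a.weight is not None else {}))
        return g

    def strict_digraph(self) -> nx.DiGraph:
        """Directed graph over the strictly oriented arcs only."""
        g = nx.DiGraph()
        g.add_nodes_from(self.profiles())
        g.add_edges_from(self.strict_arcs())
        return g

    def __eq__(self, other):
        if not isinstance(other, ResponseGraph):
            return NotImplemented
        return (self.shape == other.shape and self._signs == other._signs
                and self._weights == other._weights)

    def __hash__(self):
        return hash((self.shape, tuple(sorted(self._signs.items()))))

    def __repr__(self):
        kind = "weighted " if self.weighted else ""
        return (f"<{kind}ResponseGraph {self.n_rows}x{self.n_cols}, "
                f"{sum(1 for _ in self.strict_arcs())} strict arcs, "
                f"{sum(1 for _ in self.ties())} ties>")


# ---------------------------------------------------------------------------
# module-level operations
# ---------------------------------------------------------------------------

def build_response_graph(game: Game, weighted: bool = False) -> ResponseGraph:
    """Construct the (weighted) response graph of a game."""
    return ResponseGraph.from_game(game, weighted=weighted)


def reflect_graph(rg: ResponseGraph, player: int = 2) -> ResponseGraph:
    return rg.reflect(player)


def reverse_graph(rg: ResponseGraph) -> ResponseGraph:
    return rg.reverse()


def induced_2x2(rg: ResponseGraph, rows: Sequence[int],
                cols: Sequence[int]) -> ResponseGraph:
    """The induced subgraph on a 2 x 2 rectangle of profiles."""
    rows, cols = list(rows), list(cols)
    if len(rows) != 2 or len(cols) != 2:
        raise ValueError("need exactly two rows and two columns")
    return rg.subgraph(rows, cols)


def path_weight(rg: ResponseGraph, path: Sequence[Profile]) -> float:
    """Signed sum of payoff steps along a directed path.

    Each step between comparable profiles ``x_i, x_{i+1}`` contributes
    ``u_mover(x_i) - u_mover(x_{i+1})``, which is the *negative* of the arc
    weight when the path follows arc directions (as required here).  The sign
    convention is kept as stated in the defining formula; see
    :func:`accumulated_improvement` for the positive total gain.
    """
    if not rg.weighted:
        raise ValueError("path_weight requires a weighted response graph")
    path = [Profile(*x) for x in path]
    if len(set(path)) != len(path):
        raise ValueError("path nodes must be distinct")
    total = 0.0
    for x, y in zip(path, path[1:]):
        pair_mover(x, y)  # raises if not comparable
        if not rg.has_arc(x, y):
            raise ValueError(f"no arc {x} -> {y} in the response graph")
        total -= rg.weight(x, y)
    return total


def accumulated_improvement(rg: ResponseGraph, path: Sequence[Profile]) -> float:
    """Total (non-negative) payoff improvement accumulated along a path."""
    return -path_weight(rg, path)


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def to_edge_list(rg: ResponseGraph) -> str:
    """Text edge list: header ``dims n m`` then one arc per line."""
    lines = [f"dims {rg.n_rows} {rg.n_cols}"]
    for a in sorted(rg.arcs(), key=lambda a: (a.src, a.dst)):
        line = (f"{a.src.row},{a.src.col} -> {a.dst.row},{a.dst.col} "
                f"mover={a.mover} strict={int(a.strict)}")
        if a.weight is not None:
            line += f" weight={a.weight}"
        lines.append(line)
    return "\n".join(lines) + "\n"


def from_edge_list(text: str) -> ResponseGraph:
    """Parse the edge-list format written by :func:`to_edge_list`."""
    lines = [ln.strip() for ln in text.splitlines() if ln.strip()]
    if not lines or not lines[0].startswith("dims"):
        raise ValueError("edge list must start with a 'dims n m' header")
    _, n, m = lines[0].split()
    n, m = int(n), int(m)
    signs = {k: None for k in comparable_pairs(n, m)}
    weights = {}
    any_weight = False
    for ln in lines[1:]:
        head, _, rest = ln.partition("->")
        src = Profile(*(int(x) for x in head.strip().split(",")))
        fields = rest.split()
        dst = Profile(*(int(x) for x in fields[0].split(",")))
        kv = dict(f.split("=") for f in fields[1:])
        strict = bool(int(kv.get("strict", "1")))
        k = _key(src, dst)
        if "weight" in kv:
            any_weight = True
            weights[k] = float(kv["weight"])
        if not strict:
            signs[k] = 0
        else:
            signs[k] = 1 if (src, dst) == k else -1
    missing = [k for k, v in signs.items() if v is None]
    if missing:
        raise ValueError(f"edge list misses comparable pairs, e.g. {missing[0]}")
    if any_weight:
        for k, s in signs.items():
            weights.setdefault(k, 0.0)
    return ResponseGraph(n, m, signs, weights if any_weight else None)


def to_dot(rg: ResponseGraph, name: str = "response_graph") -> str:
    """GraphViz DOT text; undirected edges are rendered with ``dir=none``."""
    def nid(p):
        return f"p{p.row}_{p.col}"

    lines = [f"digraph {name} {{"]
    for p in rg.profiles():
        lines.append(f'  {nid(p)} [label="({p.row},{p.col})"];')
    for (p, q), s in sorted(rg._signs.items()):
        attrs = []
        if rg.weighted:
            attrs.append(f'label="{rg.weight(p, q)}"')
        if s == 0:
            attrs.append("dir=none")
            lines.append(f"  {nid(p)} -> {nid(q)} [{', '.join(attrs)}];")
        else:
            src, dst = (p, q) if s > 0 else (q, p)
            suffix = f" [{', '.join(attrs)}]" if attrs else ""
            lines.append(f"  {nid(src)} -> {nid(dst)}{suffix};")
    lines.append("}")
    return "\n".join(lines) + "\n"


def to_graphml(rg: ResponseGraph, path) -> None:
    """Write the arc-expanded digraph as GraphML (via networkx)."""
    g = nx.relabel_nodes(rg.to_networkx(), lambda p: f"{p.row},{p.col}")
    nx.write_graphml(g, path)
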