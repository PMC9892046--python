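"""Two-player normal-form games as payoff bimatrices.

A game is a pair of payoff functions ``u1, u2`` on the grid of strategy
profiles ``S1 x S2``.  Player 1 indexes rows, player 2 columns; all indices
are 0-based.  This module holds the :class:`Game` container, the payoff-level
transforms (reflection, reversal, subgames), a set of named fixture games, a
seeded random-game generator and JSON/CSV file I/O.

Genericity is exact: two payoffs are tied iff the stored values are equal.
No epsilon is applied — payoffs read from files are taken at face value.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np


class Profile(NamedTuple):
    """A cell of the strategy grid: (row strategy, column strategy)."""

    row: int
    col: int


@dataclass(frozen=True)
class Game:
    """A finite two-player normal-form game.

    Parameters
    ----------
    u1, u2 : array-like of shape (n_rows, n_cols)
        Payoff tables for player 1 (row chooser) and player 2 (column
        chooser).  All entries must be finite.
    row_names, col_names : sequence of str, optional
        Distinct strategy names; default ``R0..`` / ``C0..``.
    """

    u1: np.ndarray
    u2: np.ndarray
    row_names: tuple = field(default=None)
    col_names: tuple = field(default=None)

    def __post_init__(self):
        u1 = np.asarray(self.u1, dtype=float)
        u2 = np.asarray(self.u2, dtype=float)
        if u1.ndim != 2 or u1.shape != u2.shape:
            raise ValueError("u1 and u2 must be 2-D arrays of equal shape")
        if u1.shape[0] < 1 or u1.shape[1] < 1:
            raise ValueError("strategy sets must be nonempty")
        if not (np.isfinite(u1).all() and np.isfinite(u2).all()):
            raise ValueError("payoffs must be finite")
        u1.setflags(write=False)
        u2.setflags(write=False)
        object.__setattr__(self, "u1", u1)
        object.__setattr__(self, "u2", u2)
        n, m = u1.shape
        rn = tuple(self.row_names) if self.row_names is not None else tuple(
            f"R{i}" for i in range(n))
        cn = tuple(self.col_names) if self.col_names is not None else tuple(
            f"C{j}" for j in range(m))
        if len(rn) != n or len(set(rn)) != n:
            raise ValueError("row_names must be distinct and match n_rows")
        if len(cn) != m or len(set(cn)) != m:
            raise ValueError("col_names must be distinct and match n_cols")
        object.__setattr__(self, "row_names", rn)
        object.__setattr__(self, "col_names", cn)

    # -- basic queries -----------------------------------------------------

    @property
    def n_rows(self) -> int:
        return self.u1.shape[0]

    @property
    def n_cols(self) -> int:
        return self.u1.shape[1]

    @property
    def shape(self) -> tuple:
        return self.u1.shape

    def profiles(self):
        """Iterate over all strategy profiles in row-major order."""
        for r in range(self.n_rows):
            for c in range(self.n_cols):
                yield Profile(r, c)

    def payoff(self, player: int, profile: Profile) -> float:
        u = {1: self.u1, 2: self.u2}[player]
        return float(u[profile[0], profile[1]])

    def row_index(self, name) -> int:
        return self.row_names.index(name) if isinstance(name, str) else int(name)

    def col_index(self, name) -> int:
        return self.col_names.index(name) if isinstance(name, str) else int(name)

    def __eq__(self, other):
        if not isinstance(other, Game):
            return NotImplemented
        return (self.row_names == other.row_names
                and self.col_names == other.col_names
                and np.array_equal(self.u1, other.u1)
                and np.array_equal(self.u2, other.u2))

    def __hash__(self):
        return hash((self.row_names, self.col_names,
                     self.u1.tobytes(), self.u2.tobytes()))


# ---------------------------------------------------------------------------
# transforms
# ---------------------------------------------------------------------------

def is_generic(game: Game) -> bool:
    """True iff no two comparable profiles tie for the moving player.

    Equivalently, every column of ``u1`` and every row of ``u2`` consists of
    distinct values, so the response graph has no undirected edges.
    """
    for c in range(game.n_cols):
        col = game.u1[:, c]
        if len(np.unique(col)) != len(col):
            return False
    for r in range(game.n_rows):
        row = game.u2[r, :]
        if len(np.unique(row)) != len(row):
            return False
    return True


def reflect_game(game: Game, player: int = 2) -> Game:
    """Negate one player's payoffs: (u1, -u2) for player 2, (-u1, u2) for 1.

    Reflection is an involution and exchanges the zero-sum and
    identical-interest (potential) structures.
    """
    if player == 2:
        return Game(game.u1, -game.u2, game.row_names, game.col_names)
    if player == 1:
        return Game(-game.u1, game.u2, game.row_names, game.col_names)
    raise ValueError(f"player must be 1 or 2, got {player!r}")


def reverse_game(game: Game) -> Game:
    """Negate both payoff tables; reverses every arc of the response graph."""
    return Game(-game.u1, -game.u2, game.row_names, game.col_names)


def subgame(game: Game, rows: Sequence, cols: Sequence) -> Game:
    """Restrict the game to subsets of each player's strategies.

    ``rows`` / ``cols`` may be indices or strategy names; order is preserved
    as given.  Payoff values are carried over unchanged.
    """
    ri = [game.row_index(r) for r in rows]
    ci = [game.col_index(c) for c in cols]
    if not ri or not ci:
        raise ValueError("subgame strategy sets must be nonempty")
    if len(set(ri)) != len(ri) or len(set(ci)) != len(ci):
        raise ValueError("duplicate strategies in subgame selection")
    for i in ri:
        if not 0 <= i < game.n_rows:
            raise IndexError(f"row index {i} out of range")
    for j in ci:
        if not 0 <= j < game.n_cols:
            raise IndexError(f"col index {j} out of range")
    return Game(game.u1[np.ix_(ri, ci)], game.u2[np.ix_(ri, ci)],
                tuple(game.row_names[i] for i in ri),
                tuple(game.col_names[j] for j in ci))


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

_RPS_NAMES = ("Rock", "Paper", "Scissors")

# Standard presentation: win 1, loss -1, tie 0; row r beats row r-1's choice.
_RPS_U1 = [[0, -1, 1],
           [1, 0, -1],
           [-1, 1, 0]]


def _fixtures() -> dict:
    rps_u1 = np.array(_RPS_U1, dtype=float)
    fx = {}
    fx["rps"] = Game(rps_u1, -rps_u1, _RPS_NAMES, _RPS_NAMES)
    # Biased variant: Rock's win pays 2, all other wins pay 1, losses -1,
    # ties 0.  Per-column/row orderings are unchanged, so the (unweighted)
    # response graph is identical to plain RPS.
    b1 = rps_u1.copy()
    b2 = -rps_u1.copy()
    b1[0, 2] = 2.0   # Rock beats Scissors, bigger prize for player 1
    b2[2, 0] = 2.0   # and symmetrically for player 2's Rock
    fx["biased_rps"] = Game(b1, b2, _RPS_NAMES, _RPS_NAMES)
    mp1 = np.array([[1, -1], [-1, 1]], dtype=float)
    fx["matching_pennies"] = Game(mp1, -mp1, ("Heads", "Tails"),
                                  ("Heads", "Tails"))
    co = np.array([[1, 0], [0, 1]], dtype=float)
    fx["coordination"] = Game(co, co, ("A", "B"), ("A", "B"))
    # One dominated row strategy, none for the column player.
    fx["single_dominance"] = Game([[1, 1], [0, 0]], [[1, 0], [0, 1]])
    # One dominated strategy per player; all arcs flow to (0, 0).
    fx["double_dominance"] = Game([[1, 1], [0, 0]], [[1, 0], [1, 0]])
    return fx


def named_game(name: str) -> Game:
    """Return a deterministic fixture game by name.

    Known names: ``rps``, ``biased_rps``, ``matching_pennies``,
    ``coordination``, ``single_dominance``, ``double_dominance``.
    """
    fx = _fixtures()
    try:
        return fx[name]
    except KeyError:
        raise KeyError(
            f"unknown game {name!r}; known: {sorted(fx)}") from None


def random_game(n_rows: int, n_cols: int, seed) -> Game:
    """A generic game with i.i.d. uniform(0, 1) payoffs.

    The same seed always yields the same game.  Continuous draws are generic
    with probability 1; on the measure-zero tie event we redraw.
    """
    if n_rows < 1 or n_cols < 1:
        raise ValueError("dimensions must be positive")
    rng = np.random.default_rng(seed)
    while True:
        g = Game(rng.uniform(size=(n_rows, n_cols)),
                 rng.uniform(size=(n_rows, n_cols)))
        if is_generic(g):
            return g


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def game_to_dict(game: Game) -> dict:
    return {"row_names": list(game.row_names),
            "col_names": list(game.col_names),
            "u1": game.u1.tolist(),
            "u2": game.u2.tolist()}


def game_from_dict(d: dict) -> Game:
    return Game(np.array(d["u1"], dtype=float), np.array(d["u2"], dtype=float),
                tuple(d["row_names"]), tuple(d["col_names"]))


def save_game(game: Game, path) -> None:
    """Write a game as a JSON file (the canonical interchange format)."""
    Path(path).write_text(json.dumps(game_to_dict(game), indent=1) + "\n")


def load_game(path) -> Game:
    """Read a game from a JSON file ``{"row_names", "col_names", "u1", "u2"}``."""
    return game_from_dict(json.loads(Path(path).read_text()))


def save_game_csv(game: Game, u1_path, u2_path) -> None:
    """Write the two payoff matrices as a pair of labelled CSV files."""
    import pandas as pd

    for u, path in ((game.u1, u1_path), (game.u2, u2_path)):
        pd.DataFrame(u, index=list(game.row_names),
                     columns=list(game.col_names)).to_csv(path)


def load_game_csv(u1_path, u2_path) -> Game:
    """Read a game from paired CSV matrices (header row and index column)."""
    import pandas as pd

    d1 = pd.read_csv(u1_path, index_col=0)
    d2 = pd.read_csv(u2_path, index_col=0)
    if list(d1.index) != list(d2.index) or list(d1.columns) != list(d2.columns):
        raise ValueError("paired CSV matrices must share row and column names")
    return Game(d1.to_numpy(float), d2.to_numpy(float),
                tuple(str(x) for x in d1.index),
                tuple(str(x) for x in d1.columns))
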