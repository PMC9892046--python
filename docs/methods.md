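# Methods

## The model

A finite two-player normal-form game is a pair of payoff functions
`u1, u2 : S1 × S2 → ℝ` on the grid of strategy profiles; player 1 indexes
rows, player 2 columns, all indices 0-based. Two profiles are *i-comparable*
when they differ only in player *i*'s strategy. The **response graph** places
an arc between every comparable pair, directed toward the profile the mover
weakly prefers; equal payoffs give arcs both ways (an undirected edge). The
**weighted** variant labels arcs with the mover's payoff gain
`u_i(dst) − u_i(src) ≥ 0`.

The graph depends only on each player's per-line preference *orders*, so any
monotone payoff change leaves it fixed (e.g. the `rps` and `biased_rps`
fixtures share one graph). A game is **generic** when no mover is ever
indifferent between comparable profiles — exact equality of stored values,
no epsilon: file payoffs are treated as exact, and the generator draws
continuous uniforms for which ties have probability zero.

Internally a graph stores one sign per comparable pair (`+1`/`−1` for the
strict orientation, `0` for a tie) in a fixed pair order (player-1 pairs by
column, then player-2 pairs by row). This single convention feeds graph
equality, serialization and the canonical codes.

## Transforms and the duality

Reflection negates one player's payoffs (`(u1, −u2)` by default); at the
graph level it reverses that player's arcs. Reversal negates both and
reverses every arc. Both are involutions, and reflecting in player 1 equals
reversal composed with reflection in player 2.

A game is **preference-potential** if it shares a response graph with an
exact potential game, and **preference-zero-sum** if with a zero-sum game.
The implemented characterisation: a graph is preference-potential iff no
cycle contains a strict arc — decided by checking that every strongly
connected component (ties give two-way connectivity) is internally tie-only,
which is exact and near-linear — and preference-zero-sum iff its reflection
is preference-potential. Three independent routes to the same verdict are
kept deliberately separate:

1. the SCC test above (the production path);
2. a **constructive witness**: when the (possibly reflected) graph passes,
   set φ to the longest-path layer index of the tie-condensed DAG and return
   the game `u1 = u2 = φ` (potential) or `u1 = φ, u2 = −φ` (zero-sum); the
   builder asserts the witness's graph equals the input. Layer indices make
   witnesses small integers, exactly representable and readable;
3. a **linear-feasibility oracle** (`scipy.optimize.linprog`, HiGHS):
   φ-variables with `φ(dst) ≥ φ(src) + 1` per strict arc and equality per
   tie. Feasibility ⇔ class membership; the unit margin is harmless because
   the constraint system is scale-invariant.

The test suite asserts all three agree on every generic 2×2 and 2×3 graph
and on 1,000 seeded random 3×3 games.

At the strategic (cardinal) level, a game is an exact potential game iff
every 2×2 plaquette of payoff differences closes to zero. The implementation
accumulates a candidate φ from profile (0,0) (down column 0 by `u1`
differences, along rows by `u2` differences) and verifies every comparable
pair, which is equivalent to the plaquette condition since within-line
cycles telescope. Verification is exact for integer payoffs and uses a
relative `1e-9` tolerance for floats. Strategically-zero-sum is the
reflected condition.

The **path-weight** of a directed path is implemented with the signed
convention `Σ (u_mover(x_i) − u_mover(x_{i+1}))`, i.e. the *negative* of the
accumulated arc weights; the sign is kept as the defining formula states it
even though arc labels are non-negative, and `accumulated_improvement`
returns the positive total for convenience. Potential games make this sum
path-independent (`φ(start) − φ(end)`).

## Recognition

`recognize` decides whether an arbitrary digraph is the response graph of
some game. The underlying undirected graph of a response graph is the
comparability graph of the grid — the rook's graph `K_n □ K_m`. The
algorithm: (i) the neighborhood of any vertex must split into at most two
cliques with no cross edges (its row-mates and column-mates); (ii) each
remaining profile `(i, j)` is the unique common neighbor of `(i, 0)` and
`(0, j)` besides the origin; (iii) the resulting labeling is validated
against the full edge set, which rejects impostors such as strongly regular
lookalikes of rook's graphs; (iv) within every row and column the arcs must
form a total preorder (no strict arc inside a tie-component) — a directed
3-cycle on `K3` has a valid 1×3 skeleton but cyclic preferences no real
payoffs can produce, so it is correctly refused. Failures return a reason,
never an exception. `game_from_graph` then assigns integer payoffs per line
from the tie-condensed topological order, and asserts the rebuilt graph
matches. The contract is correctness plus near-linear behavior on valid
inputs; worst-case-linear recognition of adversarial inputs is not promised.

Single-strategy players are allowed: complete graphs are accepted as `1×k`
grids. For square grids the labeling is unique only up to row/column
renaming and a player swap; the 2×2 cycle's two factorizations are both
valid returns.

## Dominance, sinks, patterns

Dominance is strict and pure-strategy: `s` dominates `t` iff every opposing
strategy yields a strict arc toward `s`'s profile; a single tie blocks it.
Iterated elimination deletes one dominated strategy at a time (default
order: lowest player, then lowest strategy index); order-invariance of the
surviving set is asserted by tests over seeded random games rather than
assumed. Sink components come from the networkx condensation with ties
expanded to two arcs.

Every 2×2 generic graph is exactly one of MP / CO / SD / DD, decided by
cycle existence and the number of dominated strategies (0, 1, 2). A graph
with ties matches the labels of all full orientations of its undirected
edges, marked *weak*. Any 2×2 pattern occurring inside a larger response
graph sits on a full rectangle of the grid, so pattern search scans the
`C(n,2)·C(m,2)` rectangles.

Two executable theorem checkers double as property tests: a generic graph
with no strict CO rectangle has exactly one sink component whose profile set
is a *near-subgame* (for every two members, at least one cross profile also
belongs); and in a non-dominance-solvable game every surviving strategy
takes part in a weak-MP or weak-CO rectangle. The sink-uniqueness checker
reports rather than raises when its precondition fails, and is only asserted
on generic inputs — the tied case is deliberately out of its claimed scope.
The survivor-coverage checker accepts rectangles anywhere in the full grid
(the weakest faithful reading); its companion for zero-sum games checks
survivors against strict-MP rectangles only, since weak CO inside a generic
zero-sum graph is impossible.

## Enumeration and canonical codes

A generic `n × m` response graph is exactly a choice of a strict order over
rows per column and over columns per row, so enumeration iterates preference
orders — `(n!)^m (m!)^n` labeled graphs, finite and complete, with a
configurable budget (default 10⁶) that keeps 4×4 (≈10¹¹) out of reach by
design. Isomorphism of response graphs reduces to grid symmetries: row
permutations × column permutations × (player swap for square grids, or a
transpose normalizing `n ≤ m` otherwise). The player swap *is* included in
the symmetry group — with it the non-dominated 3×3 census lands on
156 = 25 + 30 + 101 and the 2×4 census on 9 = 2 + 2 + 5, which fixes the
convention. Canonicalization takes the lexicographic minimum of the sign
vector over the group (≤ 72 elements at 3×3) using precomputed index/flip
tables applied to all graphs at once; sign vectors are packed into 39-trit
integer chunks so the minimization stays exact and vectorized. The complete
3×3 census runs in about a second on one CPU.

Dominated-strategy filtering happens before canonicalization (it is cheap
and isomorphism-invariant), and the class predicates (`contains_MP`,
`preference_zero_sum`, `directed_k_cycle(k)`, ...) are evaluated once per
canonical representative.

## Random games and what the tests show

`random_game` draws i.i.d. uniform(0,1) payoffs — any atom-free law gives a
generic game with probability 1 (a redraw guards the measure-zero event) —
and is fully determined by its seed. Random games exercise the generic,
tie-free regime; the tied regime is covered separately by constructed
fixtures (all-ties games, partially tied graphs), because uniform draws
never produce it. Passing tests therefore certify: exact census counts by
exhaustive enumeration at 2×2 through 3×3; theorem conclusions over every
non-dominated 3×3 class and 500 seeded random games up to 4×3/3×4; and
triple-agreement of the classification routes. They say nothing about
games larger than the enumeration budget, players beyond two, or mixed
strategies — mixed-strategy Nash computation and mixed dominance are
explicitly out of scope.

## Problem sizes used

The default suite enumerates all graphs at 2×2 (16), 2×3 (288), 2×4 (9,216)
and 3×3 (46,656); oracle agreement is exhaustive at 2×2/2×3 and sampled at
1,000 seeds for 3×3; the theorem and round-trip suites use 500 seeded random
games each. These sizes make the whole suite run in well under a minute
while keeping every enumerative claim exact.

## Known limitations

- Recognition aims at correctness, not adversarial worst-case linearity.
- `classify_2x2` on a graph with `k` ties enumerates `2^k ≤ 16` orientations;
  fine at 2×2, but pattern scans over heavily tied large graphs pay that
  factor per rectangle.
- Preference-class witnesses use one fixed reflection convention (player 2);
  the symmetric choice is covered by tests, not by a second code path.
- The weighted graph stores absolute payoff differences; reconstructing a
  game from a weighted graph alone is not implemented (only the unweighted
  recognition path is).
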