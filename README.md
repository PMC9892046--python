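# respograph

Response-graph analysis of finite two-player normal-form games.

The *response graph* of a game has one node per strategy profile and an arc
between every pair of profiles that differ in a single player's strategy,
directed toward the profile that player weakly prefers (a payoff tie gives an
undirected edge). It records exactly the players' *preference orders* — not
the cardinal payoffs — yet it determines pure Nash equilibria, strict
dominance, and the *sink strongly connected components* that predict the
long-run outcome of evolutionary and learning dynamics (replicator dynamics,
α-rank-style rankings).

`respograph` is a toolkit for working with this object:

- **Build** (weighted) response graphs from payoff bimatrices
  (`u1, u2 : S1 × S2 → ℝ`), with reflection `(u1, u2) → (u1, −u2)` and
  reversal `(u1, u2) → (−u1, −u2)` at both the game and the graph level.
- **Recognize** whether an arbitrary unlabeled digraph is the response graph
  of some game, recover the strategy grid (the underlying graph must be a
  rook's graph, the comparability graph of an `n × m` grid), and construct a
  realizing game with integer payoffs.
- **Analyse** structure: sink components, pure Nash profiles, strict and
  iterated dominance, near-subgames, and the four-pattern taxonomy of 2×2
  graphs — Matching Pennies (MP, the directed 4-cycle), Coordination (CO),
  Single- and Double-dominance (SD, DD) — including weak forms with ties.
- **Classify** potential and zero-sum structure. A game is
  *preference-potential* iff no cycle of its response graph contains a strict
  arc, and *preference-zero-sum* iff its reflection is preference-potential:
  acyclicity is the graph property behind both classes, and the two are dual
  under reflection. Exact (strategic-level) tests via the plaquette closure
  condition, constructive witnesses (`u1 = u2 = φ` or `u2 = −u1`), and an
  independent linear-feasibility oracle are all included.
- **Enumerate** all generic `n × m` response graphs (a graph ↔ a choice of
  per-column and per-row strict preference orders; `(n!)^m (m!)^n` labeled
  graphs) and count isomorphism classes under strategy relabeling and player
  swap — reproducing, for example, the census of non-dominated 3×3 classes.

## Worked example

Rock–Paper–Scissors with the standard 1 / 0 / −1 payoffs:

```sh
$ python -c "from respograph import named_game, save_game; \
             save_game(named_game('rps'), 'rps.json')"
$ respograph classify rps.json
{
 "generic": true,
 "preference_potential": false,
 "preference_zero_sum": true,
 "dominance_solvable": false,
 "strategically_potential": false,
 "strategically_zero_sum": true
}
```

The graph of RPS is one big cycle structure — all 9 profiles form a single
sink component, so no profile is a pure Nash equilibrium and the game is not
dominance-solvable. It is zero-sum (`u2 = −u1`), hence strategically and
preference-zero-sum; it cannot be potential, since its response graph has
strict cycles. The same library calls are available directly:

```python
>>> from respograph import named_game, build_response_graph, sink_components
>>> rg = build_response_graph(named_game("rps"))
>>> [len(s) for s in sink_components(rg)]
[9]
>>> build_response_graph(named_game("biased_rps")) == rg   # payoff-invariance
True
```

The full small-game census, checked against the expected class counts:

```sh
$ respograph census --pretty
2x2: non_dominated=2 zs=1 pot=1 neither=0 [PASS]
2x3: non_dominated=3 zs=1 pot=1 neither=1 [PASS]
2x4: non_dominated=9 zs=2 pot=2 neither=5 [PASS]
3x3: non_dominated=156 zs=25 pot=30 neither=101 [PASS]
```

Reading the 3×3 line: among the 46,656 generic 3×3 preference assignments
there are 156 isomorphism classes with no strictly dominated strategy; 25 of
them share a response graph with a zero-sum game, 30 with a potential game,
and the remaining 101 with neither. (A non-dominated class can never be both:
such a game would be dominance-solvable.)

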