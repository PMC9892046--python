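import itertools

import numpy as np
import pytest
from scipy.optimize import linprog

from respograph import (Game, build_response_graph, named_game, random_game,
                        reflect_game)
from respograph.classification import (classification_report,
                                       feasible_preference_class,
                                       is_preference_potential,
                                       is_preference_zero_sum,
                                       is_strategically_potential,
                                       is_strategically_zero_sum,
                                       realize_preference_witness)
from respograph.response_graph import comparable_pairs
from respograph.structure import is_dominance_solvable, pure_nash, \
    sink_components

from conftest import graph_2x2, MP_SIGNS


class TestPreferenceLevel:
    def test_acyclic_2x2_graphs_are_potential(self, co_graph, sd_graph,
                                               dd_graph):
        for rg in (co_graph, sd_graph, dd_graph):
            assert is_preference_potential(rg)

    def test_mp_not_potential_but_zero_sum(self, mp_graph):
        assert not is_preference_potential(mp_graph)
        assert is_preference_zero_sum(mp_graph)

    def test_co_not_zero_sum(self, co_graph):
        # reflecting CO gives the MP cycle: the payoff cycle d>b>a>c>d
        assert not is_preference_zero_sum(co_graph)

    def test_all_ties_graph_is_potential(self, all_ties_graph):
        # cycles exist but contain only undirected edges
        assert is_preference_potential(all_ties_graph)
        assert is_preference_zero_sum(all_ties_graph)

    def test_rps_zero_sum_not_potential(self, rps_graph):
        assert is_preference_zero_sum(rps_graph)
        assert not is_preference_potential(rps_graph)

    def test_reflected_6_cycle_not_zero_sum_despite_no_co(self):
        from respograph.enumeration import find_classes
        from respograph.structure import find_pattern_subgames

        reps = find_classes(3, 3, ["no_dominated_strategy"])
        no_co = [rg for rg in reps if not find_pattern_subgames(rg, "CO")]
        assert any(not is_preference_zero_sum(rg) for rg in no_co)

    @pytest.mark.parametrize("seed", range(20))
    def test_duality_regression(self, seed):
        rg = build_response_graph(random_game(3, 3, seed))
        assert is_preference_zero_sum(rg) == \
            is_preference_potential(rg.reflect(2))
        # the theorems are symmetric under the choice of reflected player
        assert is_preference_potential(rg.reflect(2)) == \
            is_preference_potential(rg.reflect(1))


class TestStrategicLevel:
    def test_identical_interest_is_potential_with_phi_u1(self):
        u = np.array([[1.0, 3.0], [0.0, 5.0]])
        ok, phi = is_strategically_potential(Game(u, u))
        assert ok
        diff = phi.values - u
        assert np.allclose(diff, diff[0, 0])   # phi = u1 up to a constant

    def test_mp_payoffs_not_potential(self):
        ok, phi = is_strategically_potential(named_game("matching_pennies"))
        assert not ok and phi is None

    def test_zero_sum_game_is_strategically_zero_sum(self, rps):
        assert is_strategically_zero_sum(rps)

    def test_identical_interest_co_not_zero_sum(self):
        assert not is_strategically_zero_sum(named_game("coordination"))

    def test_biased_rps_preference_but_not_strategically_zero_sum(self):
        g = named_game("biased_rps")
        assert is_preference_zero_sum(build_response_graph(g))
        assert not is_strategically_zero_sum(g)

    @pytest.mark.parametrize("seed", range(10))
    def test_strategic_implies_preference(self, seed):
        base = random_game(3, 3, seed)
        phi = base.u1
        for g in (Game(phi, phi), Game(phi, -phi)):
            rg = build_response_graph(g)
            ok, _ = is_strategically_potential(g)
            if ok:
                assert is_preference_potential(rg)
            if is_strategically_zero_sum(g):
                assert is_preference_zero_sum(rg)

    @pytest.mark.parametrize("seed", range(5))
    def test_potential_witness_makes_paths_agree(self, seed):
        from respograph.response_graph import path_weight

        g = random_game(3, 3, seed)
        pot = Game(g.u1, g.u1)      # identical interest: potential by Def
        rg = build_response_graph(pot, weighted=True)
        ok, phi = is_strategically_potential(pot)
        assert ok
        # two directed monotone paths between the same endpoints
        lo = min(rg.profiles(), key=lambda p: phi(p))
        hi = max(rg.profiles(), key=lambda p: phi(p))
        if lo.row != hi.row and lo.col != hi.col:
            a = [lo, (lo.row, hi.col), hi]
            b = [lo, (hi.row, lo.col), hi]
            try:
                assert path_weight(rg, a) == pytest.approx(path_weight(rg, b))
            except ValueError:
                pass    # a middle hop may run against an arc; not a path then


class TestWitnesses:
    def test_mp_zero_sum_witness(self, mp_graph):
        wit = realize_preference_witness(mp_graph, "zero_sum")
        assert wit is not None
        assert np.array_equal(wit.u2, -wit.u1)
        assert build_response_graph(wit) == mp_graph

    def test_co_zero_sum_witness_does_not_exist(self, co_graph):
        assert realize_preference_witness(co_graph, "zero_sum") is None

    def test_co_potential_witness_has_two_nash(self, co_graph):
        wit = realize_preference_witness(co_graph, "potential")
        assert wit is not None
        assert np.array_equal(wit.u1, wit.u2)
        assert len(pure_nash(build_response_graph(wit))) == 2

    def test_witness_payoffs_are_small_integers(self, rps_graph):
        wit = realize_preference_witness(rps_graph, "zero_sum")
        assert wit is not None
        assert np.array_equal(wit.u1, np.round(wit.u1))
        assert np.abs(wit.u1).max() <= 9

    def test_unknown_target_rejected(self, mp_graph):
        with pytest.raises(ValueError):
            realize_preference_witness(mp_graph, "harmonic")


class TestLPOracle:
    @pytest.mark.parametrize("target", ["potential", "zero_sum"])
    def test_oracle_agrees_on_fixtures(self, target, mp_graph, co_graph,
                                       sd_graph, rps_graph):
        for rg in (mp_graph, co_graph, sd_graph, rps_graph):
            verdict = (is_preference_potential(rg) if target == "potential"
                       else is_preference_zero_sum(rg))
            assert feasible_preference_class(rg, target) == verdict
            assert (realize_preference_witness(rg, target)
                    is not None) == verdict

    def test_sd_never_both_strategic_classes(self, sd_graph):
        """No payoff assignment with the single-dominance graph is
        simultaneously an exact potential game and (up to strategic
        equivalence) a zero-sum game: the combined linear system with unit
        arc margins and both plaquette closures is infeasible."""
        n = m = 2
        nv = 2 * n * m    # u1 then u2, row-major

        def vid(player, r, c):
            return (player - 1) * n * m + r * m + c

        A_ub, b_ub = [], []
        for p, q in comparable_pairs(n, m):
            s = sd_graph.sign(p, q)
            mover = 1 if p.col == q.col else 2
            lo, hi = (p, q) if s > 0 else (q, p)
            row = np.zeros(nv)
            row[vid(mover, *lo)], row[vid(mover, *hi)] = 1.0, -1.0
            A_ub.append(row)
            b_ub.append(-1.0)
        # plaquette closures: potential (e2 = +1) and zero-sum (e2 = -1)
        A_eq = []
        for e2 in (1.0, -1.0):
            row = np.zeros(nv)
            row[vid(1, 1, 0)] += 1; row[vid(1, 0, 0)] -= 1
            row[vid(2, 1, 1)] += e2; row[vid(2, 1, 0)] -= e2
            row[vid(1, 1, 1)] -= 1; row[vid(1, 0, 1)] += 1
            row[vid(2, 0, 1)] -= e2; row[vid(2, 0, 0)] += e2
            A_eq.append(row)
        res = linprog(c=np.zeros(nv), A_ub=np.array(A_ub), b_ub=np.array(b_ub),
                      A_eq=np.array(A_eq), b_eq=np.zeros(2),
                      bounds=[(None, None)] * nv, method="highs")
        assert res.status != 0    # infeasible

        # sanity: each class alone is realizable on the SD graph
        assert feasible_preference_class(sd_graph, "potential")
        assert feasible_preference_class(sd_graph, "zero_sum")


class TestReport:
    def test_rps_report(self, rps):
        rep = classification_report(rps)
        assert rep.generic
        assert rep.preference_zero_sum and not rep.preference_potential
        assert rep.strategically_zero_sum and not rep.strategically_potential
        assert not rep.dominance_solvable

    def test_sd_report_both_preference_classes_and_solvable(self, sd_graph):
        rep = classification_report(sd_graph)
        assert rep.preference_potential and rep.preference_zero_sum
        assert rep.dominance_solvable
        assert rep.strategically_potential is None    # graph-only input

    def test_strategic_flags_imply_preference_flags(self):
        for seed in range(10):
            g = random_game(2, 3, seed)
            rep = classification_report(g)
            if rep.strategically_potential:
                assert rep.preference_potential
            if rep.strategically_zero_sum:
                assert rep.preference_zero_sum

    def test_witnesses_attached_on_request(self, mp_graph):
        rep = classification_report(mp_graph, witnesses=True)
        assert rep.zero_sum_witness is not None
        assert rep.potential_witness is None
        assert "zero_sum_witness" in rep.to_dict()

    def test_zero_sum_graphs_single_sink_at_most_one_nash(self):
        # generic zero-sum structure: one sink component, <= 1 pure Nash
        for seed in range(15):
            u = random_game(3, 3, seed).u1
            rg = build_response_graph(Game(u, -u))
            assert len(sink_components(rg)) == 1
            assert len(pure_nash(rg)) <= 1
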