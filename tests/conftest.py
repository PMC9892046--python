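import numpy as np
import pytest

from respograph import ResponseGraph, build_response_graph, named_game

# 2x2 pair order: [col0 row-pair, col1 row-pair, row0 col-pair, row1 col-pair]
MP_SIGNS = (-1, 1, 1, -1)      # directed 4-cycle (0,0)->(0,1)->(1,1)->(1,0)->
CO_SIGNS = (1, -1, 1, -1)      # sinks (0,1) and (1,0)
FIG_WEAK_MP_SD = (-1, 1, 1, 0)  # MP with one edge left undirected


def graph_2x2(signs) -> ResponseGraph:
    return ResponseGraph.from_sign_vector(2, 2, signs)


@pytest.fixture(scope="session")
def rps():
    return named_game("rps")


@pytest.fixture(scope="session")
def rps_graph(rps):
    return build_response_graph(rps)


@pytest.fixture(scope="session")
def mp_graph():
    return build_response_graph(named_game("matching_pennies"))


@pytest.fixture(scope="session")
def co_graph():
    return build_response_graph(named_game("coordination"))


@pytest.fixture(scope="session")
def sd_graph():
    return build_response_graph(named_game("single_dominance"))


@pytest.fixture(scope="session")
def dd_graph():
    return build_response_graph(named_game("double_dominance"))


@pytest.fixture(scope="session")
def all_ties_graph():
    return ResponseGraph.from_sign_vector(2, 2, (0, 0, 0, 0))
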