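"""Hypergeometric pair enrichment and sequence similarity networks."""

import itertools
import math

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from coevoscape import (
    LibraryScheme,
    SelectionDataset,
    build_ssn,
    detect_communities,
    filter_enriched,
    hamming,
    pair_enrichment,
    pairing_matrix,
)
from coevoscape.enrichment import PairEnrichmentRecord


def hypergeom_sf_oracle(k, M, n, N):
    """P(X >= k) by direct enumeration of the hypergeometric pmf."""
    total = 0.0
    for x in range(k, min(n, N) + 1):
        total += math.comb(n, x) * math.comb(M - n, N - x) / math.comb(M, N)
    return total


def test_printed_hypergeometric_example(scheme_2x2):
    # M=20, n=5, N=4, k=4 -> C(5,4) C(15,0) / C(20,4) = 5/4845
    assert hypergeom_sf_oracle(4, 20, 5, 4) == pytest.approx(5 / 4845, rel=1e-12)


@settings(derandomize=True, max_examples=80)
@given(st.data())
def test_pair_pvalues_match_enumeration_oracle(data):
    from scipy.stats import hypergeom

    M = data.draw(st.integers(5, 200))
    n = data.draw(st.integers(1, M))
    N = data.draw(st.integers(1, M))
    k = data.draw(st.integers(0, min(n, N)))
    p = float(hypergeom.sf(k - 1, M, n, N))
    oracle = hypergeom_sf_oracle(k, M, n, N)
    assert p == pytest.approx(oracle, rel=1e-12, abs=1e-300)


def test_pvalue_boundary_cases():
    assert hypergeom_sf_oracle(0, 50, 10, 5) == pytest.approx(1.0)
    # degenerate support: n = N = M, k = min(n, N)
    assert hypergeom_sf_oracle(7, 7, 7, 7) == pytest.approx(1.0)


def test_pair_enrichment_on_toy_dataset(scheme_2x2):
    ds = SelectionDataset(
        scheme=scheme_2x2,
        rounds=["R0", "R1"],
        counts={
            "R0": {("F", "F"): 10},
            "R1": {("F", "F"): 12, ("F", "V"): 4, ("V", "V"): 4},
        },
    )
    records = pair_enrichment(ds)
    by_pair = {(r.chain_a, r.chain_b): r for r in records}
    r = by_pair[("F", "F")]
    assert (r.k, r.n, r.N, r.M) == (12, 16, 12, 20)
    assert r.p_value == pytest.approx(hypergeom_sf_oracle(12, 20, 16, 12), rel=1e-12)
    assert r.k <= min(r.n, r.N) <= r.M


def test_filter_thresholds_are_strict_below_and_geq():
    rec = lambda p, k: PairEnrichmentRecord("A", "B", k, k, k, 100, p)
    assert filter_enriched([rec(0.049, 20)]) == [rec(0.049, 20)]
    assert filter_enriched([rec(0.05, 20)]) == []  # "below" is strict
    assert filter_enriched([rec(0.001, 19)]) == []  # count >= 20


@settings(derandomize=True, max_examples=30)
@given(
    st.lists(
        st.tuples(st.floats(0, 1), st.integers(0, 100)), min_size=1, max_size=30
    ),
    st.floats(0.001, 0.5),
    st.integers(1, 50),
)
def test_filter_is_monotone_in_thresholds(entries, p_max, min_count):
    records = [
        PairEnrichmentRecord(f"A{i}", f"B{i}", k, k + 1, k + 1, 1000, p)
        for i, (p, k) in enumerate(entries)
    ]
    tight = set(id(r) for r in filter_enriched(records, p_max, min_count))
    loose = set(id(r) for r in filter_enriched(records, p_max * 2, max(0, min_count - 5)))
    assert tight <= loose


def test_hamming_distance_and_errors():
    assert hamming("FILMV", "FILMV") == 0
    assert hamming("FILMV", "FILVV") == 1
    with pytest.raises(ValueError):
        hamming("FI", "FIL")


@settings(derandomize=True, max_examples=50)
@given(
    st.tuples(*[st.text(alphabet="FILMV", min_size=5, max_size=5)] * 3)
)
def test_hamming_is_a_metric(seqs):
    a, b, c = seqs
    assert hamming(a, b) == hamming(b, a)
    assert hamming(a, c) <= hamming(a, b) + hamming(b, c)
    assert (hamming(a, b) == 0) == (a == b)


def test_ssn_edges_use_strict_threshold():
    # distance 2 -> edge at threshold 3; distance 3 -> no edge
    ssn = build_ssn(["FFFFF", "FFFVV", "FFVVV"], threshold=3)
    g = ssn.graph
    assert g.has_edge("FFFFF", "FFFVV")  # distance 2
    assert not g.has_edge("FFFFF", "FFVVV")  # distance 3
    assert g.has_edge("FFFVV", "FFVVV")  # distance 1
    assert build_ssn(["FFFFF", "FFFFF"], threshold=1).graph.number_of_nodes() == 1


def test_ssn_invariant_under_reordering():
    seqs = ["FFFFF", "FFFVV", "VVVVV", "FVFVF"]
    e1 = set(build_ssn(seqs, 3).graph.edges)
    e2 = set(build_ssn(list(reversed(seqs)), 3).graph.edges)
    assert {frozenset(e) for e in e1} == {frozenset(e) for e in e2}


def test_ssn_rejects_unequal_lengths():
    with pytest.raises(ValueError):
        build_ssn(["FF", "FFF"], threshold=2)


def test_isolated_sequences_form_singleton_communities():
    ssn = build_ssn(["FFFFF", "VVVVV", "LLLLL"], threshold=2)
    ssn = detect_communities(ssn)
    assert ssn.graph.number_of_edges() == 0
    assert len(set(ssn.communities.values())) == 3


def test_two_cliques_give_two_communities():
    seqs_a = ["FFFFF", "FFFFV", "FFFVF"]  # mutual distance <= 2
    seqs_b = ["VVVVV", "VVVVL", "VVVLV"]
    ssn = detect_communities(build_ssn(seqs_a + seqs_b, threshold=3))
    labels_a = {ssn.communities[s] for s in seqs_a}
    labels_b = {ssn.communities[s] for s in seqs_b}
    assert len(labels_a) == len(labels_b) == 1
    assert labels_a != labels_b
    # community map: 2 nodes, no inter-community edges
    assert ssn.community_map.number_of_nodes() == 2
    assert ssn.community_map.number_of_edges() == 0


def test_single_clique_community_map():
    ssn = detect_communities(build_ssn(["FFFFF", "FFFFV", "FFFVF"], threshold=3))
    assert len(set(ssn.communities.values())) == 1
    assert ssn.community_map.number_of_nodes() == 1
    assert ssn.community_map.number_of_edges() == 0


def _modularity(g, part):
    return nx.algorithms.community.modularity(g, part)


def test_barbell_communities_match_exhaustive_bipartition_oracle():
    """Two 4-cliques joined by one edge: greedy modularity must find the
    bipartition that exhaustive search over all 2-partitions ranks best."""
    from coevoscape.enrichment import SSNGraph

    g = nx.barbell_graph(4, 0)  # nodes 0-3 and 4-7, bridge 3-4
    best, best_q = None, -np.inf
    nodes = list(g.nodes)
    for bits in itertools.product([0, 1], repeat=len(nodes) - 1):
        side = {nodes[0]: 0}
        side.update({n: b for n, b in zip(nodes[1:], bits)})
        parts = [
            {n for n in nodes if side[n] == 0},
            {n for n in nodes if side[n] == 1},
        ]
        if not parts[0] or not parts[1]:
            continue
        q = _modularity(g, parts)
        if q > best_q:
            best, best_q = parts, q
    ssn = detect_communities(SSNGraph(graph=g, threshold=0))
    found = {}
    for n, lab in ssn.communities.items():
        found.setdefault(lab, set()).add(n)
    assert sorted(map(sorted, found.values())) == sorted(map(sorted, best))


def test_pairing_matrix_counts():
    rec = lambda a, b: PairEnrichmentRecord(a, b, 30, 30, 30, 100, 0.01)
    labels_a = {"A1": 0, "A2": 1, "A3": 2}
    labels_b = {"B1": 0, "B2": 1, "B3": 2}
    # diagonal-only pairs
    mat = pairing_matrix([rec("A1", "B1"), rec("A2", "B2")], labels_a, labels_b)
    assert mat.loc[0, 0] == 1 and mat.loc[1, 1] == 1
    assert mat.to_numpy().sum() == 2
    # two cross pairs
    mat = pairing_matrix(
        [rec("A1", "B2"), rec("A3", "B1"), rec("A2", "B2")], labels_a, labels_b
    )
    off_diag = mat.to_numpy().sum() - np.trace(mat.to_numpy())
    assert off_diag == 2
    # empty input -> zero matrix
    assert pairing_matrix([], labels_a, labels_b).to_numpy().sum() == 0
    with pytest.raises(KeyError):
        pairing_matrix([rec("A9", "B1")], labels_a, labels_b)
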