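"""Pair-enrichment filtering and sequence similarity networks.

Final-round chain pairings are tested for enrichment beyond what the marginal
chain abundances predict with a one-sided hypergeometric test: drawing the
``n`` copies of a given A-chain from a population of ``M`` reads containing
``N`` copies of a given B-chain, the p-value is the survival probability of
observing at least the ``k`` co-occurrences seen.  Retained pairs feed a
sequence similarity network over concatenated A+B sequences (Hamming distance
strictly below a threshold) whose communities summarize the distinct binding
solutions the selection found.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .library import SelectionDataset

__all__ = [
    "PairEnrichmentRecord",
    "SSNGraph",
    "pair_enrichment",
    "filter_enriched",
    "build_ssn",
    "detect_communities",
    "pairing_matrix",
    "hamming",
]


@dataclass(frozen=True)
class PairEnrichmentRecord:
    chain_a: str
    chain_b: str
    k: int  # observed pair count
    n: int  # total count of this chain_a
    N: int  # total count of this chain_b
    M: int  # total population size
    p_value: float


def pair_enrichment(dataset: SelectionDataset, round_label: Optional[str] = None):
    """One-sided hypergeometric enrichment of every observed pair.

    For each pair, p = P(X >= k) with X ~ Hypergeometric(M, n, N), computed
    as the survival function at k - 1 (exact, log-space internally).
    """
    r = round_label or dataset.final_round
    counts = dataset.counts[r]
    if not counts:
        raise ValueError(f"round {r!r} has no counts")
    M = sum(counts.values())
    if M == 0:
        raise ValueError("total population size is zero")
    a_tot, b_tot = {}, {}
    for (a, b), c in counts.items():
        a_tot[a] = a_tot.get(a, 0) + c
        b_tot[b] = b_tot.get(b, 0) + c
    records = []
    for (a, b), k in sorted(counts.items()):
        n, N = a_tot[a], b_tot[b]
        p = float(hypergeom.sf(k - 1, M, n, N))
        records.append(PairEnrichmentRecord(a, b, k, n, N, M, p))
    return records


def filter_enriched(records, p_max: float = 0.05, min_count: int = 20):
    """Retain records with p strictly below ``p_max`` and k >= ``min_count``."""
    return [r for r in records if r.p_value < p_max and r.k >= min_count]


def records_to_frame(records, retained=None) -> pd.DataFrame:
    kept = set((r.chain_a, r.chain_b) for r in retained) if retained is not None else None
    rows = []
    for r in records:
        row = {
            "chain_a": r.chain_a, "chain_b": r.chain_b, "k": r.k,
            "n": r.n, "N": r.N, "M": r.M, "p_value": r.p_value,
        }
        if kept is not None:
            row["retained"] = (r.chain_a, r.chain_b) in kept
        rows.append(row)
    return pd.DataFrame(rows)


def hamming(s1: str, s2: str) -> int:
    if len(s1) != len(s2):
        raise ValueError("sequences must have equal length for Hamming distance")
    return sum(c1 != c2 for c1, c2 in zip(s1, s2))


@dataclass
class SSNGraph:
    """Sequence similarity network plus its community structure."""

    graph: nx.Graph
    threshold: int
    communities: dict = field(default_factory=dict)
    community_map: Optional[nx.Graph] = None

    @property
    def nodes(self):
        return list(self.graph.nodes)

    def community_sizes(self) -> dict:
        sizes = {}
        for label in self.communities.values():
            sizes[label] = sizes.get(label, 0) + 1
        return sizes


def build_ssn(sequences: Iterable[str], threshold: int = 3) -> SSNGraph:
    """Build the SSN: an edge joins sequences at Hamming distance < threshold.

    With the default threshold of 3, sequences differing at <= 2 positions are
    connected.  All sequences are fixed-length position strings, so Hamming
    distance is the natural edit distance here (indels are meaningless).
    """
    seqs = sorted(set(sequences))
    if len(set(len(s) for s in seqs)) > 1:
        raise ValueError("all sequences must have equal length")
    g = nx.Graph()
    g.add_nodes_from(seqs)
    if seqs:
        arr = np.frombuffer("".join(seqs).encode(), dtype=np.uint8).reshape(len(seqs), -1)
        # pairwise Hamming distances in blocks to bound memory
        block = max(1, 10_000_000 // max(1, arr.shape[0] * arr.shape[1]))
        for start in range(0, len(seqs), block):
            chunk = arr[start : start + block]
            d = (chunk[:, None, :] != arr[None, :, :]).sum(axis=2)
            ii, jj = np.nonzero(d < threshold)
            for i, j in zip(ii, jj):
                gi = start + i
                if gi < j:
                    g.add_edge(seqs[gi], seqs[j], distance=int(d[i, j]))
    return SSNGraph(graph=g, threshold=threshold)


def detect_communities(ssn: SSNGraph, method: str = "greedy", seed: int = 0) -> SSNGraph:
    """Assign community labels and build the condensed community map.

    ``greedy`` uses networkx greedy modularity maximization (deterministic);
    ``leiden`` uses igraph/leidenalg when available.  The community map
    merges each community into one node; edge weights count inter-community
    edges.
    """
    g = ssn.graph
    if method == "greedy":
        if g.number_of_edges() == 0:
            parts = [{n} for n in g.nodes]
        else:
            parts = list(nx.algorithms.community.greedy_modularity_communities(g))
            covered = set().union(*parts) if parts else set()
            parts += [{n} for n in g.nodes if n not in covered]
    elif method == "leiden":
        import igraph as ig
        import leidenalg

        nodes = list(g.nodes)
        index = {n: i for i, n in enumerate(nodes)}
        h = ig.Graph(n=len(nodes), edges=[(index[u], index[v]) for u, v in g.edges])
        part = leidenalg.find_partition(
            h, leidenalg.ModularityVertexPartition, seed=seed
        )
        parts = [{nodes[i] for i in community} for community in part]
    else:
        raise ValueError(f"unknown community method {method!r}")

    # stable labels: communities ordered by size desc, then lexicographic
    parts = sorted(parts, key=lambda c: (-len(c), min(c)))
    communities = {}
    for label, members in enumerate(parts):
        for node in members:
            communities[node] = label
    cmap = nx.Graph()
    cmap.add_nodes_from(
        (label, {"size": len(members)}) for label, members in enumerate(parts)
    )
    for u, v in g.edges:
        cu, cv = communities[u], communities[v]
        if cu != cv:
            w = cmap.get_edge_data(cu, cv, {}).get("weight", 0)
            cmap.add_edge(cu, cv, weight=w + 1)
    ssn.communities = communities
    ssn.community_map = cmap
    return ssn


def pairing_matrix(enriched, labels_a: dict, labels_b: dict) -> pd.DataFrame:
    """Cluster x cluster matrix of enriched pair counts.

    ``labels_a``/``labels_b`` map chain sequences to cluster labels; entry
    (i, j) counts enriched pairs whose A chain is in cluster i and B chain in
    cluster j.  The matrix total equals the number of pairs.
    """
    rows = sorted(set(labels_a.values()))
    cols = sorted(set(labels_b.values()))
    mat = pd.DataFrame(0, index=rows, columns=cols)
    for rec in enriched:
        a, b = rec.chain_a, rec.chain_b
        if a not in labels_a or b not in labels_b:
            raise KeyError(f"pair ({a}, {b}) has no cluster label")
        mat.loc[labels_a[a], labels_b[b]] += 1
    return mat
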