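"""Residue networks, consensus communities and difference contact analysis.

The workflow mirrors the four dCNA steps: build one contact network per
functional state; intersect them into a *consensus network* of contacts
stable in every state; partition the consensus graph into dynamic
communities with the Girvan–Newman algorithm under a modularity stopping
rule; and subtract per-state contact probabilities edge-by-edge to
obtain difference networks and community-pair ΔP matrices.

Two edge-weight conventions are supported:

* ``dcna`` — edges carry the contact occupancy P_ij itself; differences
  of these occupancies are the ΔP of difference contact network
  analysis;
* ``covariance`` — edges exist where the binary 4.5 Å / 75 % contact
  rule holds and carry w_ij = −ln|c_ij|, the classical covariance-based
  community network weighting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .contact_dynamics import ContactProbabilityMatrix, CorrelationMatrix, binary_contacts
from .ensemble_io import NodeTable
from .errors import AlignmentError, NetworkError

__all__ = [
    "ContactNetwork",
    "ConsensusNetwork",
    "CommunityPartition",
    "DifferenceNetwork",
    "CommunityDeltaMatrix",
    "build_network",
    "consensus_network",
    "modularity",
    "girvan_newman",
    "difference_network",
    "community_delta",
    "top_changed_residues",
]


@dataclass
class ContactNetwork:
    """Weighted residue graph for one state (nodes = node indices)."""

    graph: nx.Graph
    node_table: NodeTable
    mode: str
    state_label: str


@dataclass
class ConsensusNetwork:
    """Edges stable across all states; each edge stores per-state P."""

    graph: nx.Graph
    node_table: NodeTable
    states: list[str]
    stability_min_probability: float
    dropped_nodes: list[str] = field(default_factory=list)


@dataclass
class CommunityPartition:
    """Node→community labelling with its modularity score.

    ``trace`` records every (labels, Q) partition visited while the
    dendrogram was cut, so alternative stopping choices stay auditable.
    """

    labels: np.ndarray
    modularity: float
    trace: list[tuple[np.ndarray, float]] = field(default_factory=list)

    @property
    def n_communities(self) -> int:
        return len(np.unique(self.labels))

    def communities(self) -> list[set[int]]:
        return [set(np.flatnonzero(self.labels == c)) for c in np.unique(self.labels)]


@dataclass
class DifferenceNetwork:
    """Per consensus edge, ΔP = P(state_b) − P(state_a)."""

    graph: nx.Graph  # edge attribute 'delta'
    node_table: NodeTable
    state_a: str
    state_b: str

    @property
    def transition(self) -> str:
        return f"{self.state_a}->{self.state_b}"


@dataclass
class CommunityDeltaMatrix:
    """K×K aggregated ΔP between community pairs (diagonal = within)."""

    delta: np.ndarray
    community_ids: np.ndarray
    sizes: np.ndarray
    transition: str


def build_network(
    P: ContactProbabilityMatrix,
    c: CorrelationMatrix | None = None,
    mode: str = "dcna",
    occupancy_threshold: float = 0.75,
) -> ContactNetwork:
    """Turn contact statistics into a weighted residue graph.

    dCNA mode keeps every pair with nonzero occupancy, weighted by the
    occupancy itself.  Covariance mode keeps pairs passing the binary
    occupancy rule and weights them w_ij = −ln|c_ij|; a correlation of
    exactly zero on a qualifying edge would give infinite weight and is
    rejected.
    """
    N = P.P.shape[0]
    G = nx.Graph()
    G.add_nodes_from(range(N))
    if mode == "dcna":
        ii, jj = np.nonzero(np.triu(P.P, k=1) > 0)
        for i, j in zip(ii.tolist(), jj.tolist()):
            G.add_edge(i, j, weight=float(P.P[i, j]), p=float(P.P[i, j]))
    elif mode == "covariance":
        if c is None:
            raise NetworkError("covariance mode requires a correlation matrix")
        if c.c.shape != P.P.shape:
            raise AlignmentError("correlation and contact matrices differ in size")
        A = binary_contacts(P, occupancy_threshold)
        ii, jj = np.nonzero(np.triu(A, k=1))
        for i, j in zip(ii.tolist(), jj.tolist()):
            cij = abs(float(c.c[i, j]))
            if cij == 0.0:
                keys = P.node_table.keys()
                raise NetworkError(
                    f"zero correlation on contact edge {keys[i]}–{keys[j]}: infinite weight"
                )
            G.add_edge(i, j, weight=float(-np.log(cij)), p=float(P.P[i, j]))
    else:
        raise NetworkError(f"unknown network mode {mode!r}")
    return ContactNetwork(graph=G, node_table=P.node_table, mode=mode, state_label=P.state_label)


def consensus_network(
    matrices: list[ContactProbabilityMatrix],
    stability_min_probability: float = 0.75,
) -> ConsensusNetwork:
    """Intersect per-state contact maps into a stable-contact network.

    An edge survives iff its occupancy reaches the stability threshold in
    *every* state.  Nodes absent from any state (for example DNA present
    in only one functional state) are dropped from the consensus node
    set and reported.  Each surviving edge stores one probability per
    state under the ``p_<label>`` edge attributes.
    """
    if len(matrices) < 2:
        raise NetworkError("a consensus needs at least 2 states")
    labels = [m.state_label for m in matrices]
    if len(set(labels)) != len(labels):
        raise NetworkError(f"state labels must be distinct, got {labels}")

    key_cols = ["chain_id", "residue_number", "insertion_code"]
    key_sets = [
        set(map(tuple, m.node_table.df[key_cols].itertuples(index=False))) for m in matrices
    ]
    common = set.intersection(*key_sets)
    if not common:
        raise AlignmentError("states share no residues")
    base = matrices[0].node_table
    keep_mask = [
        tuple(row) in common for row in base.df[key_cols].itertuples(index=False)
    ]
    dropped = sorted(
        {k for s in key_sets for k in s} - common
    )
    sub_df = base.df[keep_mask].reset_index(drop=True).copy()
    sub_df["node_index"] = np.arange(len(sub_df))
    node_table = NodeTable(sub_df)

    # per-state index of each consensus node
    per_state_idx = []
    for m in matrices:
        idx = [
            m.node_table.lookup(r.chain_id, r.residue_number, r.insertion_code)
            for r in sub_df.itertuples(index=False)
        ]
        per_state_idx.append(np.asarray(idx))

    M = len(sub_df)
    sub_P = [m.P[np.ix_(ix, ix)] for m, ix in zip(matrices, per_state_idx)]
    stable = np.ones((M, M), dtype=bool)
    for P in sub_P:
        stable &= P >= stability_min_probability
    ii, jj = np.nonzero(np.triu(stable, k=1))

    G = nx.Graph()
    G.add_nodes_from(range(M))
    for i, j in zip(ii.tolist(), jj.tolist()):
        attrs = {f"p_{lab}": float(P[i, j]) for lab, P in zip(labels, sub_P)}
        G.add_edge(i, j, weight=1.0, **attrs)
    return ConsensusNetwork(
        graph=G,
        node_table=node_table,
        states=labels,
        stability_min_probability=float(stability_min_probability),
        dropped_nodes=[f"{c}:{r}{i}" for c, r, i in dropped],
    )


def _labels_from_components(G: nx.Graph, n_nodes: int) -> np.ndarray:
    labels = np.empty(n_nodes, dtype=int)
    comps = sorted(nx.connected_components(G), key=min)
    for cid, comp in enumerate(comps):
        for n in comp:
            labels[n] = cid
    return labels


def modularity(
    network: ContactNetwork | ConsensusNetwork | nx.Graph,
    partition: CommunityPartition | np.ndarray,
    weighted: bool = False,
) -> float:
    """Newman–Girvan modularity Q of a partition.

    Q = Σ_c [ e_c/m − (d_c/2m)² ] with m the (weighted) edge total, e_c
    the intra-community edge total and d_c the community degree total.
    Unweighted by default, matching the non-weighted Girvan–Newman usage.
    """
    G = network if isinstance(network, nx.Graph) else network.graph
    labels = partition.labels if isinstance(partition, CommunityPartition) else np.asarray(partition)
    if len(labels) != G.number_of_nodes():
        raise NetworkError("partition does not cover the node set")
    w = (lambda d: float(d.get("weight", 1.0))) if weighted else (lambda d: 1.0)
    m = sum(w(d) for _, _, d in G.edges(data=True))
    if m == 0:
        raise NetworkError("modularity undefined on an edgeless graph")
    e = {}
    deg = {}
    for u, v, d in G.edges(data=True):
        wt = w(d)
        cu, cv = labels[u], labels[v]
        deg[cu] = deg.get(cu, 0.0) + wt
        deg[cv] = deg.get(cv, 0.0) + wt
        if cu == cv:
            e[cu] = e.get(cu, 0.0) + wt
    q = 0.0
    for c in set(labels.tolist()):
        q += e.get(c, 0.0) / m - (deg.get(c, 0.0) / (2.0 * m)) ** 2
    return q


def _max_betweenness_edge(G: nx.Graph, use_weights: bool) -> tuple[int, int]:
    """Edge of maximal betweenness; ties broken lexicographically."""
    bw = nx.edge_betweenness_centrality(
        G, weight="weight" if use_weights else None, normalized=False
    )
    best = max(bw.values())
    candidates = [
        tuple(sorted(e)) for e, b in bw.items() if b >= best - 1e-12
    ]
    return min(candidates)


def girvan_newman(
    network: ContactNetwork | ConsensusNetwork,
    use_weights: bool = False,
    stop_delta_q: float = 0.001,
) -> CommunityPartition:
    """Divisive community detection with a modularity stopping rule.

    Edges of maximal betweenness are removed one at a time (recomputing
    betweenness after every removal).  Whenever a removal splits a
    component, the partition and its modularity Q — always evaluated on
    the *original* graph — are recorded.  Subdivision stops as soon as a
    newly recorded partition improves Q by less than ``stop_delta_q``
    over the previously recorded one; the best-Q partition recorded up
    to that point is returned.  Among equal-betweenness edges the
    lexicographically smallest node pair is removed, making the result
    deterministic.
    """
    G0 = network.graph
    n = G0.number_of_nodes()
    if n == 0 or G0.number_of_edges() == 0:
        raise NetworkError("cannot partition an empty network")
    work = G0.copy()

    labels = _labels_from_components(work, n)
    trace: list[tuple[np.ndarray, float]] = [(labels, modularity(G0, labels, weighted=False))]
    n_comp = len(np.unique(labels))

    stopped = False
    while work.number_of_edges() > 0 and not stopped:
        u, v = _max_betweenness_edge(work, use_weights)
        work.remove_edge(u, v)
        labels = _labels_from_components(work, n)
        k = len(np.unique(labels))
        if k > n_comp:
            n_comp = k
            q = modularity(G0, labels, weighted=False)
            improvement = q - trace[-1][1]
            trace.append((labels, q))
            if improvement < stop_delta_q:
                stopped = True

    best_labels, best_q = max(trace, key=lambda t: t[1])
    # canonical labels: communities numbered by their smallest member
    order = {}
    canon = np.empty(n, dtype=int)
    for node in range(n):
        c = best_labels[node]
        if c not in order:
            order[c] = len(order)
        canon[node] = order[c]
    return CommunityPartition(labels=canon, modularity=best_q, trace=trace)


def difference_network(
    consensus: ConsensusNetwork, state_a: str, state_b: str
) -> DifferenceNetwork:
    """Edgewise ΔP = P(state_b) − P(state_a) on the consensus edges.

    Positive ΔP means the contact is *gained* during the a→b transition.
    """
    for s in (state_a, state_b):
        if s not in consensus.states:
            raise NetworkError(f"state {s!r} not in consensus ({consensus.states})")
    G = nx.Graph()
    G.add_nodes_from(consensus.graph.nodes)
    for u, v, d in consensus.graph.edges(data=True):
        delta = d[f"p_{state_b}"] - d[f"p_{state_a}"]
        G.add_edge(u, v, delta=float(delta))
    return DifferenceNetwork(
        graph=G, node_table=consensus.node_table, state_a=state_a, state_b=state_b
    )


def community_delta(
    diff: DifferenceNetwork, partition: CommunityPartition
) -> CommunityDeltaMatrix:
    """Aggregate edge ΔP into a community-pair matrix.

    Entry (A, B) sums ΔP over consensus edges spanning communities A and
    B; the diagonal holds within-community sums.  The grand total over
    the upper triangle plus diagonal equals the total edge ΔP, so no
    probability change is lost or double counted.
    """
    labels = partition.labels
    if len(labels) != diff.graph.number_of_nodes():
        raise NetworkError("partition does not cover the difference network")
    comm_ids = np.unique(labels)
    pos = {c: k for k, c in enumerate(comm_ids)}
    K = len(comm_ids)
    M = np.zeros((K, K))
    for u, v, d in diff.graph.edges(data=True):
        a, b = pos[labels[u]], pos[labels[v]]
        if a == b:
            M[a, a] += d["delta"]
        else:
            M[a, b] += d["delta"]
            M[b, a] += d["delta"]
    sizes = np.array([(labels == c).sum() for c in comm_ids])
    return CommunityDeltaMatrix(
        delta=M, community_ids=comm_ids, sizes=sizes, transition=diff.transition
    )


def top_changed_residues(
    diff: DifferenceNetwork,
    k: int | None = None,
    min_abs_delta: float | None = None,
) -> pd.DataFrame:
    """Residues with the largest net gain/loss of contact probability.

    Each node's aggregate is the signed sum of ΔP over its incident
    consensus edges; nodes are ranked by |aggregate| (sign retained to
    distinguish gain from loss), ties broken by (chain, residue number).
    """
    if diff.graph.number_of_edges() == 0:
        raise NetworkError("difference network has no edges")
    n = diff.graph.number_of_nodes()
    agg = np.zeros(n)
    for u, v, d in diff.graph.edges(data=True):
        agg[u] += d["delta"]
        agg[v] += d["delta"]
    df = diff.node_table.df.copy()
    df["aggregate_delta_p"] = agg
    df["direction"] = np.where(agg > 0, "gain", np.where(agg < 0, "loss", "none"))
    df = df.sort_values(
        by=["aggregate_delta_p", "chain_id", "residue_number"],
        key=lambda s: -s.abs() if s.name == "aggregate_delta_p" else s,
        kind="stable",
    ).reset_index(drop=True)
    if min_abs_delta is not None:
        df = df[df["aggregate_delta_p"].abs() >= min_abs_delta].reset_index(drop=True)
    if k is not None:
        df = df.head(k)
    return df
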