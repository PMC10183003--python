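"""Independent oracles and small builders shared across the test suite.

The oracles here are deliberately naive (triple loops, exhaustive
enumeration) and never call the code paths they check.
"""

from __future__ import annotations

import numpy as np
import networkx as nx
import pandas as pd

from dcnatools.ensemble_io import Ensemble, NodeTable


def make_node_table(n: int, chain_size: int | None = None) -> NodeTable:
    """n protein nodes; one chain, or chains of ``chain_size`` nodes."""
    rows = []
    for i in range(n):
        if chain_size:
            chain = chr(ord("A") + i // chain_size)
            resnum = i % chain_size + 1
        else:
            chain = "A"
            resnum = i + 1
        rows.append(
            {
                "chain_id": chain,
                "residue_number": resnum,
                "insertion_code": "",
                "residue_name": "ALA",
                "node_kind": "protein",
                "representative_atom": "CA",
            }
        )
    df = pd.DataFrame(rows)
    df.insert(0, "node_index", np.arange(n))
    return NodeTable(df)


def make_ensemble(coords: np.ndarray, chain_size: int | None = None, heavy=False) -> Ensemble:
    """Wrap an (F, N, 3) array; optionally duplicate atoms as a heavy layer."""
    coords = np.asarray(coords, dtype=float)
    F, N, _ = coords.shape
    nt = make_node_table(N, chain_size)
    if heavy:
        heavy_coords = np.repeat(coords, 2, axis=1)
        heavy_coords[:, 1::2, :] += 0.05
        return Ensemble(
            node_table=nt,
            rep_coords=coords,
            state_label="test",
            heavy_coords=heavy_coords,
            atom_node=np.repeat(np.arange(N), 2),
            heavy_atom_names=["CA", "CB"] * N,
        )
    return Ensemble(node_table=nt, rep_coords=coords, state_label="test")


# ---------------------------------------------------------------------------
# brute-force contact oracle


def brute_force_contact_probability(ens: Ensemble, cutoff: float, exclusion: int, geometry: str) -> np.ndarray:
    """Frame-by-frame, pair-by-pair minimum-distance scan."""
    N = ens.n_nodes
    F = ens.n_frames
    P = np.zeros((N, N))
    chains = ens.node_table.df["chain_id"].to_list()
    resnums = ens.node_table.df["residue_number"].to_list()
    for i in range(N):
        for j in range(N):
            if i == j:
                continue
            if chains[i] == chains[j] and abs(resnums[i] - resnums[j]) <= exclusion:
                continue
            hits = 0
            for f in range(F):
                if geometry == "representative":
                    dmin = np.linalg.norm(ens.rep_coords[f, i] - ens.rep_coords[f, j])
                else:
                    ai = np.flatnonzero(ens.atom_node == i)
                    aj = np.flatnonzero(ens.atom_node == j)
                    dmin = min(
                        np.linalg.norm(ens.heavy_coords[f, a] - ens.heavy_coords[f, b])
                        for a in ai
                        for b in aj
                    )
                if dmin <= cutoff:
                    hits += 1
            P[i, j] = hits / F
    return P


# ---------------------------------------------------------------------------
# modularity oracles


def set_partitions(items: list[int]):
    """All partitions of a list (Bell-number enumeration)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for smaller in set_partitions(rest):
        for k in range(len(smaller)):
            yield smaller[:k] + [[first] + smaller[k]] + smaller[k + 1 :]
        yield [[first]] + smaller


def labels_from_blocks(blocks: list[list[int]], n: int) -> np.ndarray:
    labels = np.empty(n, dtype=int)
    for c, block in enumerate(blocks):
        for node in block:
            labels[node] = c
    return labels


def nx_modularity(G: nx.Graph, labels: np.ndarray) -> float:
    """networkx's own Newman–Girvan modularity (independent of ours)."""
    comms = {}
    for node, lab in enumerate(labels):
        comms.setdefault(lab, set()).add(node)
    return nx.algorithms.community.modularity(G, comms.values(), weight=None)


def exhaustive_max_modularity(G: nx.Graph) -> float:
    """Maximum Q over every partition of the node set."""
    n = G.number_of_nodes()
    best = -np.inf
    for blocks in set_partitions(list(range(n))):
        q = nx_modularity(G, labels_from_blocks(blocks, n))
        best = max(best, q)
    return best


def random_connected_graph(n: int, seed: int, p: float = 0.45) -> nx.Graph:
    rng = np.random.default_rng(seed)
    while True:
        G = nx.Graph()
        G.add_nodes_from(range(n))
        for i in range(n):
            for j in range(i + 1, n):
                if rng.random() < p:
                    G.add_edge(i, j)
        if G.number_of_edges() and nx.is_connected(G):
            return G
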