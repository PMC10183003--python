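"""Plain-text serialization of pipeline objects.

Everything the pipeline produces is written as TSV/GraphML/JSON keyed by
``chain:resnum`` residue identifiers (author numbering), so outputs load
into spreadsheets, molecular viewers and downstream scripts without this
package.  The loaders reconstruct the in-memory objects, which lets CLI
stages run independently of each other.
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .community_networks import CommunityPartition, ConsensusNetwork, ContactNetwork
from .contact_dynamics import ContactProbabilityMatrix
from .ensemble_io import NodeTable
from .errors import FormatError

NODE_COLUMNS = [
    "node_index", "chain_id", "residue_number", "insertion_code",
    "residue_name", "node_kind", "representative_atom",
]


def save_node_table(node_table: NodeTable, path: str | Path) -> None:
    node_table.df.to_csv(path, sep="\t", index=False)


def load_node_table(path: str | Path) -> NodeTable:
    df = pd.read_csv(
        path, sep="\t", dtype={"chain_id": str, "insertion_code": str}, keep_default_na=False
    )
    missing = [c for c in NODE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing node columns {missing}")
    df["residue_number"] = df["residue_number"].astype(int)
    df["node_index"] = df["node_index"].astype(int)
    return NodeTable(df[NODE_COLUMNS])


def save_contact_matrix(P: ContactProbabilityMatrix, directory: str | Path) -> None:
    """Write nodes.tsv + contact_p.tsv (+ a small meta.json) to a directory."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    save_node_table(P.node_table, directory / "nodes.tsv")
    keys = P.node_table.keys()
    pd.DataFrame(P.P, index=keys, columns=keys).to_csv(
        directory / "contact_p.tsv", sep="\t", float_format="%.10g"
    )
    (directory / "meta.json").write_text(
        json.dumps(
            {
                "state_label": P.state_label,
                "cutoff": P.cutoff,
                "exclusion": P.exclusion,
                "geometry": P.geometry,
            },
            indent=2,
        )
    )


def load_contact_matrix(directory: str | Path) -> ContactProbabilityMatrix:
    directory = Path(directory)
    node_table = load_node_table(directory / "nodes.tsv")
    mat = pd.read_csv(directory / "contact_p.tsv", sep="\t", index_col=0)
    meta = json.loads((directory / "meta.json").read_text())
    P = mat.to_numpy(dtype=float)
    P = (P + P.T) / 2.0
    np.fill_diagonal(P, 0.0)
    return ContactProbabilityMatrix(
        P=P,
        cutoff=float(meta["cutoff"]),
        exclusion=int(meta["exclusion"]),
        state_label=str(meta["state_label"]),
        node_table=node_table,
        geometry=str(meta.get("geometry", "heavy")),
    )


def _edge_frame(graph: nx.Graph, node_table: NodeTable) -> pd.DataFrame:
    keys = node_table.keys()
    rows = []
    for u, v, d in sorted(graph.edges(data=True)):
        row = {"node_a": keys[u], "node_b": keys[v]}
        row.update({k: float(val) for k, val in d.items()})
        rows.append(row)
    return pd.DataFrame(rows)


def save_network(net: ContactNetwork | ConsensusNetwork, directory: str | Path, name: str = "network") -> None:
    """Weighted edge-list TSV plus GraphML export."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    save_node_table(net.node_table, directory / "nodes.tsv")
    _edge_frame(net.graph, net.node_table).to_csv(
        directory / f"{name}_edges.tsv", sep="\t", index=False, float_format="%.10g"
    )
    G = nx.relabel_nodes(net.graph, dict(enumerate(net.node_table.keys())), copy=True)
    nx.write_graphml(G, directory / f"{name}.graphml")


def save_consensus(net: ConsensusNetwork, directory: str | Path) -> None:
    directory = Path(directory)
    save_network(net, directory, name="consensus")
    (directory / "consensus_meta.json").write_text(
        json.dumps(
            {
                "states": net.states,
                "stability_min_probability": net.stability_min_probability,
                "dropped_nodes": net.dropped_nodes,
            },
            indent=2,
        )
    )


def load_consensus(directory: str | Path) -> ConsensusNetwork:
    directory = Path(directory)
    node_table = load_node_table(directory / "nodes.tsv")
    meta = json.loads((directory / "consensus_meta.json").read_text())
    edges = pd.read_csv(directory / "consensus_edges.tsv", sep="\t")
    index = {k: i for i, k in enumerate(node_table.keys())}
    G = nx.Graph()
    G.add_nodes_from(range(len(node_table)))
    pcols = [c for c in edges.columns if c.startswith("p_")]
    for row in edges.itertuples(index=False):
        attrs = {c: float(getattr(row, c)) for c in pcols}
        G.add_edge(index[row.node_a], index[row.node_b], weight=1.0, **attrs)
    return ConsensusNetwork(
        graph=G,
        node_table=node_table,
        states=list(meta["states"]),
        stability_min_probability=float(meta["stability_min_probability"]),
        dropped_nodes=list(meta["dropped_nodes"]),
    )


def save_partition(
    partition: CommunityPartition, node_table: NodeTable, directory: str | Path
) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {"node": node_table.keys(), "community": partition.labels}
    ).to_csv(directory / "partition.tsv", sep="\t", index=False)
    sizes = {
        int(c): int((partition.labels == c).sum()) for c in np.unique(partition.labels)
    }
    (directory / "partition.json").write_text(
        json.dumps(
            {
                "n_communities": partition.n_communities,
                "modularity": partition.modularity,
                "sizes": sizes,
                "trace_q": [float(q) for _, q in partition.trace],
            },
            indent=2,
        )
    )


def load_partition(directory: str | Path, node_table: NodeTable) -> CommunityPartition:
    directory = Path(directory)
    df = pd.read_csv(directory / "partition.tsv", sep="\t")
    order = {k: i for i, k in enumerate(node_table.keys())}
    labels = np.empty(len(node_table), dtype=int)
    for row in df.itertuples(index=False):
        labels[order[row.node]] = int(row.community)
    meta = json.loads((directory / "partition.json").read_text())
    return CommunityPartition(labels=labels, modularity=float(meta["modularity"]))


def save_delta_matrix(delta, directory: str | Path) -> None:
    """Community-pair ΔP matrix as TSV with ids and sizes."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    ids = [f"community_{c}" for c in delta.community_ids]
    df = pd.DataFrame(delta.delta, index=ids, columns=ids)
    df.insert(0, "size", delta.sizes)
    df.to_csv(directory / "community_delta.tsv", sep="\t", float_format="%.10g")
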