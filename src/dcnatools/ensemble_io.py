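"""Topology and trajectory I/O for residue-level network analysis.

The pipeline works on a *node-centric* view of a macromolecular assembly:
one node per residue, represented by its Cα atom (protein) or P atom
(nucleic acid).  This module parses PDB topologies into a
:class:`NodeTable`, loads trajectory ensembles (DCD, XTC or multi-model
PDB) into an :class:`Ensemble` holding representative-atom and heavy-atom
coordinate stacks in Å, performs rigid-body superposition, and writes
per-node scalars (B-factors, community labels) back into PDB files for
molecular-viewer coloring.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import (
    EmptyModelError,
    EnsembleError,
    FormatError,
    MappingError,
    TopologyError,
)

logger = logging.getLogger(__name__)

@dataclass(frozen=True)
class NodeTable:
    """One row per network node (residue with a representative atom).

    The underlying frame has columns ``node_index``, ``chain_id``,
    ``residue_number`` (author numbering), ``insertion_code``,
    ``residue_name``, ``node_kind`` (``protein``/``nucleic``) and
    ``representative_atom``.  Node indices are contiguous ``0..N-1`` in
    (chain, residue number, insertion code) order.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        expected = np.arange(len(self.df))
        if not np.array_equal(self.df["node_index"].to_numpy(), expected):
            raise ValueError("node_index must be contiguous 0..N-1")
        keys = list(
            zip(self.df["chain_id"], self.df["residue_number"], self.df["insertion_code"])
        )
        if len(set(keys)) != len(keys):
            raise ValueError("(chain_id, residue_number, insertion_code) must be unique")

    def __len__(self) -> int:
        return len(self.df)

    def keys(self) -> list[str]:
        """Human-readable ``chain:resnum`` keys, in node order."""
        return [
            f"{c}:{r}{i}".rstrip()
            for c, r, i in zip(
                self.df["chain_id"], self.df["residue_number"], self.df["insertion_code"]
            )
        ]

    def lookup(self, chain_id: str, residue_number: int, insertion_code: str = "") -> int:
        """Node index for an author-numbered residue; KeyError if absent."""
        mask = (
            (self.df["chain_id"] == chain_id)
            & (self.df["residue_number"] == int(residue_number))
            & (self.df["insertion_code"] == insertion_code)
        )
        hits = self.df.index[mask]
        if len(hits) == 0:
            raise KeyError(f"no node {chain_id}:{residue_number}{insertion_code}")
        return int(self.df.loc[hits[0], "node_index"])

    def same_nodes(self, other: "NodeTable") -> bool:
        cols = ["chain_id", "residue_number", "insertion_code"]
        return len(self) == len(other) and bool(
            (self.df[cols].to_numpy() == other.df[cols].to_numpy()).all()
        )


@dataclass
class Ensemble:
    """A conformational ensemble of one functional state.

    ``rep_coords`` holds representative-atom positions, shape (F, N, 3),
    in Å.  ``heavy_coords`` optionally holds all heavy atoms (F, A, 3)
    with ``atom_node`` mapping each atom column to its node, so that
    heavy-atom contact geometry stays computable.
    """

    node_table: NodeTable
    rep_coords: np.ndarray
    state_label: str = ""
    heavy_coords: np.ndarray | None = None
    atom_node: np.ndarray | None = None
    heavy_atom_names: list[str] | None = None

    @property
    def n_frames(self) -> int:
        return int(self.rep_coords.shape[0])

    @property
    def n_nodes(self) -> int:
        return int(self.rep_coords.shape[1])

    def validate(self) -> None:
        if self.rep_coords.ndim != 3 or self.rep_coords.shape[2] != 3:
            raise EnsembleError("rep_coords must have shape (F, N, 3)")
        if self.rep_coords.shape[1] != len(self.node_table):
            raise EnsembleError("rep_coords node dimension does not match node table")
        if not np.isfinite(self.rep_coords).all():
            raise EnsembleError("rep_coords contain non-finite values")
        if self.heavy_coords is not None:
            if self.atom_node is None or len(self.atom_node) != self.heavy_coords.shape[1]:
                raise EnsembleError("heavy_coords require a matching atom_node map")


def _is_hydrogen(atom_name: str, element: str | None) -> bool:
    if element:
        return element.strip().upper() == "H"
    name = atom_name.strip()
    return bool(name) and (name[0] == "H" or (name[0].isdigit() and len(name) > 1 and name[1] == "H"))


def _representative_atom(residue) -> tuple[str, str] | None:
    """Return (atom_name, node_kind) for a Biopython residue, or None.

    Any residue containing a Cα is treated as protein; otherwise a
    residue with a P atom (nucleotide) is nucleic.  Residues with
    neither — waters, ions, 5'-terminal nucleotides missing P — yield no
    node.
    """
    names = {a.get_name() for a in residue.get_unpacked_list()}
    if "CA" in names:
        return "CA", "protein"
    if "P" in names:
        return "P", "nucleic"
    return None


def load_topology(path: str | Path) -> NodeTable:
    """Parse a PDB topology into a :class:`NodeTable`.

    One node is created per residue that carries its representative atom
    (Cα for amino acids, P for nucleotides).  Residues lacking it — for
    example the 5'-terminal nucleotide of a chain, or waters and ions —
    are skipped and logged.  Only altloc '' or 'A' positions are kept.
    """
    from Bio.PDB import PDBParser
    from Bio.PDB.PDBExceptions import PDBConstructionException

    path = Path(path)
    parser = PDBParser(QUIET=True)
    try:
        structure = parser.get_structure("topology", str(path))
    except (PDBConstructionException, ValueError, OSError) as exc:
        raise FormatError(f"cannot parse PDB file {path}: {exc}") from exc
    models = list(structure.get_models())
    if not models:
        raise FormatError(f"{path} contains no coordinate models")
    model = models[0]

    rows = []
    n_skipped = 0
    for chain in model:
        for residue in chain:
            rep = _representative_atom(residue)
            hetflag, resseq, icode = residue.get_id()
            if rep is None:
                n_skipped += 1
                logger.info(
                    "skipping residue %s %s%s%s: no representative atom",
                    residue.get_resname(), chain.id, resseq, icode.strip(),
                )
                continue
            atom_name, kind = rep
            rows.append(
                {
                    "chain_id": chain.id,
                    "residue_number": int(resseq),
                    "insertion_code": icode.strip(),
                    "residue_name": residue.get_resname().strip(),
                    "node_kind": kind,
                    "representative_atom": atom_name,
                }
            )
    if not rows:
        raise EmptyModelError(f"{path}: no residue has a representative atom")
    if n_skipped:
        logger.info("%s: skipped %d residues without representative atoms", path, n_skipped)
    df = (
        pd.DataFrame(rows)
        .sort_values(["chain_id", "residue_number", "insertion_code"], kind="stable")
        .reset_index(drop=True)
    )
    df.insert(0, "node_index", np.arange(len(df)))
    return NodeTable(df)


def _mdtraj_atom_maps(topology, node_table: NodeTable):
    """Match an mdtraj topology against a NodeTable.

    Returns (rep_atom_indices[N], heavy_atom_indices[A], atom_node[A],
    heavy_names[A]).  Residues are matched by (chain_id, residue number);
    every node must be present in the trajectory topology.
    """
    dup = node_table.df.duplicated(["chain_id", "residue_number"]).any()
    if dup:
        raise TopologyError(
            "topology has residues distinguished only by insertion code; "
            "trajectory formats cannot represent those — renumber first"
        )
    by_key = {
        (c, r): i
        for i, (c, r) in enumerate(
            zip(node_table.df["chain_id"], node_table.df["residue_number"])
        )
    }
    rep_names = node_table.df["representative_atom"].to_list()
    rep_idx = np.full(len(node_table), -1, dtype=int)
    heavy_idx: list[int] = []
    heavy_node: list[int] = []
    heavy_names: list[str] = []
    for res in topology.residues:
        key = (res.chain.chain_id, int(res.resSeq))
        node = by_key.get(key)
        if node is None:
            continue
        for atom in res.atoms:
            elem = atom.element.symbol if atom.element is not None else None
            if _is_hydrogen(atom.name, elem):
                continue
            heavy_idx.append(atom.index)
            heavy_node.append(node)
            heavy_names.append(atom.name)
            if atom.name == rep_names[node]:
                rep_idx[node] = atom.index
    missing = np.flatnonzero(rep_idx < 0)
    if len(missing):
        keys = [node_table.keys()[i] for i in missing[:5]]
        raise TopologyError(
            f"{len(missing)} topology nodes missing from trajectory (e.g. {keys})"
        )
    return rep_idx, np.asarray(heavy_idx), np.asarray(heavy_node), heavy_names


def load_ensemble(
    node_table: NodeTable,
    trajectory_paths: Sequence[str | Path],
    stride: int = 1,
    state_label: str = "",
    topology: str | Path | None = None,
) -> Ensemble:
    """Load one or more trajectory files into an :class:`Ensemble`.

    Frames are concatenated across files in the given order, then
    subsampled by ``stride``.  ``topology`` (a PDB path) is required for
    coordinate-only formats (DCD/XTC); multi-model PDB files carry their
    own topology.  Coordinates are returned in Å.
    """
    import mdtraj as md

    if stride < 1:
        raise EnsembleError(f"stride must be >= 1, got {stride}")
    if not trajectory_paths:
        raise EnsembleError("no trajectory files given")

    parts = []
    for p in trajectory_paths:
        p = Path(p)
        try:
            if p.suffix.lower() in {".pdb", ".ent"}:
                traj = md.load(str(p))
            else:
                if topology is None:
                    raise TopologyError(f"{p}: coordinate-only format needs a topology PDB")
                traj = md.load(str(p), top=str(topology))
        except (OSError, ValueError, IOError) as exc:
            raise FormatError(f"cannot read trajectory {p}: {exc}") from exc
        parts.append(traj)
    n_atoms = {t.n_atoms for t in parts}
    if len(n_atoms) != 1:
        raise TopologyError(f"trajectory files disagree on atom count: {sorted(n_atoms)}")
    traj = parts[0] if len(parts) == 1 else md.join(parts)
    traj = traj[::stride]
    if traj.n_frames == 0:
        raise EnsembleError("zero frames left after striding")

    rep_idx, heavy_idx, atom_node, heavy_names = _mdtraj_atom_maps(traj.topology, node_table)
    xyz = np.asarray(traj.xyz, dtype=np.float64) * 10.0  # nm -> Å
    ens = Ensemble(
        node_table=node_table,
        rep_coords=xyz[:, rep_idx, :].copy(),
        state_label=state_label,
        heavy_coords=xyz[:, heavy_idx, :].copy(),
        atom_node=atom_node,
        heavy_atom_names=heavy_names,
    )
    ens.validate()
    return ens


# ---------------------------------------------------------------------------
# superposition


def kabsch(mobile: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Optimal rigid-body fit of ``mobile`` onto ``target`` (rows = points).

    Returns (R, t) such that ``mobile @ R + t`` minimizes the RMSD to
    ``target``.  Rotation only — no scaling, no reflection.
    """
    mobile = np.asarray(mobile, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    mu_m = mobile.mean(axis=0)
    mu_t = target.mean(axis=0)
    H = (mobile - mu_m).T @ (target - mu_t)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(U @ Vt))
    D = np.diag([1.0, 1.0, d])
    R = U @ D @ Vt
    t = mu_t - mu_m @ R
    return R, t


def superpose(
    ensemble: Ensemble,
    reference: int | str = 0,
    fit_nodes: Iterable[int] | None = None,
    max_iter: int = 100,
    tol: float = 1e-10,
) -> Ensemble:
    """Least-squares superpose all frames, removing global rigid motion.

    With an integer ``reference`` (default frame 0) each frame is fitted
    once onto that frame; this is exactly idempotent, since an already
    optimally aligned frame yields the identity transform.  With
    ``reference='mean'`` the frames are fitted iteratively onto the
    evolving ensemble-average structure until the mean converges — the
    fit used before B-factor and PCA analysis, which converges rapidly
    for ensembles with a well-defined average structure.  Heavy atoms
    are carried along by the same rigid motions.
    """
    fit = (
        np.arange(ensemble.n_nodes)
        if fit_nodes is None
        else np.asarray(sorted(set(int(i) for i in fit_nodes)))
    )
    if len(fit) < 3:
        raise EnsembleError("superposition needs at least 3 fit nodes")
    if len(fit) and (fit.min() < 0 or fit.max() >= ensemble.n_nodes):
        raise EnsembleError("fit_nodes out of range")

    rep = ensemble.rep_coords.astype(np.float64).copy()
    heavy = None if ensemble.heavy_coords is None else ensemble.heavy_coords.astype(np.float64).copy()

    def _fit_all(target: np.ndarray) -> float:
        moved = 0.0
        for f in range(rep.shape[0]):
            R, t = kabsch(rep[f, fit], target)
            new = rep[f] @ R + t
            moved = max(moved, float(np.abs(new - rep[f]).max()))
            rep[f] = new
            if heavy is not None:
                heavy[f] = heavy[f] @ R + t
        return moved

    if reference == "mean":
        target = rep[:, fit].mean(axis=0)
        for _ in range(max_iter):
            moved = _fit_all(target)
            target = rep[:, fit].mean(axis=0)
            if moved < tol:
                break
    else:
        ref = int(reference)
        if not (0 <= ref < ensemble.n_frames):
            raise EnsembleError(f"reference frame {ref} out of range")
        _fit_all(rep[ref, fit].copy())

    return replace(ensemble, rep_coords=rep, heavy_coords=heavy)


# ---------------------------------------------------------------------------
# annotated PDB output


def write_annotated_pdb(
    node_table: NodeTable,
    per_node_values: Sequence[float] | np.ndarray,
    template: str | Path,
    out_path: str | Path,
    field: str = "bfactor",
) -> None:
    """Write a copy of ``template`` with per-node values in the B column.

    Every atom of a residue receives its node's value, formatted to two
    decimals and clipped to the PDB column range [0, 999.99]; all other
    bytes of the atom records are preserved.  ``field`` is a label only
    ('bfactor' or 'community') — both use the B-factor column, which is
    how molecular viewers color by arbitrary per-residue scalars.
    """
    values = np.asarray(per_node_values, dtype=np.float64)
    if values.shape != (len(node_table),):
        raise MappingError(
            f"need exactly one value per node ({len(node_table)}), got shape {values.shape}"
        )
    if field not in {"bfactor", "community"}:
        raise MappingError(f"unknown annotation field {field!r}")
    clipped = np.clip(values, 0.0, 999.99)
    if (clipped != values).any():
        warnings.warn("values outside [0, 999.99] clipped for PDB B-factor column")

    lookup: dict[tuple[str, int, str], float] = {}
    for row, v in zip(node_table.df.itertuples(index=False), clipped):
        lookup[(row.chain_id, row.residue_number, row.insertion_code)] = float(v)
    seen: set[tuple[str, int, str]] = set()

    out_lines = []
    with open(template) as fh:
        for line in fh:
            rec = line[:6]
            if rec in ("ATOM  ", "HETATM") and len(line.rstrip("\n")) >= 54:
                chain = line[21]
                try:
                    resseq = int(line[22:26])
                except ValueError as exc:
                    raise FormatError(f"bad residue number field: {line.rstrip()}") from exc
                icode = line[26].strip()
                key = (chain, resseq, icode)
                if key in lookup:
                    seen.add(key)
                    body = line.rstrip("\n").ljust(66)
                    line = body[:60] + f"{lookup[key]:6.2f}" + body[66:] + "\n"
            out_lines.append(line)
    if len(seen) != len(lookup):
        missing = sorted(set(lookup) - seen)[:5]
        raise MappingError(f"{len(lookup) - len(seen)} nodes absent from template (e.g. {missing})")
    Path(out_path).write_text("".join(out_lines))


def write_multimodel_pdb(ensemble: Ensemble, out_path: str | Path) -> None:
    """Serialize an ensemble as a multi-model PDB (heavy atoms).

    This is the round-trip format of the synthetic generator: the file
    doubles as topology and trajectory for :func:`load_topology` /
    :func:`load_ensemble`.
    """
    if ensemble.heavy_coords is None:
        coords = ensemble.rep_coords
        atom_node = np.arange(ensemble.n_nodes)
        names = ensemble.node_table.df["representative_atom"].to_list()
    else:
        coords = ensemble.heavy_coords
        atom_node = ensemble.atom_node
        names = ensemble.heavy_atom_names or ["CA"] * coords.shape[1]
    df = ensemble.node_table.df
    lines = []
    for f in range(coords.shape[0]):
        lines.append(f"MODEL     {f + 1:4d}\n")
        for a, node in enumerate(atom_node):
            row = df.iloc[int(node)]
            x, y, z = coords[f, a]
            name = names[a]
            pad_name = f" {name:<3s}" if len(name) < 4 else name
            lines.append(
                f"ATOM  {a + 1:5d} {pad_name}{'':1s}{row.residue_name:>3s} "
                f"{row.chain_id:1s}{row.residue_number:4d}{row.insertion_code or ' ':1s}   "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
                f"{name[0]:>2s}\n"
            )
        lines.append("ENDMDL\n")
    lines.append("END\n")
    Path(out_path).write_text("".join(lines))
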