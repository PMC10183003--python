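"""Mapping disease mutations onto dynamic community interfaces.

Missense mutations are located on the residue network by (chain,
author residue number) and classified as *internal* — every network
contact of the residue stays inside its own dynamic community — or
*interfacial* — at least one contact crosses a community boundary.
Comparing classifications between functional states reveals mutations
that sit on boundaries only in one state, i.e. positions whose
functional impact is state-specific.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .community_networks import CommunityPartition, ConsensusNetwork, ContactNetwork
from .ensemble_io import NodeTable
from .errors import AlignmentError, FormatError

logger = logging.getLogger(__name__)

PHENOTYPES = {"XP", "TTD", "XP/CS", "XP/TTD"}

AA1 = set("ACDEFGHIKLMNPQRSTVWY")

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    "HSD": "H", "HSE": "H", "HSP": "H", "HIE": "H", "HID": "H",
}

REQUIRED_COLUMNS = ["subunit", "chain_id", "wild_type", "position", "mutant", "phenotype"]


@dataclass(frozen=True)
class MutationRecord:
    """One missense disease mutation in 1-letter / author numbering."""

    subunit: str
    chain_id: str
    wild_type: str
    position: int
    mutant: str
    phenotype: str
    note: str = ""

    @property
    def name(self) -> str:
        return f"{self.subunit} {self.wild_type}{self.position}{self.mutant}"


@dataclass
class InterfaceAssignment:
    """Community placement of one mutation in one functional state."""

    record: MutationRecord
    state_label: str
    resolved: bool
    community: int | None = None
    classification: str | None = None  # 'internal' | 'interfacial'
    partners: frozenset[tuple[int, int]] = frozenset()
    n_foreign_contacts: int = 0


def load_mutations(path: str | Path, node_table: NodeTable | None = None) -> list[MutationRecord]:
    """Read a mutation annotation TSV.

    Required columns: subunit, chain_id, wild_type, position, mutant,
    phenotype; an optional free-text ``note`` column is carried along.
    When a topology is supplied, the wild-type letter is cross-checked
    against the residue name there; disagreements are kept but logged.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    except (pd.errors.ParserError, OSError) as exc:
        raise FormatError(f"cannot parse mutation table {path}: {exc}") from exc
    if df.empty:
        logger.warning("%s: empty mutation table", path)
        return []
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")

    records = []
    for lineno, row in enumerate(df.itertuples(index=False), start=2):
        try:
            wt = str(row.wild_type).strip().upper()
            mut = str(row.mutant).strip().upper()
            pos = int(str(row.position).strip())
            phenotype = str(row.phenotype).strip()
        except (ValueError, TypeError) as exc:
            raise FormatError(f"{path} line {lineno}: malformed row ({exc})") from exc
        if wt not in AA1 or mut not in AA1:
            raise FormatError(
                f"{path} line {lineno}: invalid residue letters {wt!r}/{mut!r}"
            )
        if phenotype not in PHENOTYPES:
            raise FormatError(
                f"{path} line {lineno}: phenotype {phenotype!r} not in {sorted(PHENOTYPES)}"
            )
        rec = MutationRecord(
            subunit=str(row.subunit).strip(),
            chain_id=str(row.chain_id).strip(),
            wild_type=wt,
            position=pos,
            mutant=mut,
            phenotype=phenotype,
            note=str(getattr(row, "note", "") or ""),
        )
        if node_table is not None:
            try:
                node = node_table.lookup(rec.chain_id, rec.position)
                resname = node_table.df.loc[node, "residue_name"]
                expected = _THREE_TO_ONE.get(resname)
                if expected is not None and expected != wt:
                    logger.warning(
                        "%s: wild type %s disagrees with topology residue %s at %s:%d",
                        rec.name, wt, resname, rec.chain_id, rec.position,
                    )
            except KeyError:
                logger.warning("%s: position not resolvable in topology", rec.name)
        records.append(rec)
    return records


def classify_interfacial(
    record: MutationRecord,
    partition: CommunityPartition,
    network: ContactNetwork | ConsensusNetwork,
    state_label: str = "",
) -> InterfaceAssignment:
    """Classify one mutation as internal or interfacial.

    A mutation is interfacial iff its node has at least one network edge
    into a different community; the partner set lists the crossed
    community pairs.  Unresolvable positions yield an unresolved
    assignment rather than an exception, so a run-level report can list
    them.
    """
    state = state_label or getattr(network, "state_label", "")
    try:
        node = network.node_table.lookup(record.chain_id, record.position)
    except KeyError:
        return InterfaceAssignment(record=record, state_label=state, resolved=False)
    labels = partition.labels
    if len(labels) != network.graph.number_of_nodes():
        raise AlignmentError("partition does not cover the network node set")
    own = int(labels[node])
    partners = set()
    n_foreign = 0
    for nb in network.graph.neighbors(node):
        other = int(labels[nb])
        if other != own:
            n_foreign += 1
            partners.add((min(own, other), max(own, other)))
    return InterfaceAssignment(
        record=record,
        state_label=state,
        resolved=True,
        community=own,
        classification="interfacial" if partners else "internal",
        partners=frozenset(partners),
        n_foreign_contacts=n_foreign,
    )


def classify_all(
    records: list[MutationRecord],
    partition: CommunityPartition,
    network: ContactNetwork | ConsensusNetwork,
    state_label: str = "",
) -> list[InterfaceAssignment]:
    """Classify every record; unresolved ones are kept in the output."""
    out = [classify_interfacial(r, partition, network, state_label) for r in records]
    unresolved = [a.record.name for a in out if not a.resolved]
    if unresolved:
        logger.warning("%d unresolved mutations: %s", len(unresolved), unresolved)
    return out


def compare_states(
    assignments_a: list[InterfaceAssignment],
    assignments_b: list[InterfaceAssignment],
) -> pd.DataFrame:
    """Cross-state reclassification table.

    Both inputs must cover the same mutations in the same order.  The
    result has one row per mutation with its class in each state, the
    crossed community pairs, and a ``change`` column flagging
    internal→interfacial and interfacial→internal moves.
    """
    if len(assignments_a) != len(assignments_b) or any(
        a.record != b.record for a, b in zip(assignments_a, assignments_b)
    ):
        raise AlignmentError("assignment lists cover different mutations")
    rows = []
    for a, b in zip(assignments_a, assignments_b):
        ca = a.classification if a.resolved else "unresolved"
        cb = b.classification if b.resolved else "unresolved"
        if ca == cb:
            change = "unchanged"
        elif "unresolved" in (ca, cb):
            change = "unresolved"
        else:
            change = f"{ca}->{cb}"
        rows.append(
            {
                "mutation": a.record.name,
                "phenotype": a.record.phenotype,
                "state_a": a.state_label,
                "state_b": b.state_label,
                "class_a": ca,
                "class_b": cb,
                "partners_a": ";".join(f"{p}-{q}" for p, q in sorted(a.partners)),
                "partners_b": ";".join(f"{p}-{q}" for p, q in sorted(b.partners)),
                "change": change,
            }
        )
    return pd.DataFrame(rows)


def reclassification_summary(table: pd.DataFrame) -> dict:
    """Counts of internal→interfacial / interfacial→internal / unchanged."""
    counts = table["change"].value_counts().to_dict()
    return {
        "internal_to_interfacial": int(counts.get("internal->interfacial", 0)),
        "interfacial_to_internal": int(counts.get("interfacial->internal", 0)),
        "unchanged": int(counts.get("unchanged", 0)),
        "unresolved": int(counts.get("unresolved", 0)),
    }
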