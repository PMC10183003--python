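"""Synthetic multi-state ensembles with planted community structure.

Real microsecond MD trajectories of large assemblies are rarely
shareable, so the pipeline is validated on toy ensembles whose ground
truth is known by construction:

* K compact residue clusters ("communities"), one chain each, placed
  far apart; all intra-community pairs sit inside the contact cutoff,
  so communities are densely connected cliques in the contact network;
* designated *boundary* residue pairs between communities toggle, per
  frame, between a "near" geometry (inside the cutoff) and their home
  positions (outside it) with a planted Bernoulli probability — the
  empirical contact occupancy converges to that probability, and
  state-dependent probabilities plant ΔP changes of known sign;
* intra-community occupancies below 1 are realized by sending
  non-boundary nodes on rare "excursions" to distant parking spots with
  rate 1−√p, so an eligible pair is simultaneously home — and hence in
  contact — with probability p;
* each community is translated rigidly per frame by a shared random
  vector (correlated intra-community motion; per-state amplitude
  multipliers make chosen communities mobile), plus small independent
  per-node noise.

Random displacements are norm-clipped a little above their RMS so that
the planted contact geometry can never be crossed by jitter: planted
contacts are certain when toggled on and impossible when toggled off.
All randomness flows from one mandatory seed.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .ensemble_io import Ensemble, NodeTable
from .errors import SpecError

__all__ = [
    "PlantedSpec",
    "generate_state",
    "generate_transition_pair",
    "generate_mutation_fixture",
]

_NEAR_SEPARATION = 3.0  # Å between boundary partners in the "near" geometry
_HEAVY_OFFSET = 0.1  # Å offset of the second heavy atom from the Cα
_PARK_BASE = 150.0  # Å, z offset of the first excursion parking spot
_PARK_STEP = 8.0  # Å between parking spots


def _state_value(per_state, state_label: str, default):
    """Resolve a possibly per-state field ({state: value} or scalar)."""
    if isinstance(per_state, Mapping) and per_state and all(
        isinstance(k, str) for k in per_state
    ):
        return per_state.get(state_label, default)
    if per_state is None:
        return default
    return per_state


def _norm_pair(pair) -> tuple[int, int]:
    a, b = int(pair[0]), int(pair[1])
    if a == b:
        raise SpecError(f"community pair {pair} is not a pair")
    return (min(a, b), max(a, b))


@dataclass
class PlantedSpec:
    """Blueprint of a planted multi-state ensemble.

    ``inter_contact_p`` maps a state label to ``{(i, j): p}`` community
    pair probabilities (or is a single such dict shared by all states);
    ``intra_contact_p`` and ``mobile_communities`` may likewise be
    per-state.  ``seed`` is mandatory — every coordinate is derived from
    it.
    """

    n_communities: int
    nodes_per_community: int
    frames: int
    seed: int
    intra_contact_p: float | Mapping[str, float] = 1.0
    inter_contact_p: Mapping = field(default_factory=dict)
    centroid_spacing: float = 9.0
    node_radius: float = 1.0
    correlated_amplitude: float = 0.15
    noise: float = 0.05
    contact_cutoff: float = 4.5
    mobile_communities: Mapping = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_communities < 2:
            raise SpecError("need at least 2 communities")
        if self.frames < 10:
            raise SpecError("need at least 10 frames")
        if self.nodes_per_community < 2:
            raise SpecError("need at least 2 nodes per community")
        if self.seed is None:
            raise SpecError("seed is mandatory")
        # geometric feasibility: a cluster must fit inside the cutoff,
        # and the near/far toggle must straddle it with clearance
        if 2 * self.node_radius + 4 * self.noise + 2 * _HEAVY_OFFSET >= self.contact_cutoff:
            raise SpecError(
                f"intra-community spacing {2 * self.node_radius:.2f} Å does not fit "
                f"inside the {self.contact_cutoff} Å cutoff"
            )
        if _NEAR_SEPARATION >= self.contact_cutoff - 0.5:
            raise SpecError("near geometry too wide for the cutoff")
        gap = self.centroid_spacing - 2 * self.node_radius
        if gap <= self.contact_cutoff + 1.0:
            raise SpecError(
                f"centroid spacing {self.centroid_spacing} Å leaves clusters within "
                "contact range of each other"
            )

    # -- per-state resolution -------------------------------------------------

    def intra_p(self, state_label: str) -> float:
        p = float(_state_value(self.intra_contact_p, state_label, 1.0))
        if not (0.0 <= p <= 1.0):
            raise SpecError(f"intra_contact_p {p} outside [0, 1]")
        return p

    def inter_p(self, state_label: str) -> dict[tuple[int, int], float]:
        table = _state_value(self.inter_contact_p, state_label, {})
        out = {}
        for pair, p in (table or {}).items():
            pair = _norm_pair(pair)
            p = float(p)
            if not (0.0 <= p <= 1.0):
                raise SpecError(f"inter_contact_p {p} for pair {pair} outside [0, 1]")
            if max(pair) >= self.n_communities:
                raise SpecError(f"community pair {pair} out of range")
            out[pair] = p
        return out

    def designated_pairs(self) -> list[tuple[int, int]]:
        """Community pairs owning boundary nodes, identical in all states."""
        pairs = set()
        table = self.inter_contact_p
        if isinstance(table, Mapping) and table and all(isinstance(k, str) for k in table):
            for sub in table.values():
                pairs.update(_norm_pair(p) for p in (sub or {}))
        else:
            pairs.update(_norm_pair(p) for p in (table or {}))
        for pair in pairs:
            if max(pair) >= self.n_communities:
                raise SpecError(f"community pair {pair} out of range")
        return sorted(pairs)

    def amplitudes(self, state_label: str) -> np.ndarray:
        mob = _state_value(self.mobile_communities, state_label, {}) or {}
        amp = np.full(self.n_communities, self.correlated_amplitude)
        for k, mult in mob.items():
            k = int(k)
            if not (0 <= k < self.n_communities):
                raise SpecError(f"mobile community {k} out of range")
            amp[k] *= float(mult)
        return amp


# ---------------------------------------------------------------------------
# static geometry


def _centroids(spec: PlantedSpec) -> np.ndarray:
    """Community centres: regular simplex (K<=4) or cubic grid."""
    D = spec.centroid_spacing
    K = spec.n_communities
    if K <= 4:
        simplex = np.array(
            [
                [0.0, 0.0, 0.0],
                [1.0, 0.0, 0.0],
                [0.5, np.sqrt(3.0) / 2.0, 0.0],
                [0.5, np.sqrt(3.0) / 6.0, np.sqrt(2.0 / 3.0)],
            ]
        )
        return simplex[:K] * D
    side = int(np.ceil(K ** (1.0 / 3.0)))
    pts = [
        (x, y, z)
        for x in range(side)
        for y in range(side)
        for z in range(side)
    ][:K]
    cents = np.asarray(pts, dtype=float) * D
    for i, j in spec.designated_pairs():
        if not np.isclose(np.linalg.norm(cents[i] - cents[j]), D):
            raise SpecError(
                f"communities {i} and {j} are not adjacent in the grid layout; "
                "planted contacts require centroid spacing exactly one grid step"
            )
    return cents


def _boundary_nodes(spec: PlantedSpec) -> dict[tuple[int, int], tuple[int, int]]:
    """Assign one distinct local node per community per designated pair."""
    counters = [0] * spec.n_communities
    mapping = {}
    for pair in spec.designated_pairs():
        i, j = pair
        if counters[i] >= spec.nodes_per_community or counters[j] >= spec.nodes_per_community:
            raise SpecError(
                f"community of {spec.nodes_per_community} nodes cannot host "
                f"boundary nodes for all designated pairs"
            )
        mapping[pair] = (counters[i], counters[j])
        counters[i] += 1
        counters[j] += 1
    return mapping


def _local_offsets(spec: PlantedSpec, centroids: np.ndarray, boundary) -> np.ndarray:
    """Static node offsets within each community ball.

    Boundary nodes sit at the community centre.  The remaining nodes are
    sampled uniformly in the ball of ``node_radius``, restricted to the
    half-spaces facing *away* from every designated partner so that no
    bystander node can drift into a planted interface.
    """
    rng = np.random.default_rng([int(spec.seed) & 0x7FFFFFFF, 919])
    K, n = spec.n_communities, spec.nodes_per_community
    axes: dict[int, list[np.ndarray]] = {k: [] for k in range(K)}
    fixed: dict[int, set[int]] = {k: set() for k in range(K)}
    for (i, j), (li, lj) in boundary.items():
        u = centroids[j] - centroids[i]
        u = u / np.linalg.norm(u)
        axes[i].append(u)
        axes[j].append(-u)
        fixed[i].add(li)
        fixed[j].add(lj)
    offsets = np.zeros((K, n, 3))
    for k in range(K):
        for local in range(n):
            if local in fixed[k]:
                continue  # boundary node stays at the centre
            for _ in range(5000):
                v = rng.uniform(-1.0, 1.0, 3)
                if np.dot(v, v) > 1.0:
                    continue
                if all(np.dot(v, u) <= 0.0 for u in axes[k]):
                    offsets[k, local] = v * spec.node_radius
                    break
            else:
                raise SpecError(
                    f"could not place node {local} of community {k} away from "
                    "all designated interfaces"
                )
    return offsets


def _node_table(spec: PlantedSpec) -> NodeTable:
    rows = []
    for k in range(spec.n_communities):
        chain = chr(ord("A") + k)
        for local in range(spec.nodes_per_community):
            rows.append(
                {
                    "chain_id": chain,
                    "residue_number": local + 1,
                    "insertion_code": "",
                    "residue_name": "ALA",
                    "node_kind": "protein",
                    "representative_atom": "CA",
                }
            )
    df = pd.DataFrame(rows)
    df.insert(0, "node_index", np.arange(len(df)))
    return NodeTable(df)


def _clip_norm(vectors: np.ndarray, limit: float) -> np.ndarray:
    """Rescale rows whose Euclidean norm exceeds ``limit``."""
    norms = np.linalg.norm(vectors, axis=-1, keepdims=True)
    factor = np.minimum(1.0, limit / np.maximum(norms, 1e-300))
    return vectors * factor


def ground_truth_labels(spec: PlantedSpec) -> np.ndarray:
    """Planted community label of every node."""
    return np.repeat(np.arange(spec.n_communities), spec.nodes_per_community)


def generate_state(spec: PlantedSpec, state_label: str) -> tuple[Ensemble, np.ndarray]:
    """Generate one state's ensemble and its planted partition.

    Frame randomness is drawn from a generator seeded by (seed, state
    label), so states are mutually independent but each is exactly
    reproducible; the static geometry (centroids, node offsets, boundary
    node assignment) depends on the seed only and is shared by every
    state, as a consensus analysis requires.
    """
    K, n, F = spec.n_communities, spec.nodes_per_community, spec.frames
    N = K * n
    centroids = _centroids(spec)
    boundary = _boundary_nodes(spec)
    offsets = _local_offsets(spec, centroids, boundary)
    labels = ground_truth_labels(spec)
    node_table = _node_table(spec)

    inter_p = spec.inter_p(state_label)
    intra_p = spec.intra_p(state_label)
    amplitudes = spec.amplitudes(state_label)
    state_key = zlib.crc32(state_label.encode()) & 0x7FFFFFFF
    rng = np.random.default_rng([int(spec.seed) & 0x7FFFFFFF, state_key])

    home = (centroids[:, None, :] + offsets).reshape(N, 3)

    # per-frame rigid community translations, norm-clipped
    coords = np.empty((F, N, 3))
    for k in range(K):
        t = rng.normal(0.0, amplitudes[k], size=(F, 3))
        t = _clip_norm(t, 2.34 * amplitudes[k])
        coords[:, labels == k, :] = home[labels == k][None, :, :] + t[:, None, :]

    # planted inter-community contacts: both boundary partners jump to the
    # near geometry in Bernoulli(p) frames
    for pair, (li, lj) in boundary.items():
        i, j = pair
        p = inter_p.get(pair, 0.0)
        near_frames = rng.random(F) < p
        gi, gj = i * n + li, j * n + lj
        axis = centroids[j] - centroids[i]
        axis = axis / np.linalg.norm(axis)
        mid = (centroids[i] + centroids[j]) / 2.0
        near_i = mid - (_NEAR_SEPARATION / 2.0) * axis
        near_j = mid + (_NEAR_SEPARATION / 2.0) * axis
        # keep the frame's community translation on top of the near spot
        ti = coords[:, gi, :] - home[gi]
        tj = coords[:, gj, :] - home[gj]
        coords[near_frames, gi, :] = near_i + ti[near_frames]
        coords[near_frames, gj, :] = near_j + tj[near_frames]

    # intra occupancy < 1: eligible nodes take independent excursions at
    # rate 1-sqrt(p), so an eligible pair is jointly home with probability p
    if intra_p < 1.0:
        q = 1.0 - np.sqrt(intra_p)
        boundary_globals = {
            c * n + l for (i, j), (li, lj) in boundary.items() for c, l in ((i, li), (j, lj))
        }
        eligible = np.array([g for g in range(N) if g not in boundary_globals])
        away = rng.random((F, len(eligible))) < q
        park = np.zeros((len(eligible), 3))
        park[:, 2] = _PARK_BASE + _PARK_STEP * eligible
        for col, g in enumerate(eligible):
            coords[away[:, col], g, :] += park[col]

    noise = _clip_norm(rng.normal(0.0, spec.noise, size=(F, N, 3)), 3.0 * spec.noise)
    coords = coords + noise

    # heavy layer: the representative atom plus a twin at a small offset
    hdir = np.random.default_rng([int(spec.seed) & 0x7FFFFFFF, 929]).normal(size=(N, 3))
    hdir /= np.linalg.norm(hdir, axis=1, keepdims=True)
    heavy = np.empty((F, 2 * N, 3))
    heavy[:, 0::2, :] = coords
    heavy[:, 1::2, :] = coords + _HEAVY_OFFSET * hdir[None, :, :]
    atom_node = np.repeat(np.arange(N), 2)
    names = ["CA", "CB"] * N

    ens = Ensemble(
        node_table=node_table,
        rep_coords=coords,
        state_label=state_label,
        heavy_coords=heavy,
        atom_node=atom_node,
        heavy_atom_names=names,
    )
    ens.validate()
    return ens, labels


def generate_transition_pair(
    spec: PlantedSpec,
    deltas: Mapping[tuple[int, int], float],
    state_a: str = "A",
    state_b: str = "B",
) -> tuple[Ensemble, Ensemble, dict]:
    """Two states differing by planted contact-probability changes.

    State B's inter-community contact probabilities equal state A's plus
    the given per-pair deltas.  Returns both ensembles and a ground
    truth dict with the planted partition and the intended sign of every
    community-pair change.
    """
    base = spec.inter_p(state_a)
    target = dict(base)
    signs = {}
    for pair, d in deltas.items():
        pair = _norm_pair(pair)
        pb = base.get(pair, 0.0) + float(d)
        if not (0.0 <= pb <= 1.0):
            raise SpecError(
                f"delta {d:+g} on pair {pair} drives probability to {pb:.3f}, outside [0, 1]"
            )
        target[pair] = pb
        signs[pair] = int(np.sign(d))
    paired = replace(
        spec, inter_contact_p={state_a: base, state_b: target}
    )
    ens_a, labels = generate_state(paired, state_a)
    ens_b, _ = generate_state(paired, state_b)
    truth = {
        "partition": labels,
        "delta_signs": signs,
        "inter_p_a": base,
        "inter_p_b": target,
    }
    return ens_a, ens_b, truth


def generate_mutation_fixture(
    spec: PlantedSpec,
    n_internal: int,
    n_interfacial: int,
    state_label: str = "A",
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Mutation table with known internal/interfacial ground truth.

    Interfacial mutations are placed on boundary nodes of designated
    pairs whose planted contact probability is nonzero in the given
    state; internal ones on nodes with no inter-community contacts at
    all.  Returns (mutation table, {mutation name: expected class}).
    """
    boundary = _boundary_nodes(spec)
    inter_p = spec.inter_p(state_label)
    n = spec.nodes_per_community
    active_boundary = []
    for pair, (li, lj) in sorted(boundary.items()):
        if inter_p.get(pair, 0.0) > 0.0:
            active_boundary.extend([pair[0] * n + li, pair[1] * n + lj])
    boundary_all = {
        c * n + l for (i, j), (li, lj) in boundary.items() for c, l in ((i, li), (j, lj))
    }
    internal_nodes = [g for g in range(spec.n_communities * n) if g not in boundary_all]
    if n_interfacial > len(active_boundary):
        raise SpecError(
            f"only {len(active_boundary)} boundary nodes carry planted contacts; "
            f"cannot place {n_interfacial} interfacial mutations"
        )
    if n_internal > len(internal_nodes):
        raise SpecError(f"only {len(internal_nodes)} internal nodes available")

    node_table = _node_table(spec)
    rows = []
    expected = {}
    phenos = ["XP", "TTD", "XP/CS", "XP/TTD"]
    picks = [(g, "interfacial") for g in active_boundary[:n_interfacial]]
    picks += [(g, "internal") for g in internal_nodes[:n_internal]]
    for idx, (g, cls) in enumerate(picks):
        row = node_table.df.iloc[g]
        rec = {
            "subunit": f"CHAIN{row.chain_id}",
            "chain_id": row.chain_id,
            "wild_type": "A",  # all synthetic residues are alanine
            "position": int(row.residue_number),
            "mutant": "V",
            "phenotype": phenos[idx % len(phenos)],
            "note": f"planted {cls}",
        }
        rows.append(rec)
        name = f"CHAIN{row.chain_id} A{row.residue_number}V"
        expected[name] = cls
    return pd.DataFrame(rows), expected
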