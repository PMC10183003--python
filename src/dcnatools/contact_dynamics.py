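"""Per-state contact statistics from conformational ensembles.

The quantities computed here are the raw material of the network
analysis:

* **contact probability** P_ij — the fraction of ensemble frames in
  which two non-adjacent residues are within a distance cutoff (default
  4.5 Å on the minimum heavy-atom distance);
* **binary contacts** — P_ij thresholded at an occupancy fraction
  (default 75 %), the classical "in contact for 75 % or more of the
  trajectory" rule;
* **dynamic cross-correlation** c_ij of representative-atom displacement
  vectors;
* **B-factors** from mean-square fluctuations, B = (8π²/3)·⟨Δr²⟩, the
  isotropic crystallographic convention for MD RMSF.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .ensemble_io import Ensemble, NodeTable
from .errors import EnsembleError, GeometryError

B_FACTOR_PREFACTOR = 8.0 * np.pi**2 / 3.0


@dataclass
class ContactProbabilityMatrix:
    """Symmetric N×N occupancy matrix for one functional state."""

    P: np.ndarray
    cutoff: float
    exclusion: int
    state_label: str
    node_table: NodeTable
    geometry: str = "heavy"

    def __post_init__(self) -> None:
        P = np.asarray(self.P, dtype=np.float64)
        if P.ndim != 2 or P.shape[0] != P.shape[1]:
            raise ValueError("P must be square")
        if not np.allclose(P, P.T):
            raise ValueError("P must be symmetric")
        if P.min() < 0 or P.max() > 1:
            raise ValueError("occupancies must lie in [0, 1]")
        self.P = P


@dataclass
class CorrelationMatrix:
    """Dynamic cross-correlation c_ij in [-1, 1] with unit diagonal."""

    c: np.ndarray
    state_label: str = ""

    def __post_init__(self) -> None:
        c = np.asarray(self.c, dtype=np.float64)
        if not np.allclose(c, c.T):
            raise ValueError("c must be symmetric")
        if np.abs(c).max() > 1 + 1e-12:
            raise ValueError("|c_ij| must not exceed 1")
        if not np.allclose(np.diag(c), 1.0):
            raise ValueError("diagonal must be 1")
        self.c = c


@dataclass
class BFactorProfile:
    """Per-node isotropic B-factor (Å²) and mean-square fluctuation (Å²)."""

    B: np.ndarray
    msf: np.ndarray
    state_label: str = ""


def _adjacency_exclusion_mask(node_table: NodeTable, exclusion: int) -> np.ndarray:
    """Boolean N×N mask of pairs excluded as sequence neighbours.

    Pairs on the same chain whose author residue numbers differ by at
    most ``exclusion`` are excluded (the diagonal always is).  Inter-chain
    pairs are never excluded.
    """
    chains = node_table.df["chain_id"].to_numpy()
    resnum = node_table.df["residue_number"].to_numpy()
    same_chain = chains[:, None] == chains[None, :]
    close_seq = np.abs(resnum[:, None] - resnum[None, :]) <= exclusion
    mask = same_chain & close_seq
    np.fill_diagonal(mask, True)
    return mask


def min_distance_matrix(ensemble: Ensemble, frame: int, geometry: str = "heavy") -> np.ndarray:
    """N×N minimum inter-residue distance matrix for one frame (Å)."""
    N = ensemble.n_nodes
    if geometry == "representative":
        return cdist(ensemble.rep_coords[frame], ensemble.rep_coords[frame])
    if ensemble.heavy_coords is None:
        raise GeometryError("heavy-atom geometry requested but ensemble has no heavy atoms")
    X = ensemble.heavy_coords[frame]
    d = cdist(X, X)
    out = np.full((N, N), np.inf)
    idx = ensemble.atom_node[:, None] * N + ensemble.atom_node[None, :]
    np.minimum.at(out.reshape(-1), idx.reshape(-1), d.reshape(-1))
    return out


def contact_probability(
    ensemble: Ensemble,
    cutoff: float = 4.5,
    exclusion: int = 1,
    geometry: str = "heavy",
) -> ContactProbabilityMatrix:
    """Occupancy matrix P_ij over the ensemble.

    P_ij is the fraction of frames in which the minimum inter-residue
    distance (heavy-atom by default, representative-atom optionally) is
    within ``cutoff``.  Sequence neighbours up to ``exclusion`` apart on
    the same chain are zeroed — contacts between covalently linked
    residues carry no dynamic information.
    """
    if ensemble.n_frames < 2:
        raise EnsembleError("contact probabilities need at least 2 frames")
    if geometry not in {"heavy", "representative"}:
        raise GeometryError(f"unknown contact geometry {geometry!r}")
    N = ensemble.n_nodes
    F = ensemble.n_frames
    if geometry == "heavy" and ensemble.heavy_coords is None:
        raise GeometryError("heavy-atom geometry requested but ensemble has no heavy atoms")

    counts = np.zeros((N, N), dtype=np.int64)
    if geometry == "representative":
        # distances for all frames in manageable chunks
        chunk = max(1, int(2_000_000 / max(N * N, 1)))
        for start in range(0, F, chunk):
            X = ensemble.rep_coords[start : start + chunk]
            d2 = np.sum((X[:, :, None, :] - X[:, None, :, :]) ** 2, axis=-1)
            counts += (d2 <= cutoff * cutoff).sum(axis=0)
    else:
        pair_idx = (ensemble.atom_node[:, None] * N + ensemble.atom_node[None, :]).reshape(-1)
        for f in range(F):
            X = ensemble.heavy_coords[f]
            d = cdist(X, X)
            m = np.full(N * N, np.inf)
            np.minimum.at(m, pair_idx, d.reshape(-1))
            counts += (m <= cutoff).reshape(N, N)

    P = counts / float(F)
    P[_adjacency_exclusion_mask(ensemble.node_table, exclusion)] = 0.0
    P = np.minimum(P, P.T)  # exact symmetry despite float order
    return ContactProbabilityMatrix(
        P=P,
        cutoff=float(cutoff),
        exclusion=int(exclusion),
        state_label=ensemble.state_label,
        node_table=ensemble.node_table,
        geometry=geometry,
    )


def binary_contacts(P: ContactProbabilityMatrix, occupancy_threshold: float = 0.75) -> np.ndarray:
    """Boolean adjacency: contact present iff P_ij >= threshold (inclusive)."""
    if not (0.0 < occupancy_threshold <= 1.0):
        raise ValueError(f"occupancy_threshold must be in (0, 1], got {occupancy_threshold}")
    A = P.P >= occupancy_threshold
    np.fill_diagonal(A, False)
    return A


def cross_correlation(ensemble: Ensemble) -> CorrelationMatrix:
    """Dynamic cross-correlation of representative-atom displacements.

    c_ij = ⟨Δr_i·Δr_j⟩ / √(⟨Δr_i²⟩⟨Δr_j²⟩), with Δr_i the displacement
    of node i from its ensemble mean.  This is the vector dot-product
    correlation standard in protein network analysis — not a per-axis
    Pearson coefficient.  The ensemble must be superposed first: global
    rigid-body motion masquerades as correlation.
    """
    if ensemble.n_frames < 2:
        raise EnsembleError("cross-correlation needs at least 2 frames")
    X = ensemble.rep_coords - ensemble.rep_coords.mean(axis=0, keepdims=True)
    cov = np.einsum("fia,fja->ij", X, X) / ensemble.n_frames
    var = np.diag(cov).copy()
    zero = np.flatnonzero(var <= 0)
    if len(zero):
        keys = [ensemble.node_table.keys()[i] for i in zero[:5]]
        raise EnsembleError(f"zero-variance nodes make correlation undefined: {keys}")
    c = cov / np.sqrt(np.outer(var, var))
    c = np.clip((c + c.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(c, 1.0)
    return CorrelationMatrix(c=c, state_label=ensemble.state_label)


def bfactors(ensemble: Ensemble) -> BFactorProfile:
    """Per-node B-factors from mean-square fluctuations.

    ⟨Δr_i²⟩ is averaged over frames after superposition; B_i converts it
    with the crystallographic prefactor 8π²/3.  Rigid-body components
    must have been removed by :func:`~dcnatools.ensemble_io.superpose`,
    otherwise they inflate every node equally.
    """
    if ensemble.n_frames < 2:
        raise EnsembleError("B-factors need at least 2 frames")
    X = ensemble.rep_coords - ensemble.rep_coords.mean(axis=0, keepdims=True)
    msf = np.mean(np.sum(X * X, axis=2), axis=0)
    return BFactorProfile(B=B_FACTOR_PREFACTOR * msf, msf=msf, state_label=ensemble.state_label)
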