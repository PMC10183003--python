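"""Principal component analysis of representative-atom coordinates.

PCA diagonalises the 3N×3N covariance of superposed Cα/P coordinates;
the dominant (largest-variance) modes describe the collective motions
of the assembly.  Modes are mapped back onto dynamic communities as
per-node displacement "porcupine" arrows with per-community direction
and amplitude summaries, which is how one reads off, e.g., that one
module keeps its large-scale dynamics while another is locked.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg

from .community_networks import CommunityPartition
from .ensemble_io import Ensemble
from .errors import EnsembleError, NetworkError

__all__ = [
    "PCAResult",
    "coordinate_covariance",
    "principal_modes",
    "pca_ensemble",
    "mode_arrows_by_community",
]


@dataclass
class PCAResult:
    """Eigenpairs of the coordinate covariance plus frame projections.

    ``eigenvalues`` are variances per mode (Å²), sorted descending;
    ``modes`` is (3N, n_modes) with orthonormal columns; ``projections``
    (F, n_modes) holds the coordinates of each frame along each mode
    when an ensemble was supplied.
    """

    eigenvalues: np.ndarray
    modes: np.ndarray
    mean_structure: np.ndarray
    projections: np.ndarray | None = None
    total_variance: float = 0.0

    @property
    def variance_fraction(self) -> np.ndarray:
        return self.eigenvalues / self.total_variance


def coordinate_covariance(ensemble: Ensemble) -> np.ndarray:
    """3N×3N covariance (Å²) of flattened representative coordinates."""
    if ensemble.n_frames < 2:
        raise EnsembleError("covariance needs at least 2 frames")
    X = ensemble.rep_coords.reshape(ensemble.n_frames, -1)
    Xc = X - X.mean(axis=0)
    C = Xc.T @ Xc / ensemble.n_frames
    return (C + C.T) / 2.0


def principal_modes(
    covariance: np.ndarray,
    n_modes: int,
    ensemble: Ensemble | None = None,
) -> PCAResult:
    """Top-variance eigenpairs of a coordinate covariance matrix.

    Eigenvalues come out sorted descending.  Each mode's sign is fixed
    so its largest-magnitude component is positive, making results
    reproducible across LAPACK builds.  When an ensemble is given, its
    frames are projected onto the modes.
    """
    C = np.asarray(covariance, dtype=np.float64)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise ValueError("covariance must be square")
    if not np.allclose(C, C.T, atol=1e-8):
        raise ValueError("covariance must be symmetric")
    dim = C.shape[0]
    if not (1 <= n_modes <= dim):
        raise ValueError(f"n_modes must be in [1, {dim}]")
    vals, vecs = scipy.linalg.eigh(C, subset_by_index=(dim - n_modes, dim - 1))
    vals = vals[::-1]
    vecs = vecs[:, ::-1]
    for k in range(vecs.shape[1]):
        j = int(np.argmax(np.abs(vecs[:, k])))
        if vecs[j, k] < 0:
            vecs[:, k] = -vecs[:, k]

    mean = None
    proj = None
    if ensemble is not None:
        X = ensemble.rep_coords.reshape(ensemble.n_frames, -1)
        mu = X.mean(axis=0)
        proj = (X - mu) @ vecs
        mean = mu.reshape(-1, 3)
    return PCAResult(
        eigenvalues=vals,
        modes=vecs,
        mean_structure=mean if mean is not None else np.zeros((dim // 3, 3)),
        projections=proj,
        total_variance=float(np.trace(C)),
    )


def pca_ensemble(ensemble: Ensemble, n_modes: int = 5) -> PCAResult:
    """Covariance + eigenmodes + projections for a superposed ensemble."""
    C = coordinate_covariance(ensemble)
    n_modes = min(n_modes, C.shape[0])
    return principal_modes(C, n_modes, ensemble=ensemble)


def mode_arrows_by_community(
    result: PCAResult,
    mode_index: int,
    partition: CommunityPartition,
    scale: float = 1.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-node displacement arrows of one mode, grouped by community.

    Arrows are the mode components weighted by the mode's RMS amplitude
    (√eigenvalue) and ``scale``, so a zero-variance mode draws no
    arrows.  Returns (arrows, summary): arrows has one row per node with
    the (dx, dy, dz) displacement and community id; summary has one row
    per community with the mean direction (unit vector) and the mean
    arrow amplitude in Å — the quantities behind porcupine-plot figures.
    """
    if not (0 <= mode_index < result.modes.shape[1]):
        raise ValueError(f"mode_index {mode_index} out of range")
    rms = float(np.sqrt(max(result.eigenvalues[mode_index], 0.0)))
    vecs = result.modes[:, mode_index].reshape(-1, 3) * (float(scale) * rms)
    n = vecs.shape[0]
    if len(partition.labels) != n:
        raise NetworkError("partition does not cover the PCA node set")
    arrows = pd.DataFrame(
        {
            "node_index": np.arange(n),
            "dx": vecs[:, 0],
            "dy": vecs[:, 1],
            "dz": vecs[:, 2],
            "community": partition.labels,
        }
    )
    rows = []
    for c in np.unique(partition.labels):
        sub = vecs[partition.labels == c]
        mean_vec = sub.mean(axis=0)
        norm = np.linalg.norm(mean_vec)
        rows.append(
            {
                "community": int(c),
                "n_nodes": int(sub.shape[0]),
                "mean_dx": mean_vec[0] if norm == 0 else mean_vec[0] / norm,
                "mean_dy": mean_vec[1] if norm == 0 else mean_vec[1] / norm,
                "mean_dz": mean_vec[2] if norm == 0 else mean_vec[2] / norm,
                "mean_amplitude": float(np.linalg.norm(sub, axis=1).mean()),
            }
        )
    return arrows, pd.DataFrame(rows)
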