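"""Rigid-body superposition, RMSD/RMSF machinery and medoid structures.

The superposition is the standard Kabsch least-squares fit (SVD of the
cross-covariance, reflection corrected by flipping the smallest singular
vector). RMSF is computed about the iteratively refined mean structure;
the "representative structure" of a trajectory window is its medoid under
pairwise Cα RMSD.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import Structure, Trajectory
from .metrics import MetricSeries

__all__ = [
    "SuperpositionResult",
    "RmsfProfile",
    "superpose",
    "rmsd_series",
    "rmsf_profile",
    "representative_frame",
    "pairwise_rmsd_matrix",
]


@dataclass(frozen=True)
class SuperpositionResult:
    """Optimal rigid transform mapping a mobile point set onto a reference.

    ``transformed = mobile @ rotation.T + translation`` minimises the RMSD
    to the reference; ``rmsd`` is that minimum, in Å.
    """

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, dtype=float) @ self.rotation.T + self.translation


@dataclass(frozen=True)
class RmsfProfile:
    """Per-residue positional fluctuation amplitudes, Å."""

    resids: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        if len(self.resids) != len(self.values):
            raise ValueError("resids and values must have equal length")
        if np.any(np.asarray(self.values) < 0):
            raise ValueError("RMSF values must be non-negative")

    def argmax_resid(self) -> int:
        return int(np.asarray(self.resids)[int(np.argmax(self.values))])

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"resid": self.resids, "rmsf_A": self.values})


def _as_points(x) -> np.ndarray:
    pts = np.asarray(x, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError(f"expected (n, 3) point set, got shape {pts.shape}")
    return pts


def superpose(mobile, reference) -> SuperpositionResult:
    """Kabsch least-squares fit of ``mobile`` onto ``reference``.

    Both inputs are (n, 3) arrays with n >= 3 corresponding points.
    Returns the proper rotation (det = +1) and translation minimising the
    RMSD, together with that minimum RMSD.
    """
    P = _as_points(mobile)
    Q = _as_points(reference)
    if P.shape != Q.shape:
        raise ValueError(f"point-count mismatch: {P.shape[0]} vs {Q.shape[0]}")
    n = P.shape[0]
    if n < 3:
        raise ValueError("superposition requires at least 3 points")
    cp, cq = P.mean(axis=0), Q.mean(axis=0)
    P0, Q0 = P - cp, Q - cq
    H = P0.T @ Q0
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    if d == 0:  # degenerate (e.g. planar) — treat as proper
        d = 1.0
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    # residual computed directly: immune to the cancellation the
    # |P|^2 + |Q|^2 - 2 tr(S) form suffers near rmsd = 0
    rmsd = float(np.sqrt(((P0 @ R.T - Q0) ** 2).sum() / n))
    t = cq - R @ cp
    return SuperpositionResult(rotation=R, translation=t, rmsd=rmsd)


def _selection_coords(t: Trajectory, selection) -> np.ndarray:
    """(n_frames, n_sel, 3) coordinates for an index-array selection."""
    idx = np.asarray(selection, dtype=int)
    if idx.size == 0:
        raise ValueError("empty selection")
    return t.coords[:, idx, :]


def rmsd_series(
    t: Trajectory, selection, reference_frame: int = 0, label: str = "rmsd"
) -> MetricSeries:
    """Per-frame backbone RMSD to a reference frame, after superposition.

    ``selection`` is an array of topology atom indices (e.g. from
    :func:`groovekit.io.calpha_indices`).
    """
    if not (-t.n_frames <= reference_frame < t.n_frames):
        raise IndexError(
            f"reference frame {reference_frame} out of range for "
            f"{t.n_frames}-frame trajectory"
        )
    X = _selection_coords(t, selection)
    ref = X[reference_frame]
    values = np.array([superpose(x, ref).rmsd for x in X])
    return MetricSeries(times=t.times, values=values, label=label)


def rmsf_profile(
    t: Trajectory,
    selection,
    resids=None,
    use_mean_structure: bool = True,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> RmsfProfile:
    """Per-atom RMSF of a Cα selection about the mean structure.

    Frames are superposed onto the running mean structure, the mean is
    recomputed, and the loop repeats until the mean moves less than
    ``tol`` Å. ``use_mean_structure=False`` instead superposes every frame
    onto the first frame of the selection (the simpler convention some
    packages use).
    """
    if t.n_frames < 2:
        raise ValueError("RMSF requires at least 2 frames")
    X = _selection_coords(t, selection).copy()
    ref = X.mean(axis=0) if use_mean_structure else X[0]
    for _ in range(max_iter):
        for k in range(X.shape[0]):
            X[k] = superpose(X[k], ref).apply(X[k])
        if not use_mean_structure:
            break
        new_mean = X.mean(axis=0)
        shift = float(np.sqrt(((new_mean - ref) ** 2).sum(axis=1).mean()))
        ref = new_mean
        if shift < tol:
            break
    mean = X.mean(axis=0)
    rmsf = np.sqrt(((X - mean) ** 2).sum(axis=2).mean(axis=0))
    if resids is None:
        idx = np.asarray(selection, dtype=int)
        resids = np.array([t.topology.atoms[i].resid for i in idx])
    return RmsfProfile(resids=np.asarray(resids), values=rmsf)


def pairwise_rmsd_matrix(X: np.ndarray) -> np.ndarray:
    """Symmetric matrix of minimum (superposed) RMSDs between frames.

    ``X`` is (n_frames, n_atoms, 3). Uses a batched Kabsch: per-pair 3x3
    cross-covariances and stacked SVDs.
    """
    X = np.asarray(X, dtype=float)
    K, n, _ = X.shape
    C = X - X.mean(axis=1, keepdims=True)
    sq = (C**2).sum(axis=(1, 2))
    ii, jj = np.triu_indices(K, k=1)
    H = np.einsum("pni,pnj->pij", C[ii], C[jj])
    _, S, Vt = np.linalg.svd(H)
    dets = np.sign(np.linalg.det(H))
    dets[dets == 0] = 1.0
    trace = S[:, 0] + S[:, 1] + dets * S[:, 2]
    ssd = np.maximum(sq[ii] + sq[jj] - 2.0 * trace, 0.0)
    # identical frames should compare at exactly 0, not cancellation noise
    ssd[ssd < 1e-10 * (sq[ii] + sq[jj])] = 0.0
    M = np.zeros((K, K))
    M[ii, jj] = M[jj, ii] = np.sqrt(ssd / n)
    return M


def representative_frame(t: Trajectory, selection, window: int = 1000) -> int:
    """Medoid frame of the trailing window: the trajectory's representative.

    Among the last ``window`` frames, returns the (absolute) index of the
    frame minimising mean pairwise Cα RMSD to every other in-window frame.
    Ties break toward the lowest index.
    """
    if window < 2:
        raise ValueError("window must contain at least 2 frames")
    if window > t.n_frames:
        raise ValueError(
            f"window ({window}) exceeds trajectory length ({t.n_frames})"
        )
    start = t.n_frames - window
    X = _selection_coords(t, selection)[start:]
    M = pairwise_rmsd_matrix(X)
    means = M.sum(axis=1) / (window - 1)
    return start + int(np.argmin(means))  # argmin takes first on ties
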