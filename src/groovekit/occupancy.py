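"""Voxel occupancy maps of ligand/peptide positions over a trajectory.

A voxel's occupancy is the fraction of frames in which at least one
selected atom centre falls inside it. The 50% occupancy volume — the set
of voxels occupied in at least half of the frames — outlines where a
molecule persistently sits in the groove. Frames are superposed onto the
receptor framework first, so the map lives in the receptor's frame of
reference.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .geometry import superpose
from .io import Trajectory

__all__ = ["OccupancyGrid", "occupancy_grid", "occupancy_isovolume", "write_dx"]


@dataclass
class OccupancyGrid:
    """Regular voxel lattice of per-voxel occupied-frame fractions."""

    origin: np.ndarray  # corner of voxel (0,0,0), Å
    spacing: float  # voxel edge, Å
    values: np.ndarray  # (nx, ny, nz) fractions in [0, 1]

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3 or min(self.values.shape) < 1:
            raise ValueError("grid must be 3-D with positive dims")
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        if self.values.min() < 0 or self.values.max() > 1:
            raise ValueError("occupancy fractions must lie in [0, 1]")

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.values.shape

    def voxel_center(self, ijk) -> np.ndarray:
        return self.origin + (np.asarray(ijk, dtype=float) + 0.5) * self.spacing


def occupancy_grid(
    t: Trajectory,
    selection,
    spacing: float = 1.0,
    padding: float = 2.0,
    align_selection=None,
) -> OccupancyGrid:
    """Occupancy map of an atom selection over all frames.

    The grid spans the selection's all-frame bounding box plus ``padding``.
    ``align_selection`` (topology indices) names the framework the frames
    are superposed on before counting — pass ``None`` to count raw
    coordinates. Occupancy counts atom centres, not van der Waals volumes.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    idx = np.asarray(selection, dtype=int)
    if idx.size == 0:
        raise ValueError("empty selection")
    if t.n_frames == 0:
        raise ValueError("trajectory has no frames")
    coords = t.coords.copy()
    if align_selection is not None:
        aidx = np.asarray(align_selection, dtype=int)
        ref = coords[0, aidx]
        for k in range(1, t.n_frames):
            fit = superpose(coords[k, aidx], ref)
            coords[k] = fit.apply(coords[k])
    pts = coords[:, idx, :]  # (n_frames, n_sel, 3)
    lo = pts.reshape(-1, 3).min(axis=0) - padding
    hi = pts.reshape(-1, 3).max(axis=0) + padding
    dims = np.maximum(np.ceil((hi - lo) / spacing).astype(int), 1)
    counts = np.zeros(tuple(dims), dtype=np.int64)
    for k in range(t.n_frames):
        ijk = np.floor((pts[k] - lo) / spacing).astype(int)
        ijk = np.clip(ijk, 0, dims - 1)
        ijk = np.unique(ijk, axis=0)  # >=1 atom in the voxel counts once
        counts[ijk[:, 0], ijk[:, 1], ijk[:, 2]] += 1
    return OccupancyGrid(origin=lo, spacing=spacing, values=counts / t.n_frames)


def occupancy_isovolume(
    g: OccupancyGrid, threshold: float = 0.5
) -> tuple[np.ndarray, float]:
    """Voxels occupied in at least ``threshold`` of frames, and their volume.

    The threshold is inclusive (``>=``). Returns an (m, 3) array of voxel
    indices and the volume ``m * spacing**3`` in Å³; an empty set is a
    legitimate result at high thresholds.
    """
    if not (0 < threshold <= 1):
        raise ValueError("threshold must lie in (0, 1]")
    voxels = np.argwhere(g.values >= threshold)
    volume = float(len(voxels) * g.spacing**3)
    return voxels, volume


def write_dx(g: OccupancyGrid, path: str | Path) -> None:
    """Write the grid as an OpenDX scalar field (readable by PyMOL/VMD)."""
    nx, ny, nz = g.dims
    # OpenDX positions are grid-point centres
    o = g.origin + 0.5 * g.spacing
    lines = [
        f"object 1 class gridpositions counts {nx} {ny} {nz}",
        f"origin {o[0]:.6f} {o[1]:.6f} {o[2]:.6f}",
        f"delta {g.spacing:.6f} 0.0 0.0",
        f"delta 0.0 {g.spacing:.6f} 0.0",
        f"delta 0.0 0.0 {g.spacing:.6f}",
        f"object 2 class gridconnections counts {nx} {ny} {nz}",
        f"object 3 class array type double rank 0 items {nx * ny * nz} data follows",
    ]
    flat = g.values.ravel(order="C")
    for i in range(0, len(flat), 3):
        lines.append(" ".join(f"{v:.6f}" for v in flat[i : i + 3]))
    lines.append('attribute "dep" string "positions"')
    lines.append('object "occupancy" class field')
    Path(path).write_text("\n".join(lines) + "\n")


def read_dx(path: str | Path) -> OccupancyGrid:
    """Read back a grid written by :func:`write_dx` (round-trip utility)."""
    txt = Path(path).read_text().splitlines()
    counts = None
    origin = None
    deltas = []
    data: list[float] = []
    in_data = False
    for line in txt:
        if line.startswith("object 1"):
            counts = tuple(int(x) for x in line.split()[-3:])
        elif line.startswith("origin"):
            origin = np.array([float(x) for x in line.split()[1:]])
        elif line.startswith("delta"):
            deltas.append([float(x) for x in line.split()[1:]])
        elif "data follows" in line:
            in_data = True
        elif line.startswith("attribute") or line.startswith('object "'):
            in_data = False
        elif in_data:
            data.extend(float(x) for x in line.split())
    if counts is None or origin is None or not deltas:
        raise ValueError(f"{path}: not a groovekit OpenDX grid")
    spacing = deltas[0][0]
    values = np.array(data).reshape(counts, order="C")
    return OccupancyGrid(origin=origin - 0.5 * spacing, spacing=spacing, values=values)
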