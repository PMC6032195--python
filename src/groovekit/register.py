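"""Peptide register enumeration along the groove axis and pocket assignment.

Class II grooves are open at both ends, so a bound peptide can slide:
which nine consecutive residues occupy pockets P1–P9 is its *register*.
This module slides the peptide along the groove's principal axis in
one-residue-sized steps, scores each candidate register geometrically
(steric clashes, and contacts with either groove wall), and maps a chosen
P1 anchor position to the full P1–P9 pocket assignment.

Ranking is geometric only — a clash-free pose with many contacts, spread
over both the α- and β-chain walls, wins. Energetic re-scoring of the
survivors (the usual final arbiter) is out of scope here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio.SeqUtils import seq3
from scipy.spatial.distance import cdist

from .io import GrooveDefinition, Structure, select_atoms, select_calpha

__all__ = [
    "RegisterFrame",
    "PocketAssignment",
    "groove_axis",
    "enumerate_registers",
    "rank_registers",
    "assign_pockets",
    "CLASH_CUTOFF",
    "CONTACT_CUTOFF",
    "RESIDUE_RISE",
]

#: Heavy-atom pair distance below which two atoms clash, Å.
CLASH_CUTOFF = 2.5
#: Heavy-atom pair distance below which two atoms are in contact, Å.
CONTACT_CUTOFF = 4.5
#: Per-residue rise of an extended peptide, Å — one step = one register shift.
RESIDUE_RISE = 3.4


@dataclass(frozen=True)
class RegisterFrame:
    """One candidate register: a rigid slide of the peptide plus its scores."""

    offset_residues: int
    translation: tuple[float, float, float]
    clash_count: int
    contacts_alpha: int
    contacts_beta: int
    label: str

    @property
    def contacts_total(self) -> int:
        return self.contacts_alpha + self.contacts_beta


@dataclass(frozen=True)
class PocketAssignment:
    """Mapping of pockets P1..P9 to consecutive peptide residues."""

    pockets: dict[str, tuple[int, str]]

    def __post_init__(self) -> None:
        if sorted(self.pockets) != [f"P{i}" for i in range(1, 10)]:
            raise ValueError("pocket assignment must cover exactly P1..P9")
        positions = [self.pockets[f"P{i}"][0] for i in range(1, 10)]
        if positions != list(range(positions[0], positions[0] + 9)):
            raise ValueError("pockets must map to consecutive residues")

    def __getitem__(self, pocket: str) -> tuple[int, str]:
        return self.pockets[pocket]


def groove_axis(
    s: Structure, g: GrooveDefinition
) -> tuple[np.ndarray, np.ndarray]:
    """Principal axis of the groove and its centroid.

    The axis is the largest-variance eigenvector of the combined α+β
    helix Cα coordinates, with its sign chosen to point toward increasing
    α-helix residue number.
    """
    a = select_calpha(s, g.alpha_chain, g.alpha_helix)
    b = select_calpha(s, g.beta_chain, g.beta_helix)
    if not a or not b:
        raise ValueError("empty helix selection for groove axis")
    pts = np.array([at.xyz for at in a + b], dtype=float)
    centroid = pts.mean(axis=0)
    cov = np.cov((pts - centroid).T)
    w, v = np.linalg.eigh(cov)
    if w[-1] < 1e-9 or (w[-1] - w[-2]) / max(w[-1], 1e-12) < 1e-6:
        raise ValueError("degenerate helix point cloud: no unique principal axis")
    axis = v[:, -1]
    alpha_dir = np.asarray(a[-1].xyz) - np.asarray(a[0].xyz)
    if axis @ alpha_dir < 0:
        axis = -axis
    return axis / np.linalg.norm(axis), centroid


def _heavy_coords(s: Structure, chain: str) -> np.ndarray:
    atoms = select_atoms(s, chain=chain, elements_not=("H", "D"))
    return np.array([a.xyz for a in atoms], dtype=float)


def count_clashes_contacts(
    peptide_xyz: np.ndarray, wall_xyz: np.ndarray
) -> tuple[int, int]:
    """(clashes, contacts) between a peptide pose and one groove wall."""
    d = cdist(peptide_xyz, wall_xyz)
    return int((d < CLASH_CUTOFF).sum()), int((d < CONTACT_CUTOFF).sum())


def enumerate_registers(
    s: Structure,
    g: GrooveDefinition,
    max_shift: int = 3,
    step: float = RESIDUE_RISE,
    clash_cutoff: float = CLASH_CUTOFF,
    contact_cutoff: float = CONTACT_CUTOFF,
) -> list[RegisterFrame]:
    """Slide the peptide along the groove axis and score every offset.

    For each integer offset in [−max_shift, +max_shift] the peptide is
    rigidly translated by ``offset * step`` along the groove axis and the
    pose scored: ``clash_count`` = peptide/HLA heavy-atom pairs closer
    than ``clash_cutoff``; contacts = pairs closer than ``contact_cutoff``,
    split by groove wall. Always returns ``2 * max_shift + 1`` frames.
    """
    if g.peptide_chain is None:
        raise ValueError("groove definition has no peptide chain")
    if step <= 0:
        raise ValueError("step must be positive")
    pep = _heavy_coords(s, g.peptide_chain)
    if pep.size == 0:
        raise ValueError(f"peptide chain {g.peptide_chain!r} not found")
    wall_a = _heavy_coords(s, g.alpha_chain)
    wall_b = _heavy_coords(s, g.beta_chain)
    axis, _ = groove_axis(s, g)
    frames: list[RegisterFrame] = []
    for offset in range(-max_shift, max_shift + 1):
        shift = axis * (offset * step)
        pose = pep + shift
        da = cdist(pose, wall_a)
        db = cdist(pose, wall_b)
        clashes = int((da < clash_cutoff).sum() + (db < clash_cutoff).sum())
        frames.append(
            RegisterFrame(
                offset_residues=offset,
                translation=tuple(shift),
                clash_count=clashes,
                contacts_alpha=int((da < contact_cutoff).sum()),
                contacts_beta=int((db < contact_cutoff).sum()),
                label=f"offset{offset:+d}",
            )
        )
    return frames


def rank_registers(frames: list[RegisterFrame]) -> list[RegisterFrame]:
    """Total geometric ordering of candidate registers, best first.

    Sort key: fewest clashes, then most total contacts, then the larger
    balanced contact count min(contacts_alpha, contacts_beta) — rewarding
    poses gripping both walls of the groove — then smallest |offset|
    (negative before positive on the final tie, for determinism).
    """
    if not frames:
        raise ValueError("no register frames to rank")
    return sorted(
        frames,
        key=lambda f: (
            f.clash_count,
            -f.contacts_total,
            -min(f.contacts_alpha, f.contacts_beta),
            abs(f.offset_residues),
            f.offset_residues,
        ),
    )


def assign_pockets(peptide_seq: str, p1_index: int) -> PocketAssignment:
    """Map pockets P1..P9 onto a peptide given the P1 anchor position.

    ``peptide_seq`` is a one-letter sequence; ``p1_index`` is the 1-based
    position of the residue sitting in pocket P1. The nine consecutive
    residues from there form the core register.
    """
    n = len(peptide_seq)
    if p1_index < 1 or p1_index + 8 > n:
        raise ValueError(
            f"P1 at position {p1_index} leaves no room for a 9-mer core in a "
            f"{n}-residue peptide"
        )
    pockets = {
        f"P{i + 1}": (p1_index + i, seq3(peptide_seq[p1_index - 1 + i]).capitalize())
        for i in range(9)
    }
    return PocketAssignment(pockets=pockets)
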