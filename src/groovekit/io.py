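"""Structure and trajectory I/O plus atom-selection primitives.

Structures are lightweight, order-stable containers of atoms; trajectories
are a shared topology plus an ``(n_frames, n_atoms, 3)`` coordinate array.
PDB reading and writing go through :mod:`gemmi`; multi-model files are the
trajectory interchange format (MODEL/ENDMDL blocks sharing one atom set).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np

__all__ = [
    "Atom",
    "Structure",
    "Trajectory",
    "GrooveDefinition",
    "PDBParseError",
    "EmptySelectionWarning",
    "read_pdb",
    "write_pdb",
    "read_trajectory",
    "write_trajectory",
    "select_calpha",
    "select_atoms",
]

#: Default time step between saved frames, ns (1250 frames over a 5 ns run).
DEFAULT_DT = 0.004


class PDBParseError(ValueError):
    """Raised when a PDB file cannot be interpreted."""


class EmptySelectionWarning(UserWarning):
    """Emitted when an atom selection matches nothing."""


@dataclass(frozen=True)
class Atom:
    """A single atom: identity plus Cartesian coordinates in Å."""

    name: str
    element: str
    resid: int
    resname: str
    chain: str
    xyz: tuple[float, float, float]

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("atom name must be non-empty")
        if not np.all(np.isfinite(self.xyz)):
            raise ValueError(f"non-finite coordinates for atom {self.name}")


@dataclass
class Structure:
    """An ordered collection of atoms representing one conformation.

    ``(chain, resid, name)`` is unique within a structure and iteration
    order is stable, so selections are deterministic.
    """

    atoms: list[Atom]
    label: str = ""

    def __post_init__(self) -> None:
        keys = [(a.chain, a.resid, a.name) for a in self.atoms]
        if len(set(keys)) != len(keys):
            seen: set[tuple[str, int, str]] = set()
            for k in keys:
                if k in seen:
                    raise ValueError(f"duplicate atom {k} in structure")
                seen.add(k)

    def __len__(self) -> int:
        return len(self.atoms)

    def __iter__(self):
        return iter(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        """(n_atoms, 3) coordinate array, Å."""
        return np.array([a.xyz for a in self.atoms], dtype=float)

    def with_coords(self, coords: np.ndarray, label: str | None = None) -> "Structure":
        """A copy of this structure with replaced coordinates."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise ValueError(
                f"coordinate shape {coords.shape} does not match {len(self.atoms)} atoms"
            )
        atoms = [replace(a, xyz=tuple(c)) for a, c in zip(self.atoms, coords)]
        return Structure(atoms, label=self.label if label is None else label)

    def chains(self) -> list[str]:
        out: list[str] = []
        for a in self.atoms:
            if a.chain not in out:
                out.append(a.chain)
        return out


@dataclass
class Trajectory:
    """Ordered frames sharing one topology.

    Parameters
    ----------
    topology : Structure
        Defines atom identity and order for every frame.
    coords : ndarray, shape (n_frames, n_atoms, 3)
        Per-frame Cartesian coordinates, Å.
    dt : float
        Time between consecutive frames, ns. Not stored in PDB files, so
        it is always supplied by the caller (default 0.004 ns).
    """

    topology: Structure
    coords: np.ndarray
    dt: float = DEFAULT_DT

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[1:] != (len(self.topology), 3):
            raise ValueError(
                f"coords shape {self.coords.shape} incompatible with "
                f"{len(self.topology)}-atom topology"
            )
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def times(self) -> np.ndarray:
        """Frame times in ns, starting at 0."""
        return np.arange(self.n_frames) * self.dt

    def frame(self, i: int) -> Structure:
        """Frame ``i`` as a Structure."""
        return self.topology.with_coords(self.coords[i], label=f"frame {i}")


@dataclass(frozen=True)
class GrooveDefinition:
    """Where the groove metrics read their atoms.

    The class II binding groove is flanked by one helix from the α chain
    and one from the β chain; ``alpha_helix``/``beta_helix`` are inclusive
    author-numbered residue ranges for those helices. ``framework`` names
    the chains whose Cα atoms anchor superpositions (receptor frame).
    """

    alpha_chain: str
    beta_chain: str
    alpha_helix: tuple[int, int]
    beta_helix: tuple[int, int]
    framework_chains: tuple[str, ...] = ()
    peptide_chain: str | None = None
    ligand_resname: str = "NVP"

    def __post_init__(self) -> None:
        for lo, hi in (self.alpha_helix, self.beta_helix):
            if hi < lo:
                raise ValueError("helix residue range is empty")
        if self.peptide_chain is not None and self.alpha_chain == self.peptide_chain:
            raise ValueError("alpha chain and peptide chain must differ")
        if not self.framework_chains:
            object.__setattr__(
                self, "framework_chains", (self.alpha_chain, self.beta_chain)
            )


#: Helix spans of the canonical HLA-DR architecture (α 46–78, β 54–91),
#: shipped as a named preset; real studies should override to taste.
DRB1_DEFAULT = GrooveDefinition(
    alpha_chain="A",
    beta_chain="B",
    alpha_helix=(46, 78),
    beta_helix=(54, 91),
    peptide_chain="C",
)

GROOVE_PRESETS: dict[str, GrooveDefinition] = {"drb1-default": DRB1_DEFAULT}


# ---------------------------------------------------------------------------
# Reading


def _precheck_coordinate_fields(path: Path) -> None:
    """Validate ATOM/HETATM coordinate columns, naming the offending line."""
    with open(path, "r") as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(("ATOM  ", "HETATM")) and len(line) >= 54:
                for lo, hi in ((30, 38), (38, 46), (46, 54)):
                    try:
                        float(line[lo:hi])
                    except ValueError:
                        raise PDBParseError(
                            f"{path}: malformed coordinate field on line {lineno}: "
                            f"{line.rstrip()!r}"
                        ) from None


def _atoms_from_model(model: gemmi.Model, path: Path) -> list[Atom]:
    """Flatten a gemmi model, resolving altlocs and rejecting icodes.

    Altloc policy: keep the highest-occupancy conformer; ties break toward
    altloc 'A' (then alphabetically). Insertion codes are rejected — the
    synthetic/toy data this package targets never carries them.
    """
    atoms: list[Atom] = []
    for chain in model:
        for residue in chain:
            icode = residue.seqid.icode.strip()
            if icode:
                raise PDBParseError(
                    f"{path}: insertion code {icode!r} at {chain.name} "
                    f"{residue.name} {residue.seqid.num} is not supported"
                )
            best: dict[str, gemmi.Atom] = {}
            for atom in residue:
                prev = best.get(atom.name)
                if prev is None:
                    best[atom.name] = atom
                    continue
                key_new = (atom.occ, -ord(atom.altloc or "A"))
                key_old = (prev.occ, -ord(prev.altloc or "A"))
                if key_new > key_old:
                    best[atom.name] = atom
            for atom in best.values():
                atoms.append(
                    Atom(
                        name=atom.name,
                        element=atom.element.name,
                        resid=residue.seqid.num,
                        resname=residue.name,
                        chain=chain.name,
                        xyz=(atom.pos.x, atom.pos.y, atom.pos.z),
                    )
                )
    return atoms


def _read_gemmi(path: str | Path) -> gemmi.Structure:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    _precheck_coordinate_fields(path)
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError) as exc:
        raise PDBParseError(f"{path}: {exc}") from exc
    if len(st) == 0 or all(st[i].count_atom_sites() == 0 for i in range(len(st))):
        raise PDBParseError(f"{path}: no ATOM/HETATM records found")
    return st


def read_pdb(path: str | Path) -> Structure:
    """Read a single-conformation PDB file.

    Multi-model files are accepted; only the first model is returned
    (use :func:`read_trajectory` for ensembles).
    """
    st = _read_gemmi(path)
    return Structure(_atoms_from_model(st[0], Path(path)), label=Path(path).stem)


def read_trajectory(path: str | Path, dt: float = DEFAULT_DT) -> Trajectory:
    """Read a multi-model PDB as a trajectory.

    Frames are ordered by MODEL number; the topology comes from the first
    model. Every model must contain the same atoms in the same order.
    """
    p = Path(path)
    st = _read_gemmi(p)
    models = [_atoms_from_model(st[i], p) for i in range(len(st))]
    top_atoms = models[0]
    topo = Structure(top_atoms, label=p.stem)
    ids0 = [(a.chain, a.resid, a.name) for a in top_atoms]
    coords = np.empty((len(models), len(top_atoms), 3), dtype=float)
    for k, model_atoms in enumerate(models):
        model_name = st[k].num
        if len(model_atoms) != len(top_atoms):
            raise PDBParseError(
                f"{p}: model {model_name} has {len(model_atoms)} atoms, "
                f"expected {len(top_atoms)} (from model {st[0].num})"
            )
        ids = [(a.chain, a.resid, a.name) for a in model_atoms]
        if ids != ids0:
            raise PDBParseError(
                f"{p}: model {model_name} atom identities differ from model 1"
            )
        coords[k] = [a.xyz for a in model_atoms]
    return Trajectory(topo, coords, dt=dt)


# ---------------------------------------------------------------------------
# Writing


def _to_gemmi(frames: Sequence[Structure]) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = frames[0].label or "groovekit"
    for k, frame in enumerate(frames):
        model = gemmi.Model(k + 1)
        chain_map: dict[str, gemmi.Chain] = {}
        for atom in frame.atoms:
            chain = chain_map.get(atom.chain)
            if chain is None:
                chain = gemmi.Chain(atom.chain)
                model.add_chain(chain)
                # re-fetch: gemmi stores a copy
                chain = model[atom.chain]
                chain_map[atom.chain] = chain
            res = None
            if len(chain) > 0:
                last = chain[len(chain) - 1]
                if last.seqid.num == atom.resid and last.name == atom.resname:
                    res = last
            if res is None:
                res = gemmi.Residue()
                res.name = atom.resname
                res.seqid = gemmi.SeqId(atom.resid, " ")
                res.het_flag = "H" if atom.resname == "NVP" else "A"
                chain.add_residue(res)
                res = chain[len(chain) - 1]
            g = gemmi.Atom()
            g.name = atom.name
            g.element = gemmi.Element(atom.element or "X")
            g.pos = gemmi.Position(*atom.xyz)
            g.occ = 1.0
            g.b_iso = 0.0
            res.add_atom(g)
        st.add_model(model)
    st.setup_entities()
    return st


def write_pdb(
    s: Structure, path: str | Path, bfactors: np.ndarray | None = None
) -> None:
    """Write a structure as PDB; ``bfactors`` optionally fills the B column."""
    st = _to_gemmi([s])
    if bfactors is not None:
        bfactors = np.asarray(bfactors, dtype=float)
        if bfactors.shape != (len(s),):
            raise ValueError("bfactors must have one value per atom")
        i = 0
        for chain in st[0]:
            for res in chain:
                for atom in res:
                    atom.b_iso = float(bfactors[i])
                    i += 1
    st.write_pdb(str(path))


def write_trajectory(t: Trajectory, path: str | Path) -> None:
    """Write a trajectory as a multi-model PDB (MODEL/ENDMDL blocks)."""
    frames = [t.frame(i) for i in range(t.n_frames)]
    _to_gemmi(frames).write_pdb(str(path))


# ---------------------------------------------------------------------------
# Selections


def select_atoms(
    s: Structure,
    chain: str | None = None,
    resid_range: tuple[int, int] | None = None,
    name: str | None = None,
    resname: str | None = None,
    elements_not: Iterable[str] = (),
) -> list[Atom]:
    """Deterministic, order-stable atom selection.

    All criteria are conjunctive; ``resid_range`` is inclusive on both ends
    (author numbering, as helix spans are quoted in the HLA literature).
    """
    excluded = set(elements_not)
    out = [
        a
        for a in s.atoms
        if (chain is None or a.chain == chain)
        and (resid_range is None or resid_range[0] <= a.resid <= resid_range[1])
        and (name is None or a.name == name)
        and (resname is None or a.resname == resname)
        and a.element not in excluded
    ]
    if not out:
        warnings.warn(
            f"selection (chain={chain!r}, resid_range={resid_range!r}, "
            f"name={name!r}, resname={resname!r}) matched no atoms",
            EmptySelectionWarning,
            stacklevel=2,
        )
    return out


def select_calpha(
    s: Structure, chain: str, resid_range: tuple[int, int] | None = None
) -> list[Atom]:
    """Cα atoms of ``chain`` within the inclusive residue range, ordered by resid."""
    atoms = select_atoms(s, chain=chain, resid_range=resid_range, name="CA")
    return sorted(atoms, key=lambda a: a.resid)


def atom_indices(s: Structure, atoms: Iterable[Atom]) -> np.ndarray:
    """Indices of ``atoms`` within ``s`` (for trajectory coordinate slicing)."""
    lookup = {(a.chain, a.resid, a.name): i for i, a in enumerate(s.atoms)}
    return np.array([lookup[(a.chain, a.resid, a.name)] for a in atoms], dtype=int)


def calpha_indices(
    s: Structure, chain: str, resid_range: tuple[int, int] | None = None
) -> np.ndarray:
    """Topology indices of the Cα selection (see :func:`select_calpha`)."""
    return atom_indices(s, select_calpha(s, chain, resid_range))
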