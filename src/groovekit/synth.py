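"""Synthetic groove structures, trajectories and ground-truth oracles.

Real groove trajectories come from force-field MD on crystal structures;
this module builds geometrically idealised stand-ins with *known* ground
truth so every analysis stage is testable without any simulation engine
or download. A synthetic groove is two ideal Cα-trace α-helices (radius
2.3 Å, rise 1.5 Å/residue, 100°/residue) laid antiparallel at a chosen
inter-helical separation, an extended peptide strand (3.4 Å/residue)
running along the groove axis between them, and an optional three-atom
ligand pseudo-molecule parked near mid-groove (a P4-pocket analogue).

Trajectories realise a prescribed separation process

    d(t) = d0 + slope * t + eps_t,   eps_t ~ Normal(0, sigma_d) i.i.d.,

by rigidly displacing the beta helix along the separation axis, with
independent isotropic per-atom jitter on top. The noise is deliberately
time-uncorrelated: it emulates a trajectory's *marginal* mean/SD/slope
structure, not its dynamics. All randomness flows from one seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import ndtr

from .io import Atom, GrooveDefinition, Structure, Trajectory
from .metrics import inter_helical_distance

__all__ = [
    "GrooveSimSpec",
    "build_groove",
    "simulate_trajectory",
    "groove_definition",
    "ligand_occupancy_truth",
    "d0_for_target_mean",
    "analytic_mean",
]

HELIX_RADIUS = 2.3  # Å, Cα trace of an ideal alpha helix
HELIX_RISE = 1.5  # Å per residue
HELIX_TWIST = np.deg2rad(100.0)  # per residue
PEPTIDE_RISE = 3.4  # Å per residue, extended strand
LIGAND_PARK_OFFSET = np.array([60.0, 0.0, 0.0])  # where absent-frame ligands sit


@dataclass(frozen=True)
class GrooveSimSpec:
    """Ground-truth parameters of a synthetic groove trajectory.

    ``residue_jitter`` is an isotropic per-coordinate SD in Å: a scalar
    applied to every protein residue, optionally overridden per residue
    via ``jitter_overrides`` keyed by (chain, resid).
    """

    n_res_alpha: int = 33
    n_res_beta: int = 38
    d0: float = 13.0  # initial inter-helical separation, Å
    slope: float = 0.0  # drift, Å/ns
    sigma_d: float = 0.0  # per-frame separation noise SD, Å
    residue_jitter: float = 0.0
    jitter_overrides: tuple[tuple[tuple[str, int], float], ...] = ()
    n_frames: int = 1250
    dt: float = 0.004  # ns
    peptide_len: int = 13
    ligand: bool = True
    ligand_presence: float = 1.0  # fraction of frames the ligand is in-groove
    ligand_jitter: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.sigma_d < 0 or self.residue_jitter < 0 or self.ligand_jitter < 0:
            raise ValueError("noise SDs must be non-negative")
        if not (0.0 <= self.ligand_presence <= 1.0):
            raise ValueError("ligand_presence must lie in [0, 1]")

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.dt


def groove_definition(spec: GrooveSimSpec) -> GrooveDefinition:
    """The GrooveDefinition matching :func:`build_groove` output."""
    return GrooveDefinition(
        alpha_chain="A",
        beta_chain="B",
        alpha_helix=(1, spec.n_res_alpha),
        beta_helix=(1, spec.n_res_beta),
        peptide_chain="C" if spec.peptide_len > 0 else None,
        ligand_resname="NVP",
    )


def _helix_trace(n_res: int, y_axis: float, reverse: bool) -> np.ndarray:
    i = np.arange(n_res, dtype=float)
    x = (i - (n_res - 1) / 2.0) * HELIX_RISE
    if reverse:
        x = -x
    theta = i * HELIX_TWIST
    y = y_axis + HELIX_RADIUS * np.cos(theta)
    z = HELIX_RADIUS * np.sin(theta)
    return np.column_stack([x, y, z])


def _assemble(spec: GrooveSimSpec, axis_sep: float) -> Structure:
    atoms: list[Atom] = []

    def add_chain(coords: np.ndarray, chain: str, resname: str = "ALA") -> None:
        for r, xyz in enumerate(coords, start=1):
            atoms.append(
                Atom(
                    name="CA",
                    element="C",
                    resid=r,
                    resname=resname,
                    chain=chain,
                    xyz=tuple(xyz),
                )
            )

    add_chain(_helix_trace(spec.n_res_alpha, +axis_sep / 2, reverse=False), "A")
    add_chain(_helix_trace(spec.n_res_beta, -axis_sep / 2, reverse=True), "B")
    if spec.peptide_len > 0:
        p = np.arange(spec.peptide_len, dtype=float)
        pep = np.column_stack(
            [
                (p - (spec.peptide_len - 1) / 2.0) * PEPTIDE_RISE,
                np.zeros_like(p),
                np.zeros_like(p),
            ]
        )
        add_chain(pep, "C")
    if spec.ligand:
        for j, dx in enumerate((-1.2, 0.0, 1.2), start=1):
            atoms.append(
                Atom(
                    name=f"C{j}",
                    element="C",
                    resid=1,
                    resname="NVP",
                    chain="D",
                    xyz=(dx, 0.0, 3.0),
                )
            )
    return Structure(atoms, label="synthetic groove")


def build_groove(spec: GrooveSimSpec) -> Structure:
    """Build the idealised groove with its metric calibrated to ``d0``.

    The helix-axis separation is iterated so that the *inter-helical
    distance metric* of the built structure equals ``spec.d0`` (the metric
    averages nearest-neighbour Cα distances, which differ slightly from
    the axis separation because of the helical wobble).
    """
    g = groove_definition(spec)
    sep = spec.d0
    for _ in range(12):
        s = _assemble(spec, sep)
        err = spec.d0 - inter_helical_distance(s, g)
        if abs(err) < 1e-9:
            break
        sep += err
    return _assemble(spec, sep)


def _per_atom_jitter_sd(spec: GrooveSimSpec, topology: Structure) -> np.ndarray:
    overrides = dict(spec.jitter_overrides)
    sd = np.zeros(len(topology))
    for i, a in enumerate(topology.atoms):
        if a.chain == "D":
            sd[i] = spec.ligand_jitter
        else:
            sd[i] = overrides.get((a.chain, a.resid), spec.residue_jitter)
    return sd


def simulate_trajectory(spec: GrooveSimSpec) -> Trajectory:
    """Realise a groove trajectory with the spec's ground-truth process.

    Per frame: the beta helix is rigidly displaced along the separation
    axis so the groove separation follows d0 + slope*t + eps; every
    protein atom then receives independent isotropic Gaussian jitter; the
    ligand is present with probability ``ligand_presence`` (absent frames
    park it 60 Å outside the groove — the trajectory atom set is
    constant, so absence is encoded positionally).
    """
    base = build_groove(spec)
    X0 = base.coords
    rng = np.random.default_rng(spec.seed)
    n, na = spec.n_frames, len(base)

    eps = rng.normal(0.0, spec.sigma_d, size=n) if spec.sigma_d > 0 else np.zeros(n)
    delta = spec.slope * spec.times + eps

    present = (
        rng.random(n) < spec.ligand_presence
        if spec.ligand
        else np.zeros(n, dtype=bool)
    )

    sd = _per_atom_jitter_sd(spec, base)
    jitter = (
        rng.standard_normal((n, na, 3)) * sd[None, :, None]
        if np.any(sd > 0)
        else None
    )

    beta_mask = np.array([a.chain == "B" for a in base.atoms])
    ligand_mask = np.array([a.chain == "D" for a in base.atoms])

    coords = np.broadcast_to(X0, (n, na, 3)).copy()
    # beta helix sits on the -y side: moving it further -y opens the groove
    coords[:, beta_mask, 1] -= delta[:, None]
    if spec.ligand and not np.all(present):
        for k in np.where(~present)[0]:
            coords[k, ligand_mask, :] = X0[ligand_mask] + LIGAND_PARK_OFFSET
    if jitter is not None:
        coords += jitter
    return Trajectory(base, coords, dt=spec.dt)


def analytic_mean(spec: GrooveSimSpec) -> float:
    """Expected trajectory-mean separation: d0 + slope * mean(times)."""
    return spec.d0 + spec.slope * float(spec.times.mean())


def d0_for_target_mean(
    target_mean: float, slope: float, n_frames: int, dt: float
) -> float:
    """The d0 making the analytic trajectory-mean equal ``target_mean``."""
    mean_t = (n_frames - 1) / 2.0 * dt
    return target_mean - slope * mean_t


def ligand_occupancy_truth(spec: GrooveSimSpec, grid) -> np.ndarray:
    """Closed-form expected occupancy of every voxel of ``grid``.

    For a grid built from an *unaligned* trajectory of this spec with the
    ligand selected: each ligand atom lands near its home position (or the
    parked position in absent frames) with independent isotropic Gaussian
    jitter, so the expected per-voxel occupancy is

        p * P(>=1 atom in v | home) + (1 - p) * P(>=1 atom in v | parked)

    with per-atom box probabilities given by products of normal CDFs.
    Only exact when the receptor separation process does not move the
    ligand (it never does — the ligand rides chain D).
    """
    if not spec.ligand:
        raise ValueError("spec has no ligand")
    base = build_groove(spec)
    lig = np.array(
        [a.xyz for a in base.atoms if a.chain == "D"], dtype=float
    )
    sigma = spec.ligand_jitter

    def box_prob(centers: np.ndarray) -> np.ndarray:
        """P(>=1 atom in voxel) for every voxel, atoms independent."""
        nx, ny, nz = grid.dims
        lo = [grid.origin[d] + np.arange(grid.dims[d]) * grid.spacing for d in range(3)]
        p_not = np.ones(grid.dims)
        for mu in centers:
            if sigma == 0:
                ijk = np.floor((mu - grid.origin) / grid.spacing).astype(int)
                p_atom = np.zeros(grid.dims)
                if all(0 <= ijk[d] < grid.dims[d] for d in range(3)):
                    p_atom[tuple(ijk)] = 1.0
            else:
                per_axis = [
                    ndtr((lo[d] + grid.spacing - mu[d]) / sigma)
                    - ndtr((lo[d] - mu[d]) / sigma)
                    for d in range(3)
                ]
                p_atom = np.einsum("i,j,k->ijk", *per_axis)
            p_not *= 1.0 - p_atom
        return 1.0 - p_not

    p = spec.ligand_presence
    expected = p * box_prob(lig)
    if p < 1.0:
        expected = expected + (1.0 - p) * box_prob(lig + LIGAND_PARK_OFFSET)
    return expected
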