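"""Drug-induced peptide displacement between trimer and dimer structures.

Compares where each ligand-peptide residue sits with the drug present
(trimer: HLA + peptide + drug) versus absent (dimer: HLA + peptide).
Both structures are superposed on the receptor framework — all HLA α- and
β-chain Cαs — and the per-residue displacement is the distance between
corresponding peptide Cαs. Small values mean the drug barely perturbs the
bound peptide.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import superpose
from .io import GrooveDefinition, Structure, select_calpha

__all__ = ["DisplacementTable", "peptide_displacement", "encode_bfactor"]


@dataclass
class DisplacementTable:
    """Per-residue Cα displacement of the peptide, Å.

    ``clamp_range`` is the colour-encoding window used when the table is
    baked into a B-factor column (default 0–10 Å); raw values are always
    kept unclamped here.
    """

    resids: np.ndarray
    resnames: list[str]
    displacement: np.ndarray
    clamp_range: tuple[float, float] = (0.0, 10.0)

    def __post_init__(self) -> None:
        self.resids = np.asarray(self.resids, dtype=int)
        self.displacement = np.asarray(self.displacement, dtype=float)
        if np.any(self.displacement < 0):
            raise ValueError("displacements must be non-negative")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "resid": self.resids,
                "resname": self.resnames,
                "displacement_A": self.displacement,
            }
        )


def _framework_coords(s: Structure, g: GrooveDefinition) -> np.ndarray:
    atoms = []
    for chain in g.framework_chains:
        atoms.extend(select_calpha(s, chain))
    if not atoms:
        raise ValueError("framework selection is empty")
    return np.array([a.xyz for a in atoms], dtype=float)


def peptide_displacement(
    trimer: Structure, dimer: Structure, g: GrooveDefinition
) -> DisplacementTable:
    """Per-residue peptide Cα displacement of ``trimer`` relative to ``dimer``.

    The trimer is superposed onto the dimer using the HLA framework Cαs
    only, so the statistic reports genuine peptide motion within the
    groove, not a global rigid drift.
    """
    if g.peptide_chain is None:
        raise ValueError("groove definition has no peptide chain")
    fw_t = _framework_coords(trimer, g)
    fw_d = _framework_coords(dimer, g)
    if fw_t.shape != fw_d.shape:
        raise ValueError(
            f"framework size mismatch: {fw_t.shape[0]} vs {fw_d.shape[0]} Cα atoms"
        )
    pep_t = select_calpha(trimer, g.peptide_chain)
    pep_d = select_calpha(dimer, g.peptide_chain)
    rid_t = [a.resid for a in pep_t]
    rid_d = [a.resid for a in pep_d]
    if rid_t != rid_d:
        only_t = sorted(set(rid_t) - set(rid_d))
        only_d = sorted(set(rid_d) - set(rid_t))
        raise ValueError(
            "peptide residue sets differ between trimer and dimer "
            f"(trimer-only: {only_t}, dimer-only: {only_d})"
        )
    fit = superpose(fw_t, fw_d)
    xt = fit.apply(np.array([a.xyz for a in pep_t], dtype=float))
    xd = np.array([a.xyz for a in pep_d], dtype=float)
    disp = np.linalg.norm(xt - xd, axis=1)
    return DisplacementTable(
        resids=np.array(rid_t),
        resnames=[a.resname for a in pep_t],
        displacement=disp,
    )


def encode_bfactor(
    s: Structure, table: DisplacementTable, g: GrooveDefinition
) -> np.ndarray:
    """Per-atom B-factor channel carrying the clamped displacements.

    Peptide atoms get their residue's displacement clamped to the table's
    ``clamp_range``; every other atom gets 0. Pass the result to
    :func:`groovekit.io.write_pdb` to produce a colourable structure.
    """
    lo, hi = table.clamp_range
    by_resid = dict(zip(table.resids.tolist(), table.displacement.tolist()))
    b = np.zeros(len(s.atoms))
    for i, atom in enumerate(s.atoms):
        if atom.chain == g.peptide_chain and atom.resid in by_resid:
            b[i] = float(np.clip(by_resid[atom.resid], lo, hi))
    return b
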