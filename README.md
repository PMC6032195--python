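# groovekit

Analysis toolkit for the peptide-binding groove of MHC class II (HLA-DR)
molecules. Small drugs such as the anti-HIV agent nevirapine can bind
inside the groove and reshape it — a proposed mechanism for HLA-linked
drug hypersensitivity. `groovekit` implements the quantitative pipeline
used to characterise that reshaping from structure ensembles:

- **Groove geometry** — the inter-helical distance metric
  d = mean over α-helix Cα atoms of the distance to the nearest β-helix
  Cα, its per-frame time series, and mean ± SD / OLS-slope summaries
  (Å and Å/ns) that quantify groove opening or closing.
- **Fluctuation analysis** — Kabsch superposition, RMSD time series,
  per-residue RMSF about the iteratively refined mean structure, and the
  *representative structure* of a trajectory window (the medoid under
  pairwise Cα RMSD).
- **Occupancy volumes** — voxel maps of the fraction of frames a ligand
  or peptide occupies each cell of a receptor-frame grid, and the 50%
  occupancy isovolume (OpenDX output for PyMOL/VMD).
- **Peptide displacement** — per-residue Cα displacement of the bound
  peptide between drug-bound (trimer) and drug-free (dimer) structures
  after superposing on the HLA framework, optionally baked into a PDB
  B-factor column (clamped 0–10 Å for colouring).
- **Register scanning** — sliding the peptide along the groove's
  principal axis in residue-sized steps, scoring each candidate register
  by steric clashes and contacts with the α/β walls, and mapping a P1
  anchor to the P1–P9 pocket assignment.
- **Assay statistics** — %-of-control normalisation and a two-tailed
  Dunnett many-to-one test (equicorrelated multivariate-t quadrature
  with a seeded Monte Carlo cross-check), including a fixed-reference
  mode for published tables that print treatment mean ± SD but no
  control SD.
- **Synthetic groove generator** — idealised two-helix grooves whose
  separation follows d(t) = d₀ + slope·t + ε, ε ~ N(0, σ²), with known
  per-residue jitter and ligand presence, so every stage is testable
  against ground truth without an MD engine.

Structures and multi-model-PDB trajectories are read and written with
[gemmi]. The intended audience is structural immunology / pharmacology
groups analysing HLA–drug–peptide ensembles, and anyone needing a
self-contained, oracle-tested reference for these metrics.

## Worked example

Simulate a drug-bound-like groove (5 ns at 0.004 ns/frame, separation
drifting −0.14 Å/ns around a 13.1 Å mean with 0.4 Å noise) and summarise
its inter-helical distance:

```sh
$ cat spec.yaml
d0: 13.45
slope: -0.14
sigma_d: 0.4
n_frames: 1250
seed: 42

$ groove simulate --spec spec.yaml --out traj.pdb
wrote 1250 frames x 87 atoms ...

$ groove iheld --traj traj.pdb --groove groove.yaml
{
  "mean": 13.095606208838303,
  "sd": 0.43606664409654905,
  "slope": -0.13777996980713397,
  "n_frames": 1250
}
```

The recovered mean (13.10 Å), SD (0.44 Å) and slope (−0.138 Å/ns) match
the generator's ground truth (analytic mean 13.10 Å, σ 0.4 Å, slope
−0.14 Å/ns) to within sampling error — a negative slope of this size is
the signature of a slow groove-closing motion over a 5 ns window.

Small-molecule arithmetic for nevirapine (C15H14N4O):

```sh
$ groove chem --formula C15H14N4O --ugml 100
{
  "formula": "C15H14N4O",
  "average_mass_g_mol": 266.304,
  "monoisotopic_mass_Da": 266.1168,
  "protonated_mz": 267.124,
  "micromolar": 375.5107
}
```

i.e. a nominal 100 μg/mL dose is 375.5 μM, and the LC-MS/MS precursor
ion [M+H]+ sits at m/z 267.1.

Other subcommands: `groove rmsf`, `groove rmsd`, `groove medoid`,
`groove occupancy`, `groove displace`, `groove register`,
`groove assay`. Every subcommand is a thin wrapper over the library API
(`import groovekit`).

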