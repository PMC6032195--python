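# Methods

This note documents the models and procedures groovekit implements, the
defaults and why they were chosen, and what the synthetic generator does
and does not emulate.

## The groove and its geometry

An MHC class II binding groove is flanked by one α-chain helix and one
β-chain helix over a β-sheet floor; a peptide binds between them in an
extended conformation, its nine-residue core occupying pockets P1–P9.
A `GrooveDefinition` names the two chains, their helix residue ranges
(inclusive, author/PDB numbering — the convention in which HLA helix
spans are quoted), the framework chains used for superposition, and the
peptide chain. The shipped preset `drb1-default` uses the canonical
HLA-DR architecture (α 46–78, β 54–91); helix spans differ slightly
between studies, so the preset is configuration, not a constant.

**Inter-helical distance.** For each Cα of the α-chain helix, take the
Euclidean distance to the *nearest* Cα of the β-chain helix; the metric
is the mean over α-helix Cαs. It is deliberately directional (α→β):
averaging nearest-neighbour distances from the longer helix would weight
the walls differently. A symmetrised variant (mean of both directions)
exists behind a flag but is never the default. The metric is invariant
to rigid motion of the frame and, on parallel-row toys, responds exactly
one-for-one to rigid separation changes.

**Series summaries.** A distance (or any per-frame scalar, e.g.
externally computed energies) paired with its time axis is summarised as
mean, sample SD (n−1), and the ordinary-least-squares slope of value on
time, in Å/ns. No detrending or smoothing is applied — the slope is read
off the raw curve, so a negative slope directly reports a net closing
motion over the window.

## Superposition, RMSF, representative structures

Superposition is the standard Kabsch fit: SVD of the cross-covariance of
centred point sets, with the reflection case (det = −1) corrected by
flipping the smallest singular vector. The residual is computed directly
from the transformed coordinates rather than from the trace identity,
which loses precision near zero RMSD.

RMSF uses the mean-structure convention: frames are superposed onto the
running mean, the mean recomputed, iterating until the mean shifts by
less than 1e-6 Å. This removes the arbitrary choice of a reference frame;
a first-frame mode is available (`use_mean_structure=False`). For i.i.d.
isotropic jitter of per-coordinate SD σ the expected per-atom RMSF is
σ√3, shrunk by √(1 − 6/(3N)) because the rigid-body fit absorbs six
degrees of freedom — about 3% for a 30-residue selection. Tests assert
recovery within 5% at 2000 frames, which accommodates exactly this.

The *representative structure* of a trajectory window (default: the
final 1000 frames) is the medoid: the in-window frame minimising mean
pairwise Cα RMSD to the other in-window frames, ties broken toward the
lowest index. "Most representative" has no unique definition; the medoid
is the common, deterministic choice and is validated against brute-force
enumeration. Pairwise RMSDs use a batched Kabsch (stacked 3×3 SVDs), so
a 1000-frame window is interactive on one CPU.

## Occupancy volumes

A voxel's occupancy is the fraction of frames in which at least one
selected atom *centre* lies inside it (multiple atoms in one voxel in
one frame count once). The grid spans the selection's all-frame bounding
box plus padding; spacing defaults to 1.0 Å. Frames are first superposed
on the receptor framework so the map lives in the receptor's frame —
without this, receptor tumbling smears the envelope into
meaninglessness. Atom-centre counting, spacing and alignment are all
configurable since conventions differ between tools. The isovolume at
threshold τ is the set of voxels with occupancy ≥ τ (inclusive at the
boundary, tested there) and its volume is count × spacing³; the 50%
isovolume is the usual "occupancy envelope". Isovolumes nest as the
threshold grows.

## Peptide displacement

Drug-induced peptide displacement compares a drug-bound trimer
(HLA + peptide + drug) to the drug-free dimer: the trimer is superposed
onto the dimer on the *framework* — all HLA α+β Cαs, not just the
helices, for a stable fit, and never the peptide itself — and each
peptide residue's displacement is the distance between corresponding
Cαs. Tests pin the superposition set: moving only the peptide changes
the result, moving everything rigidly does not. For visualisation the
values are clamped to 0–10 Å and written to the PDB B-factor column;
raw values are always retained in the CSV. The pipeline defaults to
comparing medoid representatives but accepts any pair of structures.

## Register scanning and pockets

Because the class II groove is open-ended, the bound peptide's register
is ambiguous. `enumerate_registers` slides the peptide rigidly along the
groove's principal axis — the largest-variance eigenvector of the
combined helix Cα cloud, signed toward increasing α-helix residue
number — in steps of 3.4 Å (the extended-peptide rise, so one step ≈ one
register shift; configurable). Each offset in [−k, +k] is scored:
clashes are peptide/HLA heavy-atom pairs closer than 2.5 Å, contacts
pairs closer than 4.5 Å split by wall. Ranking is lexicographic: fewest
clashes, most total contacts, then the larger min(α, β) contact count —
rewarding poses that grip both walls — with |offset| as the
deterministic tie-break. This is a geometric pre-screen; energetic
re-scoring of surviving registers (by MD or docking) is deliberately out
of scope. Offsets are labelled relative to the input pose
("offset−1", "offset+2"); any external "frame n" nomenclature can be
layered on by the user, since such numbering has no intrinsic origin.

`assign_pockets` maps a chosen 1-based P1 anchor position to the nine
consecutive core residues P1..P9, e.g. HA 306–318 (PRYVKQNTLKLAT) with
P1 at position 3 gives P1–P5 = Tyr-Val-Lys-Gln-Asn and P9 = Leu.

## Small-molecule arithmetic

Atomic masses (IUPAC 2021 average weights; principal-isotope
monoisotopic masses) are pinned in-code so results are bit-stable.
Mass concentration converts to molarity as μM = (μg/mL) / (g/mol) ×
1000; for nevirapine (C15H14N4O, 266.304 g/mol) 100 μg/mL ↔ 375.5 μM.
The [M+H]+ m/z is the monoisotopic mass plus 1.00728; fragment ions are
not modelled.

## Dunnett statistics

Competitive-binding readouts are normalised to % of the vehicle (DMSO)
control and each dose compared to control with a two-tailed Dunnett
test. Writing the many-to-one statistics as
T_i = (λ_i Z₀ + √(1−λ_i²) Z_i)/U with U = S/σ and
λ_i = √(n_i/(n_i+n₀)) — the n-weighted generalisation of the equal-n
correlation ½ — the family-wise adjusted p is P(max_i |T_i| ≥ |t_obs|),
evaluated by Gauss–Hermite × chi quadrature. Numerical choices that
matter:

- the chi integral uses a composite rule with log-spaced nodes in the
  lower tail, because extreme t tails are dominated by small pooled-SD
  draws that a linear probability-scale rule cannot resolve;
- everything is computed in complement form (log1p/expm1), so p-values
  far below machine epsilon of 1 keep relative accuracy;
- beyond the quadrature's resolution (family-wise p < 1e-8) the union
  bound k·P(|t_df| > q) is returned — there it is exact to within
  O(q^(−2df)/q^(−df)) and scipy's t tail carries the precision;
- a seeded Monte Carlo estimator of the same probability serves as a
  cross-check (tests require agreement within 0.002 at 10⁶ draws), and
  replicate-mode results are cross-validated against an independent
  implementation of the same test.

*Fixed-reference mode* handles published tables that print treatment
mean ± SD on the %-of-control scale but no control SD: the control is
treated as the exact constant 100, variance is pooled across treatment
groups only, and λ = 0 (no shared control noise). This slightly
understates uncertainty when the control truly varies — the caveat is
accepted because it is the only mode such a table supports, and the
headline comparison (t ≈ 30 at df = 12) is insensitive to it; an n = 8
reading of the replicate count only strengthens it.

## The synthetic generator

`GrooveSimSpec`/`simulate_trajectory` emulate the statistical structure
of a groove trajectory, not its physics. The groove is two ideal Cα
helices (radius 2.3 Å, rise 1.5 Å/residue, twist 100°/residue, 33 and 38
residues — matching the preset helix span lengths) antiparallel at a
separation *calibrated so the inter-helical metric equals d₀ exactly*,
with a 13-mer extended peptide strand along the groove axis and an
optional 3-atom ligand pseudo-molecule near mid-groove (a P4-pocket
analogue). Per frame, the β helix is rigidly displaced along the
separation axis so the separation follows d₀ + slope·t + ε_t with
ε_t ~ N(0, σ_d²) i.i.d.; per-residue isotropic jitter and per-frame
ligand presence (absent frames park the ligand 60 Å outside the groove,
keeping the atom set constant) come from the same single seed, making
multi-model PDB output byte-identical across runs.

Default study conditions follow the 5-ns trajectory setting the toolkit
targets: 1250 frames at dt = 0.004 ns (dt is never stored in PDB, so it
is always a user parameter), separation SD 0.4 Å, and d₀ chosen via
`d0_for_target_mean` so the analytic trajectory mean
d₀ + slope·⟨t⟩ lands on the desired value (13.1 Å drug-bound,
13.0 Å apo, slopes −0.14 and −0.12 Å/ns).

What the generator does *not* emulate, and hence what passing tests do
not show about real data: time-correlated (autocorrelated) fluctuations —
noise is i.i.d., so SDs are matched marginally, not dynamically; side
chains (models are Cα-only plus ligand pseudo-atoms, so contact counts
are much sparser than in all-atom structures); anharmonic or multi-state
dynamics; and any force-field physics. Parameter-recovery tests (20-seed
coverage of nominal 95% intervals) validate the estimators, not MD.

The inter-helical metric is not perfectly linear in the rigid β-helix
displacement (nearest-neighbour pairings carry small transverse
offsets); the effective derivative is ≈0.97 at the default geometry,
biasing recovered slopes by ~3% of their value and trajectory means by
~0.005 Å — an order of magnitude inside the 0.1 Å recovery tolerance,
and verified by the noiseless-generator tests.

## Degenerate inputs and edge behaviour

Empty atom selections warn explicitly rather than silently propagating;
empty helix selections are errors. Superposition requires ≥3
non-degenerate points; the groove axis requires an anisotropic Cα cloud.
Multi-model readers verify a constant atom set and name the offending
model on mismatch; malformed coordinate fields name the line. Altlocs
keep the highest-occupancy conformer (ties → 'A'); insertion codes are
rejected outright — the toy and synthetic structures this package
targets never carry them, and silently renumbering would corrupt
author-numbered helix ranges.

## Problem sizes

The shipped tests and the acceptance script run at the study's native
scale where that is cheap (1250-frame series, 10⁴-family error
calibration, 10⁶-draw Monte Carlo cross-checks) and at reduced scale
where exhaustive oracles are quadratic (100-frame medoid windows,
20-seed recovery sweeps); the full suite completes in well under a
minute on one CPU.
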