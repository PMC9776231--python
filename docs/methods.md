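# Methods

`mdinteract` re-implements, as a tested library, the post-simulation analyses
used to characterize how an amyloid-β (Aβ) dimer trapped inside the chamber of
insulin-degrading enzyme (IDE) interacts with the enzyme's four domains, and
how the relative populations of competing dimer conformers follow from their
conformational energies.  This note records the models, the parameters that
matter, and the design choices made where the procedure was genuinely open.

## Inputs and in-memory model

Trajectories are consumed as multi-model PDB files: one MODEL per saved frame,
constant topology across frames, 1-based residue numbering.  Frames are
stamped `(model − 1) × frame_interval` ps with a 10 ps default frame interval
(the saved-frame spacing of the underlying simulations).  HETATM records,
waters and ions are dropped on read; alternate locations keep the
highest-occupancy conformer; insertion codes are rejected outright because the
target systems do not use them and silently merging them would corrupt residue
numbering.  Conformational energies arrive as a plain CSV
(`conformer_label,energy_kcal_mol`) — energy evaluation itself (implicit-solvent
GBMV with a SASA term) happens upstream and is out of scope here.

Two region schemes ship as defaults: the enzyme's four domains
(43–285, 286–515, 542–768, 769–1016; domains 1–2 form the N-terminal half
IDE-N, domains 3–4 the C-terminal half IDE-C) and the peptide's
N-/C-terminal split after residue K16 of the 42-residue Aβ chain.

## Superposition, RMSD, RMSF

Rigid-body fits use the Kabsch (SVD) solution, computed via
`scipy.spatial.transform.Rotation.align_vectors` on centered coordinates; the
residual is re-evaluated from the fitted coordinates because the SVD-derived
residual loses half its significant digits near zero.  Fits are on Cα atoms
by default: the source procedure never states the fitted atom set, the
surrounding analyses are Cα-centric, and the choice is configurable.
Identical mobile/reference inputs short-circuit to the identity transform, so
a static trajectory reports exactly zero RMSD and RMSF rather than
floating-point dust.  Degenerate (collinear, < 3 point) selections are
rejected, since the optimal rotation is not unique there.

RMSF is taken about an iteratively refined mean structure (superpose all
frames on the running mean, recompute, tolerance 10⁻⁶ Å; two iterations
normally converge).  A mean reference avoids biasing fluctuations toward an
arbitrarily chosen frame; per-domain RMSD fits on that domain's own Cα atoms
so that each domain's convergence is tracked in its own frame of reference.

## Secondary structure

Assignment follows the classical hydrogen-bond-pattern method: a backbone
N-H···O=C pair is scored with the dipole electrostatic model

E = q₁q₂f (1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN),  q₁q₂f = 27.888 kcal·Å/mol,

bonded when E < −0.5 kcal/mol.  Missing amide hydrogens are synthesized
1.0 Å from N opposite the bisector of the C(prev)–N–Cα angle (minimized
frames often lack hydrogens); a test confirms the synthesized and explicit
hydrogen give the same bonding verdict on an ideal helix.  Two consecutive
i→i+4 turns label residues i+1…i+4 as H; residues in parallel or
antiparallel bridge ladders of at least two consecutive bridges are E;
everything else — including 3₁₀/π helices, turns and bends — is C, since only
α/β percentages are analysed downstream.  Chains under five residues are all
C; pairs closer than i±2 along a chain are excluded, as are pairs whose Cα
atoms are over 9 Å apart (no backbone H-bond can span that).  Windowed
percentages are per-residue frame fractions; a whole-chain mean is also
exposed because the reported percentages can be read either way.

Note one consequence of the two-consecutive-turns rule: the shortest
assignable α-helix spans six residues, so a five-residue ideal helix
correctly assigns no H.

## Interaction occurrence maps and the contact rubric

All cutoffs are inclusive (≤) and configurable; defaults are the study's:

| criterion | measured between | cutoff |
|---|---|---|
| hydrophobic | Cα–Cα of two hydrophobic residues | 10 Å |
| electrostatic | side-chain charged-group atoms, opposite charges | 4 Å |
| hydrogen bond | donor H to acceptor N/O | 2.4 Å |

The *occurrence* of a pair is the percentage of frames satisfying its
criterion, and is always an exact frame fraction.  The hydrophobic inventory
is A, V, L, I, M, F, W, Y, P (tyrosine and proline included so aromatic and
ring contacts are not dropped; glycine excluded for having no side chain);
the source never lists a membership, so it is configurable.  Charged groups
are Asp/Glu carboxylate oxygens against Lys NZ, Arg NE/NH1/NH2 and His
ND1/NE2; histidine is treated as positively charged by default and can be
excluded.  Hydrogen bonds are purely distance-based (no angle term), matching
the single-cutoff definition; explicit hydrogens are required, and their
donors are identified by a 1.25 Å covalency test against N/O.

Region-level contacts are graded by four rules: (1) the side chains face each
other — the Cα→side-chain-centroid vector of each residue within 90° of the
direction to the partner's Cα, summarized per pair as the fraction of facing
frames and thresholded at 0.5; (2) the pair registers nonzero occurrence
under the Cα cutoff; (3) the number of qualifying pairs between the two
regions; and (4) their occurrence percentage.  *Strong* requires ≥ 2
qualifying pairs at ≥ 85% occurrence; any qualifying pair short of that is
*weak*; none is *none*.  The strong and weak conditions as stated overlap at
exactly (2 pairs, 85%): that case grades strong, reading the ≥ of the strong
rule as governing.  Rule 3's "number of interactions" is read as the count of
qualifying residue pairs between two regions, because contacts are reported
at region (domain) level.  An exhaustive independent enumeration of the four
rules, run over 1,000 randomized instances, agrees with the implementation
exactly, including the boundary.

## Open/closed chamber gauges

Six named descriptors track the chamber geometry: Cα–Cα distances H134–K884,
F424–G615, V410–A614, K353–K657 spanning the IDE-N/IDE-C mouth, and the
hinge angles E176–A403–S721 and A403–S721–D876.  Cα is used because the
descriptors are named by residue, not atom.  No numeric open/closed threshold
is asserted — none is defined — so the module reports traces and per-window
mean/SD; a user-supplied threshold can label frames.

## Conformer populations by Metropolis Monte Carlo

Each conformer contributes its saved conformations with precomputed energies.
The walk starts at a uniformly random conformation of the pooled ensemble;
each step proposes a uniformly random conformation of a uniformly random
*other* conformer and accepts when e^−(Eⱼ−Eᵢ)/kT exceeds a uniform(0,1) draw
(Metropolis; factors above 1 always accepted).  The occupied conformer is
tallied every step, rejected moves included, so ΣN_n equals the step count
and P_n = N_n/N_total.  Defaults: T = 298 K, 10⁶ steps,
k_B = 0.0019872041 kcal/(mol·K).

The proposal — uniform over other conformers, then uniform within — is
symmetric, so the stationary distribution is the Boltzmann measure over all
pooled conformations.  `exact_populations` evaluates that measure in closed
form (energies shifted by their minimum before exponentiation, so the sum is
overflow-free) and serves as the independent oracle: at the study scale of
7 conformers × 500 conformations the 10⁶-step walk stays within 0.01 of it.
No burn-in is applied, matching the literal procedure; with a uniform random
start and 10⁶ steps the initialization bias is far below the Monte Carlo
error, which the oracle comparison enforces.  Whether only accepted moves or
every step is counted is ambiguous in the source; every-step counting is used
because it is what makes the visit counts sum to the step total, and both
conventions share the same stationary populations.  Standard errors come
from 10 batch means, appropriate for an autocorrelated chain.  Relative free
energies are ΔG_n = −kT ln(P_n/P_max), zero for the most populated conformer;
zero-population conformers are flagged unbounded rather than raising.

## Synthetic data

The generators produce the study *conditions* with known ground truth; they
emulate bookkeeping, not force-field physics:

* **Dimer trajectories** — two 42-residue chains of hydrophobic residues with
  single pseudo-atom side chains pointed at the partner (so facing is exactly
  controllable), plus a minimal N/H/O backbone.  Scheduled pairs sit at their
  contact distance in exactly `round(occupancy × n_frames / 100)` frames
  (seeded permutation, so occurrences are exact rather than binomial) and at
  their apart distance otherwise; isotropic Gaussian noise is added on top.
  Defaults: 100 frames, 5 Å contact / 15 Å apart against the 10 Å cutoff.
* **Ideal helix/sheet backbones** — built from internal coordinates
  (φ = −57°, ψ = −47° helical; φ = −139°, ψ = 135° extended) with standard
  bond geometry and explicit amide hydrogens.  The sheet partner strand is
  placed by a deterministic rigid-body fit that drives the register's
  H-bonds to near-linear 1.95 Å H···O geometry (antiparallel strands related
  by a two-fold about the sheet normal; parallel by translation).
* **Open/closed toy** — four rigid pseudo-domains carrying the gauge
  residues; the C-terminal half swings 100° about a hinge above the chamber,
  which at least doubles every cross-chamber gauge distance and shifts the
  hinge angles by > 20°.
* **Energy ensembles** — Gaussian energies per conformer; the default is the
  study scale (7 conformers × 500 conformations, means spanning 3 kcal/mol,
  spread 1 kcal/mol).  `exact_populations` of the output is the recovery
  target.  Note that equal *means* with nonzero spread do not give exactly
  uniform populations at finite sample size — the Boltzmann weight of a
  finite Gaussian sample is dominated by its low-energy tail — so exact
  uniformity is only asserted at zero spread.

What passing these tests does *not* show: real trajectories have correlated,
anisotropic fluctuations, real side chains are articulated, and real contact
lifetimes are autocorrelated rather than scheduled.  The synthetic results
validate the measurement machinery, not any biological conclusion.

## Pipeline determinism and problem sizes

All randomness flows from one top-level seed (only the population stage is
stochastic), CSV formatting is fixed, and the manifest contains no
timestamps, so identical config + seed reproduces outputs byte for byte.
Desk-scale defaults keep the full test suite and the acceptance script to a
few minutes on one CPU: 100-frame dimer trajectories, 8 + 8 sheet strands,
10⁶-step walks over 3,500 conformations.

## Known limitations

* Three-state (H/E/C) assignment only; no solvent accessibility, no
  eight-state classes.
* Hydrogen bonds ignore angles; π-stacking, cation–π and water-mediated
  interactions are not modeled.
* PDB input only (no DCD/XTC); no mass-weighted RMSD; no PCA.
* The Metropolis walk assumes its symmetric proposal; feeding it weights from
  a non-uniform sampler would bias populations.
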