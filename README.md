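# mdinteract

Post-MD analysis for protease–amyloid dimer trajectories: interaction
occurrence maps with a strong/weak/none contact rubric, RMSD/RMSF
convergence metrics, secondary-structure percentages, open/closed chamber
gauges, and conformer populations by Metropolis Monte Carlo.

## The problem

Insulin-degrading enzyme (IDE) encloses substrates — here an amyloid-β (Aβ)
dimer, the earliest species on the aggregation pathway — in an internal
chamber formed by its four domains.  Characterizing such simulations means
answering, frame by frame: which residue pairs across an interface are
actually in contact and how often; does the chamber sit open or closed; how
converged and structured are the chains; and, given conformational energies
for several competing dimer conformers, what are their equilibrium
populations?  `mdinteract` implements those analyses as a reusable, tested
library over multi-model PDB trajectories and plain-text energy tables, with
synthetic generators providing ground-truth inputs for every stage.

## The core quantities

**Occurrence maps.** For residues a, b and a distance criterion d(a,b) ≤ c,
the occurrence is the percentage of trajectory frames satisfying the
criterion — Cα–Cα ≤ 10 Å between hydrophobic residues, charged-group atoms
≤ 4 Å for salt bridges, donor-H to acceptor ≤ 2.4 Å for hydrogen bonds.
Region-pair contacts grade *strong* when ≥ 2 facing residue pairs reach
≥ 85% occurrence, *weak* when any facing pair is in contact short of that,
*none* otherwise.

**Conformer populations.** Given energies E for the saved conformations of
each conformer, a random walk proposes a conformation of another conformer
and accepts with the Metropolis rule, P(accept) = min(1, e^−ΔE/kT); counting
the occupied conformer at every step for N_total steps gives

P_n = N_n / N_total,  ΔG_n = −kT ln(P_n / P_max),

at T = 298 K.  The exact Boltzmann sum over all pooled conformations is
computed alongside as an oracle; at the study scale (7 conformers × 500
conformations) the 10⁶-step walk agrees with it to better than 0.01 in
every population.

**Structure metrics.** Kabsch-superposed Cα RMSD series and mean-structure
RMSF profiles; hydrogen-bond-pattern secondary-structure assignment (H/E/C)
with per-residue helix/strand percentages over the first and last 5 ns; and
named cross-chamber distances (H134–K884, F424–G615, V410–A614, K353–K657)
and hinge angles (E176–A403–S721, A403–S721–D876) gauging the open/closed
state.

## Worked example

Generate the synthetic study inputs and run the analyses:

```bash
python analysis/01_simulate_fixtures.py --seed 1
python analysis/02_contact_maps.py
python analysis/03_structure_metrics.py
python analysis/04_conformer_populations.py --seed 1
```

The contact step recovers the scheduled ground truth exactly and grades the
regions:

```
10 residue pairs in contact (of 1764 hydrophobic pairs)
  scheduled pair ('A', 5)–('B', 5): occurrence 85.0%
  scheduled pair ('A', 10)–('B', 10): occurrence 0.0%
  scheduled pair ('A', 20)–('B', 20): occurrence 100.0%
  c_half vs partner: weak
  n_half vs partner: strong
```

— the first half of chain A holds several facing pairs at ≥ 85% occurrence
(strong), the second half only one (weak).  The gauge step shows every
cross-chamber distance at least doubling between the closed and open toy
assemblies (e.g. `H134-K884: closed 16.0 Å, open 36.3 Å (x2.27)`), and the
population step reports, per conformer, the Monte Carlo estimate, the exact
Boltzmann value, and the relative free energy:

```
  M1: P_mc 0.4915  P_exact 0.4843  dG -0.000 kcal/mol
  M2: P_mc 0.3221  P_exact 0.3296  dG 0.250 kcal/mol
  ...
max |P_mc - P_exact| = 0.0075
```

Low-mean conformers dominate; a 10:1 population ratio corresponds to
kT ln 10 ≈ 1.36 kcal/mol at 298 K.

The same stages run from the command line on any inputs:

```bash
mdinteract simulate dimer --out dimer.pdb --frames 100
mdinteract contacts --pdb dimer.pdb --out results/
mdinteract populations --energies energies.csv --steps 1000000 --seed 1 --out results/
mdinteract run --config pipeline.yaml   # full configured pipeline + manifest
```

## Layout

- `src/mdinteract/` — the library: structures & PDB I/O, superposition
  metrics, secondary structure, contacts, gauges, populations, synthetic
  generators, pipeline, CLI
- `analysis/` — numbered narrative drivers over the library
- `tests/` — unit, property, and acceptance tests
- `docs/methods.md` — models, parameters, and design choices in detail
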