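#!/usr/bin/env python
"""Generate the synthetic study inputs every later analysis step consumes.

Since no trajectory data accompany the study system, all inputs are
synthetic with known ground truth: a two-chain dimer trajectory with
scheduled per-pair contact occupancies (85%, 0%, 100%), the open and closed
four-domain toy assemblies, ideal helix and sheet backbones, and the
7-conformer x 500-conformation Gaussian energy ensemble.  All generated
inputs land in scratch/fixtures; later steps write their summary tables to
results/.
"""

import argparse
from pathlib import Path

import numpy as np

from mdinteract import (
    EnergyModelSpec,
    Trajectory,
    make_conformer_energies,
    make_dimer_trajectory,
    make_ideal_helix,
    make_ideal_sheet,
    make_open_closed_toy,
    write_pdb,
)
from mdinteract.populations import write_energy_table
from mdinteract.synthetic import ScheduledContact

SCRATCH = Path("scratch/fixtures")
RESULTS = Path("results")


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=1)
    args = parser.parse_args()
    SCRATCH.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(parents=True, exist_ok=True)

    schedule = [
        ScheduledContact(5, 5, 85.0),
        ScheduledContact(10, 10, 0.0),
        ScheduledContact(20, 20, 100.0),
    ]
    dimer = make_dimer_trajectory(schedule, n_frames=100, noise_sd=0.1, seed=args.seed)
    write_pdb(dimer, SCRATCH / "dimer.pdb")
    print(f"dimer: {len(dimer)} frames, scheduled occupancies 85/0/100% at pairs 5/10/20")

    for state in ("open", "closed"):
        write_pdb(Trajectory(frames=[make_open_closed_toy(state)]), SCRATCH / f"toy_{state}.pdb")
    write_pdb(Trajectory(frames=[make_ideal_helix(20)]), SCRATCH / "helix20.pdb")
    write_pdb(Trajectory(frames=[make_ideal_sheet(8, "antiparallel")]), SCRATCH / "sheet_anti.pdb")
    print("wrote open/closed toys, 20-residue helix, 8+8 antiparallel sheet")

    spec = EnergyModelSpec(
        conformers=tuple(
            (f"M{i + 1}", float(m), 1.0, 500) for i, m in enumerate(np.linspace(0.0, 3.0, 7))
        ),
        seed=args.seed,
    )
    energies = make_conformer_energies(spec)
    write_energy_table(energies, SCRATCH / "conformer_energies.csv")
    print(
        "energy ensemble: 7 conformers x 500 conformations, means 0-3 kcal/mol, "
        f"spread 1 kcal/mol -> {SCRATCH / 'conformer_energies.csv'}"
    )


if __name__ == "__main__":
    main()
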