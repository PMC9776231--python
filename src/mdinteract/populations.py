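"""Conformer populations from conformational energies by Metropolis Monte Carlo.

Each *conformer* (one simulated model) contributes a set of saved
*conformations*, each with a precomputed implicit-solvent conformational
energy in kcal/mol.  A random walk moves between individual conformations:
from the current conformation i, a conformation j of a uniformly chosen
*other* conformer is proposed, and the move is accepted when the Boltzmann
factor e^-(Ej-Ei)/kT exceeds a uniform(0,1) draw (Metropolis acceptance;
factors above 1 always pass).  The occupied conformer is tallied at every
step, so visit counts sum to the step total and

    P_n = N_n / N_total

estimates conformer n's equilibrium population.  Because the proposal is
symmetric, the walk's stationary distribution is the Boltzmann measure over
all conformations, which :func:`exact_populations` evaluates in closed form
as the independent check.  Relative free energies follow as
dG_n = -kT ln(P_n / P_max), zero for the most populated conformer.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "BOLTZMANN_KCAL",
    "ConformerEnergySet",
    "PopulationConfig",
    "PopulationEstimate",
    "mc_populations",
    "exact_populations",
    "relative_free_energies",
    "read_energy_table",
    "write_energy_table",
]

logger = logging.getLogger(__name__)

#: Boltzmann constant in kcal/(mol*K).
BOLTZMANN_KCAL = 0.0019872041


@dataclass
class ConformerEnergySet:
    """Conformer label -> per-conformation energies (kcal/mol)."""

    conformers: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        if not self.conformers:
            raise ValueError("at least one conformer is required")
        clean = {}
        for label, energies in self.conformers.items():
            arr = np.asarray(energies, dtype=float)
            if arr.size == 0:
                raise ValueError(f"conformer {label!r} has no conformations")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"conformer {label!r} contains non-finite energies")
            clean[str(label)] = arr
        self.conformers = clean

    @property
    def labels(self) -> list[str]:
        return list(self.conformers)

    def shifted(self, delta: float) -> "ConformerEnergySet":
        return ConformerEnergySet({k: v + delta for k, v in self.conformers.items()})


@dataclass(frozen=True)
class PopulationConfig:
    """Walk settings: temperature (K), step count, RNG seed."""

    temperature: float = 298.0
    steps: int = 1_000_000
    seed: int = 0
    n_batches: int = 10

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.steps < 1:
            raise ValueError("steps must be >= 1")


@dataclass
class PopulationEstimate:
    """Visit counts, probabilities P_n = N_n/N_total, and batch-means SEs."""

    labels: list[str]
    visits: np.ndarray
    n_total: int
    probabilities: np.ndarray
    stderr: np.ndarray

    def __post_init__(self) -> None:
        if int(self.visits.sum()) != self.n_total:
            raise ValueError("visit counts must sum to the total step count")
        if abs(float(self.probabilities.sum()) - 1.0) > 1e-12:
            raise ValueError("probabilities must sum to 1")

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.labels, self.probabilities))

    def to_frame(self, temperature: float = 298.0) -> pd.DataFrame:
        dg, unbounded = relative_free_energies(self.probabilities, temperature)
        return pd.DataFrame(
            {
                "conformer": self.labels,
                "N_n": self.visits.astype(int),
                "P_n": self.probabilities,
                "stderr": self.stderr,
                "dG_kcal_mol": dg,
            }
        )


def mc_populations(
    energies: ConformerEnergySet, config: PopulationConfig = PopulationConfig()
) -> PopulationEstimate:
    """Estimate conformer populations by the Metropolis walk described above.

    Deterministic for a given seed.  Standard errors come from 10 batch
    means, which respects the chain's autocorrelation.
    """
    labels = energies.labels
    k = len(labels)
    kt = BOLTZMANN_KCAL * config.temperature
    rng = np.random.default_rng(config.seed)
    steps = config.steps

    if k == 1:
        logger.info("single conformer: population is trivially 1")
        return PopulationEstimate(
            labels=labels,
            visits=np.array([steps]),
            n_total=steps,
            probabilities=np.array([1.0]),
            stderr=np.array([0.0]),
        )

    energy_arrays = [energies.conformers[label] for label in labels]
    sizes = np.array([len(a) for a in energy_arrays])

    # Start at a uniformly random conformation of the pooled ensemble.
    start_conf = int(rng.integers(sizes.sum()))
    cum = np.cumsum(sizes)
    cur_model = int(np.searchsorted(cum, start_conf, side="right"))
    cur_energy = energy_arrays[cur_model][start_conf - (cum[cur_model - 1] if cur_model else 0)]

    # Pre-drawn randomness; the loop itself is sequential by nature.
    other = rng.integers(0, k - 1, size=steps)
    within = rng.random(size=steps)
    accept_u = rng.random(size=steps)

    occupancy = np.empty(steps, dtype=np.int16)
    inv_kt = 1.0 / kt
    for t in range(steps):
        j_model = other[t]
        if j_model >= cur_model:
            j_model += 1
        arr = energy_arrays[j_model]
        e_j = arr[int(within[t] * arr.shape[0])]
        # Metropolis: accept when e^-(Ej-Ei)/kT beats a uniform draw.
        if e_j <= cur_energy or np.exp(-(e_j - cur_energy) * inv_kt) > accept_u[t]:
            cur_model = j_model
            cur_energy = e_j
        occupancy[t] = cur_model

    visits = np.bincount(occupancy, minlength=k)
    probabilities = visits / steps

    # Batch-means standard errors.
    nb = config.n_batches
    batch = steps // nb
    if batch >= 1:
        trimmed = occupancy[: nb * batch].reshape(nb, batch)
        batch_p = np.stack([(trimmed == m).mean(axis=1) for m in range(k)], axis=1)
        stderr = batch_p.std(axis=0, ddof=1) / np.sqrt(nb)
    else:
        stderr = np.full(k, np.nan)

    return PopulationEstimate(
        labels=labels,
        visits=visits,
        n_total=steps,
        probabilities=probabilities,
        stderr=stderr,
    )


def exact_populations(energies: ConformerEnergySet, temperature: float = 298.0) -> dict[str, float]:
    """Closed-form Boltzmann populations over the pooled conformations.

    P_n = sum_{c in n} e^-(E_c - E_min)/kT / sum_all e^-(E_c - E_min)/kT.
    The minimum-energy shift makes the exponentials overflow-free.
    """
    kt = BOLTZMANN_KCAL * temperature
    e_min = min(float(a.min()) for a in energies.conformers.values())
    weights = {
        label: float(np.sum(np.exp(-(arr - e_min) / kt)))
        for label, arr in energies.conformers.items()
    }
    total = sum(weights.values())
    return {label: w / total for label, w in weights.items()}


def relative_free_energies(
    populations: np.ndarray | dict[str, float], temperature: float = 298.0
) -> tuple[np.ndarray, np.ndarray]:
    """dG_n = -kT ln(P_n / P_max), kcal/mol; zero for the most populated.

    Returns ``(dG, unbounded)`` where ``unbounded`` flags zero-population
    conformers (their dG is +inf, not an exception).
    """
    if isinstance(populations, dict):
        p = np.array(list(populations.values()), dtype=float)
    else:
        p = np.asarray(populations, dtype=float)
    if np.any(p < 0):
        raise ValueError("populations must be non-negative")
    kt = BOLTZMANN_KCAL * temperature
    p_max = p.max()
    if p_max <= 0:
        raise ValueError("at least one population must be positive")
    unbounded = p == 0
    with np.errstate(divide="ignore"):
        dg = -kt * np.log(p / p_max)
    return dg, unbounded


def read_energy_table(path: str | Path) -> ConformerEnergySet:
    """Read a delimited text table with columns conformer_label,energy_kcal_mol."""
    df = pd.read_csv(path)
    required = {"conformer_label", "energy_kcal_mol"}
    if not required.issubset(df.columns):
        raise ValueError(
            f"{path}: energy table needs columns {sorted(required)}, got {list(df.columns)}"
        )
    grouped = {
        str(label): group["energy_kcal_mol"].to_numpy()
        for label, group in df.groupby("conformer_label", sort=False)
    }
    return ConformerEnergySet(grouped)


def write_energy_table(energies: ConformerEnergySet, path: str | Path) -> Path:
    path = Path(path)
    rows = [
        {"conformer_label": label, "energy_kcal_mol": e}
        for label, arr in energies.conformers.items()
        for e in arr
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
    return path
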