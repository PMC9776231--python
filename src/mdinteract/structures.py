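"""Domain types for structures and trajectories.

The in-memory model is deliberately small: a :class:`Trajectory` is an
ordered list of :class:`Frame` objects sharing one topology (same chains,
same residues, same atom names), which is exactly the contract a saved MD
trajectory written as a multi-model PDB provides.  Residue numbering is
1-based, as in PDB records.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "Atom",
    "Residue",
    "Frame",
    "Trajectory",
    "RegionScheme",
    "AnalysisWindow",
    "SelectionError",
    "TopologyError",
    "select",
]

BACKBONE_NAMES = frozenset({"N", "CA", "C", "O", "OXT", "H", "HN", "H1", "H2", "H3", "HA"})


class SelectionError(ValueError):
    """A selection referenced a chain, residue, or atom that is not there."""


class TopologyError(ValueError):
    """Frames of one trajectory disagree on chains, residues, or atom names."""


@dataclass
class Atom:
    """One atom: PDB atom name, element symbol, Cartesian coordinates in Å."""

    name: str
    element: str
    coords: np.ndarray
    serial: int = 0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,):
            raise ValueError(f"atom {self.name!r}: coords must be a 3-vector")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.name!r}: non-finite coordinates")
        if not self.name:
            raise ValueError("atom name must be non-empty")


@dataclass
class Residue:
    """One residue: 1-based sequence index, 3-letter code, chain label, atoms."""

    index: int
    name: str
    chain_id: str
    atoms: list[Atom] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [a.name for a in self.atoms]
        if len(names) != len(set(names)):
            raise ValueError(
                f"residue {self.name}{self.index} chain {self.chain_id}: duplicate atom names"
            )

    def atom(self, name: str) -> Atom:
        for a in self.atoms:
            if a.name == name:
                return a
        raise SelectionError(
            f"atom {name!r} absent in residue {self.name}{self.index} of chain {self.chain_id}"
        )

    def has_atom(self, name: str) -> bool:
        return any(a.name == name for a in self.atoms)

    @property
    def label(self) -> str:
        """Compact residue label such as ``A:LEU17``."""
        return f"{self.chain_id}:{self.name}{self.index}"

    def sidechain_atoms(self) -> list[Atom]:
        """Heavy atoms outside the backbone (empty for glycine)."""
        return [
            a
            for a in self.atoms
            if a.name not in BACKBONE_NAMES and not a.element.upper().startswith("H")
        ]


@dataclass
class Frame:
    """One saved conformation: ordered chains of residues plus a time stamp (ps)."""

    chains: list[list[Residue]]
    time: float = 0.0

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError("frame time must be non-negative")
        for chain in self.chains:
            if not chain:
                raise ValueError("every chain must contain at least one residue")
            idx = [r.index for r in chain]
            if len(idx) != len(set(idx)):
                raise ValueError(
                    f"chain {chain[0].chain_id}: residue indices must be unique"
                )

    @property
    def chain_ids(self) -> list[str]:
        return [c[0].chain_id for c in self.chains]

    def chain(self, chain_id: str) -> list[Residue]:
        for c in self.chains:
            if c[0].chain_id == chain_id:
                return c
        raise SelectionError(f"chain {chain_id!r} not present (have {self.chain_ids})")

    def residue(self, chain_id: str, index: int) -> Residue:
        for r in self.chain(chain_id):
            if r.index == index:
                return r
        raise SelectionError(f"residue {index} not present in chain {chain_id}")

    def residues(self) -> Iterable[Residue]:
        for chain in self.chains:
            yield from chain

    def topology_key(self) -> tuple:
        return tuple(
            tuple((r.chain_id, r.index, r.name, tuple(a.name for a in r.atoms)) for r in chain)
            for chain in self.chains
        )


@dataclass
class Trajectory:
    """An ordered sequence of frames with constant topology.

    Parameters
    ----------
    frames:
        One or more :class:`Frame` objects with strictly increasing times.
    frame_interval:
        Spacing between saved frames in ps (used when a file carries no time
        metadata; saved-frame spacing defaults to 10 ps).
    """

    frames: list[Frame]
    frame_interval: float = 10.0

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValueError("a trajectory needs at least one frame")
        times = [f.time for f in self.frames]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("frame times must be strictly increasing")
        key0 = self.frames[0].topology_key()
        for i, f in enumerate(self.frames[1:], start=2):
            if f.topology_key() != key0:
                raise TopologyError(
                    f"frame {i} topology differs from frame 1 (chains/residues/atoms)"
                )

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def times(self) -> np.ndarray:
        return np.array([f.time for f in self.frames])

    def window_indices(self, window: "AnalysisWindow") -> np.ndarray:
        """Indices of frames whose time lies in [start, end]."""
        t = self.times
        idx = np.nonzero((t >= window.start) & (t <= window.end))[0]
        if idx.size == 0:
            raise ValueError(
                f"analysis window [{window.start}, {window.end}] ps contains no frames "
                f"(trajectory spans [{t[0]}, {t[-1]}] ps)"
            )
        return idx


@dataclass(frozen=True)
class AnalysisWindow:
    """Half-open time slab [start, end] in ps over which statistics are taken."""

    start: float
    end: float

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"window requires 0 <= start < end, got [{self.start}, {self.end}]")


@dataclass
class RegionScheme:
    """Named residue ranges, e.g. the protease domains or peptide termini.

    ``regions`` maps a region name to ``(chain_id, first, last)`` with an
    inclusive 1-based residue range.
    """

    regions: dict[str, tuple[str, int, int]]

    def __post_init__(self) -> None:
        for name, (chain_id, first, last) in self.regions.items():
            if first > last:
                raise ValueError(f"region {name!r}: first residue {first} > last {last}")

    def __getitem__(self, name: str) -> tuple[str, int, int]:
        return self.regions[name]

    def names(self) -> list[str]:
        return list(self.regions)

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, Sequence]) -> "RegionScheme":
        return cls({str(k): (str(v[0]), int(v[1]), int(v[2])) for k, v in mapping.items()})


# Default region schemes of the studied system: the four domains of
# insulin-degrading enzyme (IDE) and the N-/C-terminal split of the 42-residue
# amyloid-beta peptide at K16/L17.
IDE_DOMAINS = {
    "domain1": (43, 285),
    "domain2": (286, 515),
    "domain3": (542, 768),
    "domain4": (769, 1016),
}

ABETA_REGIONS = {
    "n_terminal": (1, 16),
    "c_terminal": (17, 42),
}


def ide_domain_scheme(chain_id: str = "A") -> RegionScheme:
    """IDE's four-domain scheme on the given chain."""
    return RegionScheme({k: (chain_id, a, b) for k, (a, b) in IDE_DOMAINS.items()})


def abeta_region_scheme(chain_id: str) -> RegionScheme:
    """Amyloid-beta N-/C-terminal scheme (split after K16) on the given chain."""
    return RegionScheme({k: (chain_id, a, b) for k, (a, b) in ABETA_REGIONS.items()})


def select(
    frame: Frame,
    chain_id: str,
    first: int,
    last: int,
    atom_names: Sequence[str] | None = None,
) -> tuple[np.ndarray, list[int]]:
    """Extract coordinates over an inclusive residue range of one chain.

    Returns ``(coords, residue_indices)`` where ``coords`` is an ``(n, 3)``
    array in residue-major order.  With ``atom_names`` given, only those atoms
    are taken (each must be present in every residue of the range); without it,
    all atoms of each residue are taken.
    """
    chain = frame.chain(chain_id)
    residues = [r for r in chain if first <= r.index <= last]
    if not residues:
        raise SelectionError(
            f"no residues in range {first}-{last} of chain {chain_id}"
        )
    present = {r.index for r in residues}
    missing = [i for i in range(first, last + 1) if i not in present]
    if missing:
        raise SelectionError(
            f"chain {chain_id}: residues {missing} of range {first}-{last} are absent"
        )
    coords: list[np.ndarray] = []
    indices: list[int] = []
    for r in residues:
        if atom_names is None:
            chosen = r.atoms
        else:
            chosen = [r.atom(name) for name in atom_names]
        for a in chosen:
            coords.append(a.coords)
            indices.append(r.index)
    return np.array(coords), indices


def select_region(
    frame: Frame, scheme: RegionScheme, region: str, atom_names: Sequence[str] | None = None
) -> tuple[np.ndarray, list[int]]:
    """:func:`select` addressed through a named region of a scheme."""
    chain_id, first, last = scheme[region]
    return select(frame, chain_id, first, last, atom_names)
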