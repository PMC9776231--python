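"""Interaction occurrence maps and the strong/weak/none contact rubric.

Three interaction kinds are counted frame by frame along a trajectory:

* hydrophobic -- Cα-Cα distance of two hydrophobic residues within 10 Å;
* electrostatic -- any side-chain charged-group atom of an oppositely
  charged pair within 4 Å (salt bridge);
* hydrogen bond -- any donor hydrogen within 2.4 Å of an acceptor N/O.

The *occurrence* of a pair is the percentage of frames satisfying its
criterion (all cutoffs inclusive).  Region-level contacts are then graded by
four rules: (1) the side chains face each other in most frames, (2) the pair
is within the Cα cutoff in at least one frame, (3) at least ``min_interactions``
qualifying pairs link the two regions, and (4) their occurrence clears the
strong threshold.  Rules 3+4 jointly satisfied give *strong*; any facing
in-contact pair short of that gives *weak*; otherwise *none*.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .structures import RegionScheme, Residue, Trajectory

__all__ = [
    "HYDROPHOBIC_RESIDUES",
    "NEGATIVE_GROUP_ATOMS",
    "POSITIVE_GROUP_ATOMS",
    "InteractionCriteria",
    "OccurrenceMap",
    "ContactLevel",
    "hydrophobic_occurrence_map",
    "electrostatic_occurrence_map",
    "hbond_occurrence_map",
    "facing_fraction",
    "facing_fractions",
    "classify_region_contacts",
]

logger = logging.getLogger(__name__)

#: Residues treated as hydrophobic for Cα contact maps (configurable).
HYDROPHOBIC_RESIDUES = frozenset(
    {"ALA", "VAL", "LEU", "ILE", "MET", "PHE", "TRP", "TYR", "PRO"}
)

#: Side-chain atoms carrying the formal negative charge.
NEGATIVE_GROUP_ATOMS = {"ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2")}

#: Side-chain atoms carrying the formal positive charge.  Histidine is
#: included as positively charged by default; drop it from this map for a
#: neutral-His convention.
POSITIVE_GROUP_ATOMS = {"LYS": ("NZ",), "ARG": ("NE", "NH1", "NH2"), "HIS": ("ND1", "NE2")}


@dataclass(frozen=True)
class InteractionCriteria:
    """Distance cutoffs (Å) and rubric thresholds for contact analysis."""

    hydrophobic_ca_cutoff: float = 10.0
    electrostatic_cutoff: float = 4.0
    hbond_cutoff: float = 2.4
    strong_occurrence_threshold: float = 85.0
    min_interactions: int = 2
    facing_angle_cutoff: float = 90.0
    hydrophobic_residues: frozenset[str] = HYDROPHOBIC_RESIDUES

    def __post_init__(self) -> None:
        for name in ("hydrophobic_ca_cutoff", "electrostatic_cutoff", "hbond_cutoff"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0 < self.strong_occurrence_threshold <= 100):
            raise ValueError("strong_occurrence_threshold must lie in (0, 100]")
        if self.min_interactions < 1:
            raise ValueError("min_interactions must be >= 1")


PairKey = tuple[tuple[str, int], tuple[str, int]]


def _pair_key(a: tuple[str, int], b: tuple[str, int]) -> PairKey:
    return (a, b) if a <= b else (b, a)


@dataclass
class OccurrenceMap:
    """Residue-pair -> percent of frames satisfying an interaction criterion."""

    entries: dict[PairKey, float]
    n_frames: int
    criterion: str

    def get(self, a: tuple[str, int], b: tuple[str, int]) -> float:
        """Occurrence of the (unordered) pair, 0.0 when unrecorded."""
        return self.entries.get(_pair_key(a, b), 0.0)

    def nonzero(self) -> dict[PairKey, float]:
        return {k: v for k, v in self.entries.items() if v > 0}


class ContactLevel(str, Enum):
    STRONG = "strong"
    WEAK = "weak"
    NONE = "none"


def _selection_residues(traj: Trajectory, selection: tuple[str, int, int]) -> list[tuple[str, int]]:
    chain_id, first, last = selection
    chain = traj.frames[0].chain(chain_id)
    return [(chain_id, r.index) for r in chain if first <= r.index <= last]


def _occurrence(counts: int, n_frames: int) -> float:
    return 100.0 * counts / n_frames


def hydrophobic_occurrence_map(
    traj: Trajectory,
    group_a: tuple[str, int, int],
    group_b: tuple[str, int, int],
    criteria: InteractionCriteria = InteractionCriteria(),
) -> OccurrenceMap:
    """Cα-Cα contact occurrence between hydrophobic residues of two groups."""
    res_a = [
        k
        for k in _selection_residues(traj, group_a)
        if traj.frames[0].residue(*k).name in criteria.hydrophobic_residues
    ]
    res_b = [
        k
        for k in _selection_residues(traj, group_b)
        if traj.frames[0].residue(*k).name in criteria.hydrophobic_residues
    ]
    if not res_a or not res_b:
        logger.warning(
            "hydrophobic map %s vs %s: a group has no hydrophobic residues", group_a, group_b
        )
        return OccurrenceMap(entries={}, n_frames=len(traj), criterion="hydrophobic")

    counts: dict[PairKey, int] = {}
    for frame in traj.frames:
        ca_a = np.array([frame.residue(*k).atom("CA").coords for k in res_a])
        ca_b = np.array([frame.residue(*k).atom("CA").coords for k in res_b])
        dist = np.linalg.norm(ca_a[:, None, :] - ca_b[None, :, :], axis=2)
        hits = dist <= criteria.hydrophobic_ca_cutoff
        for ia, ib in zip(*np.nonzero(hits)):
            key = _pair_key(res_a[ia], res_b[ib])
            counts[key] = counts.get(key, 0) + 1
    entries = {
        _pair_key(a, b): _occurrence(counts.get(_pair_key(a, b), 0), len(traj))
        for a in res_a
        for b in res_b
        if a != b
    }
    return OccurrenceMap(entries=entries, n_frames=len(traj), criterion="hydrophobic")


def _charged_atoms(res: Residue) -> tuple[int, list[np.ndarray]]:
    """(sign, coords of the charged-group atoms present) or (0, [])."""
    if res.name in NEGATIVE_GROUP_ATOMS:
        names = NEGATIVE_GROUP_ATOMS[res.name]
        sign = -1
    elif res.name in POSITIVE_GROUP_ATOMS:
        names = POSITIVE_GROUP_ATOMS[res.name]
        sign = +1
    else:
        return 0, []
    coords = [res.atom(n).coords for n in names if res.has_atom(n)]
    return (sign if coords else 0), coords


def electrostatic_occurrence_map(
    traj: Trajectory,
    group_a: tuple[str, int, int],
    group_b: tuple[str, int, int],
    criteria: InteractionCriteria = InteractionCriteria(),
) -> OccurrenceMap:
    """Salt-bridge occurrence between oppositely charged residues of two groups.

    A frame counts when the minimum distance between the two residues'
    charged-group atoms is within the electrostatic cutoff.  Like-charged
    pairs are excluded.
    """
    res_a = _selection_residues(traj, group_a)
    res_b = _selection_residues(traj, group_b)
    frame0 = traj.frames[0]
    sign = {k: _charged_atoms(frame0.residue(*k))[0] for k in set(res_a) | set(res_b)}
    pairs = [
        _pair_key(a, b)
        for a in res_a
        for b in res_b
        if a != b and sign[a] * sign[b] == -1
    ]
    pairs = sorted(set(pairs))
    counts = {p: 0 for p in pairs}
    for frame in traj.frames:
        for a, b in pairs:
            _, atoms_a = _charged_atoms(frame.residue(*a))
            _, atoms_b = _charged_atoms(frame.residue(*b))
            dmin = min(
                float(np.linalg.norm(pa - pb)) for pa in atoms_a for pb in atoms_b
            )
            if dmin <= criteria.electrostatic_cutoff:
                counts[(a, b)] += 1
    entries = {p: _occurrence(c, len(traj)) for p, c in counts.items()}
    return OccurrenceMap(entries=entries, n_frames=len(traj), criterion="electrostatic")


def _donor_hydrogens(res: Residue) -> list[np.ndarray]:
    """Hydrogens covalently attached to an N or O of the residue."""
    heavies = [a.coords for a in res.atoms if a.element.upper() in {"N", "O"}]
    out = []
    for a in res.atoms:
        if not a.element.upper().startswith("H"):
            continue
        if any(np.linalg.norm(a.coords - h) <= 1.25 for h in heavies):
            out.append(a.coords)
    return out


def _acceptors(res: Residue) -> list[np.ndarray]:
    return [a.coords for a in res.atoms if a.element.upper() in {"N", "O"}]


def hbond_occurrence_map(
    traj: Trajectory,
    group_a: tuple[str, int, int],
    group_b: tuple[str, int, int],
    criteria: InteractionCriteria = InteractionCriteria(),
) -> OccurrenceMap:
    """Hydrogen-bond occurrence: any donor H within the cutoff of an acceptor.

    Purely distance-based (no angle term).  Requires explicit hydrogens; a
    structure with none raises, since every occurrence would be trivially zero.
    """
    if not any(
        a.element.upper().startswith("H") for r in traj.frames[0].residues() for a in r.atoms
    ):
        raise ValueError(
            "hydrogen-bond analysis requires explicit hydrogens; "
            "provide hydrogen-bearing input structures"
        )
    res_a = _selection_residues(traj, group_a)
    res_b = _selection_residues(traj, group_b)
    pairs = sorted({_pair_key(a, b) for a in res_a for b in res_b if a != b})
    counts = {p: 0 for p in pairs}
    for frame in traj.frames:
        for a, b in pairs:
            ra, rb = frame.residue(*a), frame.residue(*b)
            found = False
            for donor, acceptor in ((ra, rb), (rb, ra)):
                hs = _donor_hydrogens(donor)
                accs = _acceptors(acceptor)
                if any(
                    np.linalg.norm(h - x) <= criteria.hbond_cutoff for h in hs for x in accs
                ):
                    found = True
                    break
            if found:
                counts[(a, b)] += 1
    entries = {p: _occurrence(c, len(traj)) for p, c in counts.items()}
    return OccurrenceMap(entries=entries, n_frames=len(traj), criterion="hbond")


def _facing_in_frame(ra: Residue, rb: Residue, angle_cutoff_deg: float) -> bool:
    def centroid(res: Residue) -> np.ndarray:
        side = res.sidechain_atoms()
        if not side:
            if res.name == "GLY":
                return res.atom("CA").coords
            raise ValueError(f"residue {res.label} has no side-chain heavy atoms")
        return np.mean([a.coords for a in side], axis=0)

    ca_a, ca_b = ra.atom("CA").coords, rb.atom("CA").coords
    cos_cut = np.cos(np.deg2rad(angle_cutoff_deg))
    for res, ca_self, ca_other in ((ra, ca_a, ca_b), (rb, ca_b, ca_a)):
        v = centroid(res) - ca_self
        w = ca_other - ca_self
        nv, nw = np.linalg.norm(v), np.linalg.norm(w)
        if nv < 1e-9:  # Gly centroid collapses onto CA: orientation-free, counts as facing
            continue
        if np.dot(v, w) / (nv * nw) <= cos_cut:
            return False
    return True


def facing_fraction(
    traj: Trajectory,
    pair: tuple[tuple[str, int], tuple[str, int]],
    angle_cutoff_deg: float = 90.0,
) -> float:
    """Fraction of frames in which the pair's side chains point at each other.

    A residue faces its partner when the Cα -> side-chain-centroid vector
    makes less than ``angle_cutoff_deg`` with the vector to the partner's Cα;
    both residues must face for the frame to count.
    """
    a, b = pair
    hits = sum(
        _facing_in_frame(f.residue(*a), f.residue(*b), angle_cutoff_deg) for f in traj.frames
    )
    return hits / len(traj)


def facing_fractions(
    traj: Trajectory, occ: OccurrenceMap, angle_cutoff_deg: float = 90.0
) -> dict[PairKey, float]:
    """Facing fractions for every pair recorded in an occurrence map."""
    return {
        pair: facing_fraction(traj, pair, angle_cutoff_deg) for pair in occ.entries
    }


def classify_region_contacts(
    occ: OccurrenceMap,
    facing: dict[PairKey, float],
    scheme_a: RegionScheme,
    scheme_b: RegionScheme,
    criteria: InteractionCriteria = InteractionCriteria(),
) -> dict[tuple[str, str], ContactLevel]:
    """Grade every (region of A, region of B) pair strong / weak / none.

    Qualifying pairs face each other in at least half the frames (rule 1)
    and register nonzero occurrence under the Cα cutoff (rule 2).  The pair
    of regions is *strong* when at least ``min_interactions`` qualifying
    pairs reach ``strong_occurrence_threshold`` occurrence (rules 3 and 4),
    *weak* when any qualifying pair exists short of that, *none* otherwise.
    The boundary case (exactly ``min_interactions`` pairs at exactly the
    threshold) grades strong.
    """
    out: dict[tuple[str, str], ContactLevel] = {}
    for name_a in scheme_a.names():
        chain_a, first_a, last_a = scheme_a[name_a]
        for name_b in scheme_b.names():
            chain_b, first_b, last_b = scheme_b[name_b]
            qualifying: list[float] = []
            for (ka, kb), pct in occ.entries.items():
                in_a = ka[0] == chain_a and first_a <= ka[1] <= last_a
                in_b = kb[0] == chain_b and first_b <= kb[1] <= last_b
                in_a_swapped = kb[0] == chain_a and first_a <= kb[1] <= last_a
                in_b_swapped = ka[0] == chain_b and first_b <= ka[1] <= last_b
                if not ((in_a and in_b) or (in_a_swapped and in_b_swapped)):
                    continue
                if pct <= 0:
                    continue
                if facing.get((ka, kb), 0.0) < 0.5:
                    continue
                qualifying.append(pct)
            n_strong = sum(pct >= criteria.strong_occurrence_threshold for pct in qualifying)
            if n_strong >= criteria.min_interactions:
                level = ContactLevel.STRONG
            elif qualifying:
                level = ContactLevel.WEAK
            else:
                level = ContactLevel.NONE
            out[(name_a, name_b)] = level
    return out
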