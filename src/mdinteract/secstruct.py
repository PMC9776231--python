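"""Backbone-geometry secondary-structure assignment and windowed percentages.

Assignment follows the classic hydrogen-bond-pattern approach: an
electrostatic dipole model scores each backbone N-H...O=C pair, a bond is
called below -0.5 kcal/mol, and helices/strands are read off the bond
pattern (two consecutive i->i+4 turns make a helix; paired bridges make a
strand ladder).  Three states are reported: H (alpha-helix), E (beta-strand),
C (everything else) -- 3-10/pi helices, turns and bends fold into C, since
only alpha/beta percentages are analysed downstream.

The dipole model places partial charges on N,H and C,O:

    E = q1*q2*f * (1/r_ON + 1/r_CH - 1/r_OH - 1/r_CN),  q1*q2*f = 27.888 kcal*A/mol

Missing amide hydrogens are synthesized 1.0 A from N, opposite the bisector
of the C(prev)-N-CA angle, so minimized frames without hydrogens remain
assignable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structures import AnalysisWindow, Frame, Residue, Trajectory

__all__ = [
    "HBOND_ENERGY_CUTOFF",
    "SsAssignment",
    "SsPercentageProfile",
    "backbone_hbond_energy",
    "assign_ss",
    "ss_percentages",
]

#: Bond is called when the dipole energy falls below this (kcal/mol).
HBOND_ENERGY_CUTOFF = -0.5

#: q1 * q2 * f of the dipole model, kcal*Å/mol.
_COUPLING = 27.888

#: Pairs closer than this are treated as clashes, not bonds (Å).
_MIN_DIST = 0.5


@dataclass
class SsAssignment:
    """Per-residue H/E/C labels for one frame, keyed like the frame's residues."""

    labels: dict[tuple[str, int], str]

    def label(self, chain_id: str, index: int) -> str:
        return self.labels[(chain_id, index)]

    def counts(self) -> dict[str, int]:
        out = {"H": 0, "E": 0, "C": 0}
        for v in self.labels.values():
            out[v] += 1
        return out


@dataclass
class SsPercentageProfile:
    """Percent of window frames each residue spends helical / in strand."""

    residue_keys: list[tuple[str, int]]
    helix_pct: np.ndarray
    strand_pct: np.ndarray

    def __post_init__(self) -> None:
        self.helix_pct = np.asarray(self.helix_pct, dtype=float)
        self.strand_pct = np.asarray(self.strand_pct, dtype=float)
        for arr in (self.helix_pct, self.strand_pct):
            if np.any((arr < 0) | (arr > 100)):
                raise ValueError("percentages must lie in [0, 100]")
        if np.any(self.helix_pct + self.strand_pct > 100 + 1e-9):
            raise ValueError("helix + strand percentage cannot exceed 100 per residue")

    def mean_helix_pct(self) -> float:
        """Whole-chain mean helicity (residue-averaged)."""
        return float(self.helix_pct.mean())

    def mean_strand_pct(self) -> float:
        return float(self.strand_pct.mean())


def _amide_h(res: Residue, prev: Residue | None) -> np.ndarray | None:
    for name in ("H", "HN", "H1"):
        if res.has_atom(name):
            return res.atom(name).coords
    if prev is None or not (res.has_atom("N") and res.has_atom("CA") and prev.has_atom("C")):
        return None
    n = res.atom("N").coords
    ca = res.atom("CA").coords
    c_prev = prev.atom("C").coords
    u1 = c_prev - n
    u2 = ca - n
    u1 /= np.linalg.norm(u1)
    u2 /= np.linalg.norm(u2)
    direction = -(u1 + u2)
    nrm = np.linalg.norm(direction)
    if nrm < 1e-8:
        return None
    return n + direction / nrm


def backbone_hbond_energy(
    donor: Residue, acceptor: Residue, donor_prev: Residue | None = None
) -> float:
    """Dipole H-bond energy (kcal/mol) of donor N-H against acceptor C=O.

    Returns ``inf`` when required backbone atoms are missing (the pair is
    then simply not bonded).  Proline has no amide hydrogen and cannot donate.
    """
    if donor.name == "PRO":
        return float("inf")
    if not donor.has_atom("N") or not acceptor.has_atom("C") or not acceptor.has_atom("O"):
        return float("inf")
    h = _amide_h(donor, donor_prev)
    if h is None:
        return float("inf")
    n = donor.atom("N").coords
    c = acceptor.atom("C").coords
    o = acceptor.atom("O").coords
    r_on = np.linalg.norm(o - n)
    r_ch = np.linalg.norm(c - h)
    r_oh = np.linalg.norm(o - h)
    r_cn = np.linalg.norm(c - n)
    if min(r_on, r_ch, r_oh, r_cn) < _MIN_DIST:
        return float("inf")
    return float(_COUPLING * (1.0 / r_on + 1.0 / r_ch - 1.0 / r_oh - 1.0 / r_cn))


def _hbond_matrix(frame: Frame) -> tuple[np.ndarray, list[tuple[str, int]], list[tuple[int, int]]]:
    """bonded[d, a] = True when residue d's N-H donates to residue a's C=O.

    Also returns residue keys and (chain_number, position_in_chain) for each
    flattened residue index, used for sequence-adjacency exclusions.
    """
    residues: list[Residue] = []
    keys: list[tuple[str, int]] = []
    chain_pos: list[tuple[int, int]] = []
    prev_map: list[Residue | None] = []
    for ci, chain in enumerate(frame.chains):
        for pi, res in enumerate(chain):
            residues.append(res)
            keys.append((res.chain_id, res.index))
            chain_pos.append((ci, pi))
            prev_map.append(chain[pi - 1] if pi > 0 else None)

    n = len(residues)
    bonded = np.zeros((n, n), dtype=bool)
    for d in range(n):
        for a in range(n):
            if d == a:
                continue
            # i and i+-1 of the same chain share the peptide bond: excluded.
            if chain_pos[d][0] == chain_pos[a][0] and abs(chain_pos[d][1] - chain_pos[a][1]) < 2:
                continue
            # 9 Å Cα prefilter: backbone H-bonds cannot span further.
            try:
                ca_d = residues[d].atom("CA").coords
                ca_a = residues[a].atom("CA").coords
            except Exception:
                continue
            if np.linalg.norm(ca_d - ca_a) > 9.0:
                continue
            e = backbone_hbond_energy(residues[d], residues[a], prev_map[d])
            if e < HBOND_ENERGY_CUTOFF:
                bonded[d, a] = True
    return bonded, keys, chain_pos


def assign_ss(frame: Frame) -> SsAssignment:
    """Assign H/E/C to every residue of a frame.

    H: residue lies inside a run generated by two consecutive i->i+4 turns.
    E: residue participates in a parallel or antiparallel bridge ladder of
    at least two consecutive bridges.  Chains shorter than 5 residues are all C.
    """
    bonded, keys, chain_pos = _hbond_matrix(frame)
    n = len(keys)
    labels = ["C"] * n
    chain_len = {ci: sum(1 for c, _ in chain_pos if c == ci) for ci in {c for c, _ in chain_pos}}
    eligible = [chain_len[chain_pos[i][0]] >= 5 for i in range(n)]

    def seq_neighbor(i: int, offset: int) -> int | None:
        """Flattened index of the residue `offset` positions along i's chain."""
        ci, pi = chain_pos[i]
        j = i + offset
        if 0 <= j < n and chain_pos[j] == (ci, pi + offset):
            return j
        return None

    # hbond(i, j) in the ladder definitions below: CO of i accepts from NH of j.
    def hb(i: int | None, j: int | None) -> bool:
        return i is not None and j is not None and bonded[j, i]

    # Turns: CO of i accepts from NH of i+4.
    turn4 = np.zeros(n, dtype=bool)
    for i in range(n):
        turn4[i] = hb(i, seq_neighbor(i, 4))
    # Minimal alpha-helix: turns at i-1 and i put residues i+1..i+4 in H.
    for i in range(1, n):
        im1 = seq_neighbor(i, -1)
        if im1 is not None and turn4[im1] and turn4[i]:
            for off in range(1, 5):
                j = seq_neighbor(i, off)
                if j is not None and eligible[j]:
                    labels[j] = "H"

    # Bridges.
    bridges: list[tuple[int, int, str]] = []
    for i in range(n):
        for j in range(i + 1, n):
            if chain_pos[i][0] == chain_pos[j][0] and abs(chain_pos[i][1] - chain_pos[j][1]) < 3:
                continue
            im1, ip1 = seq_neighbor(i, -1), seq_neighbor(i, 1)
            jm1, jp1 = seq_neighbor(j, -1), seq_neighbor(j, 1)
            if (hb(im1, j) and hb(j, ip1)) or (hb(jm1, i) and hb(i, jp1)):
                bridges.append((i, j, "P"))
            elif (hb(i, j) and hb(j, i)) or (hb(im1, jp1) and hb(jm1, ip1)):
                bridges.append((i, j, "A"))

    # Ladders: runs of consecutive same-type bridges; >=2 bridges -> E.
    bridge_set = set(bridges)
    in_ladder: set[int] = set()
    for i, j, kind in bridges:
        step = 1 if kind == "P" else -1
        neighbors = [(i + 1, j + step, kind), (i - 1, j - step, kind)]
        if any(b in bridge_set for b in neighbors):
            in_ladder.update((i, j))
    for i in in_ladder:
        if eligible[i] and labels[i] != "H":
            labels[i] = "E"

    return SsAssignment(labels=dict(zip(keys, labels)))


def ss_percentages(traj: Trajectory, window: AnalysisWindow | None = None) -> SsPercentageProfile:
    """Per-residue helix/strand percentages over the frames of a window."""
    if window is None:
        idx = np.arange(len(traj))
    else:
        idx = traj.window_indices(window)
    keys: list[tuple[str, int]] | None = None
    h_counts: np.ndarray | None = None
    e_counts: np.ndarray | None = None
    for k in idx:
        assignment = assign_ss(traj.frames[k])
        if keys is None:
            keys = list(assignment.labels)
            h_counts = np.zeros(len(keys))
            e_counts = np.zeros(len(keys))
        lab = np.array([assignment.labels[key] for key in keys])
        h_counts += lab == "H"
        e_counts += lab == "E"
    assert keys is not None and h_counts is not None and e_counts is not None
    n_frames = len(idx)
    return SsPercentageProfile(
        residue_keys=keys,
        helix_pct=100.0 * h_counts / n_frames,
        strand_pct=100.0 * e_counts / n_frames,
    )
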