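"""Synthetic structures, trajectories, and energy sets with known ground truth.

Every analysis stage in this package is exercised against generated inputs:
ideal helix/strand backbones built from internal coordinates, a two-chain
dimer trajectory whose per-pair contact occupancies are scheduled exactly, a
four-domain open/closed toy assembly for the chamber gauges, and Gaussian
per-conformer energy ensembles whose exact Boltzmann populations are the
recovery target.  All generators are deterministic given their seed, and all
structural outputs round-trip through multi-model PDB.

The generators emulate the *bookkeeping* structure of real MD output (chains,
residues, saved frames, controlled contact occupancy), not force-field
physics: bond geometry is idealized and fluctuations are isotropic Gaussian
noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from .populations import ConformerEnergySet
from .structures import Atom, Frame, Residue, Trajectory

__all__ = [
    "ContactSchedule",
    "ScheduledContact",
    "EnergyModelSpec",
    "make_ideal_helix",
    "make_ideal_sheet",
    "make_dimer_trajectory",
    "make_open_closed_toy",
    "make_conformer_energies",
    "make_charged_pair_trajectory",
    "make_hbond_pair_trajectory",
]

# Idealized backbone internal coordinates (Å / degrees).
_B_N_CA = 1.458
_B_CA_C = 1.525
_B_C_N = 1.329
_B_C_O = 1.231
_A_C_N_CA = 121.7
_A_N_CA_C = 111.2
_A_CA_C_N = 116.2
_A_CA_C_O = 120.5
_OMEGA = 180.0

HELIX_PHI, HELIX_PSI = -57.0, -47.0
STRAND_PHI, STRAND_PSI = -139.0, 135.0


def _place(a: np.ndarray, b: np.ndarray, c: np.ndarray, r: float, theta_deg: float,
           phi_deg: float) -> np.ndarray:
    """Place atom D with bond C-D = r, angle B-C-D = theta, torsion A-B-C-D = phi."""
    theta = np.deg2rad(theta_deg)
    phi = np.deg2rad(phi_deg)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array(
        [-r * np.cos(theta), r * np.sin(theta) * np.cos(phi), r * np.sin(theta) * np.sin(phi)]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def dihedral_deg(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Signed torsion angle p0-p1-p2-p3 in degrees (IUPAC sign convention)."""
    b0 = -(p1 - p0)
    b1 = p2 - p1
    b2 = p3 - p2
    b1u = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1u) * b1u
    w = b2 - np.dot(b2, b1u) * b1u
    x = np.dot(v, w)
    y = np.dot(np.cross(b1u, v), w)
    return float(np.degrees(np.arctan2(y, x)))


def _backbone_chain(n_residues: int, phi: float, psi: float) -> list[dict[str, np.ndarray]]:
    """Poly-backbone N/CA/C/O (+amide H) coordinates from repeating dihedrals."""
    coords: list[dict[str, np.ndarray]] = []
    # Seed the first residue in the xy-plane.
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = np.array([_B_N_CA, 0.0, 0.0])
    theta = np.deg2rad(_A_N_CA_C)
    c0 = ca0 + _B_CA_C * np.array([-np.cos(theta), np.sin(theta), 0.0])
    coords.append({"N": n0, "CA": ca0, "C": c0})
    for _ in range(1, n_residues):
        prev = coords[-1]
        n = _place(prev["N"], prev["CA"], prev["C"], _B_C_N, _A_CA_C_N, psi)
        ca = _place(prev["CA"], prev["C"], n, _B_N_CA, _A_C_N_CA, _OMEGA)
        c = _place(prev["C"], n, ca, _B_CA_C, _A_N_CA_C, phi)
        coords.append({"N": n, "CA": ca, "C": c})
    # Carbonyl O anti to the next amide N: torsion N-CA-C-O = psi + 180.
    for i, res in enumerate(coords):
        res["O"] = _place(res["N"], res["CA"], res["C"], _B_C_O, _A_CA_C_O, psi + 180.0)
        if i > 0:
            # Amide H: 1.0 Å from N, opposite the bisector of C(prev)-N-CA.
            c_prev = coords[i - 1]["C"]
            u1 = c_prev - res["N"]
            u2 = res["CA"] - res["N"]
            u1 /= np.linalg.norm(u1)
            u2 /= np.linalg.norm(u2)
            h_dir = -(u1 + u2)
            res["H"] = res["N"] + h_dir / np.linalg.norm(h_dir)
    return coords


def _chain_to_residues(
    coords: list[dict[str, np.ndarray]],
    chain_id: str,
    resname: str = "ALA",
    first_index: int = 1,
) -> list[Residue]:
    order = ("N", "H", "CA", "C", "O")
    residues = []
    serial = 1
    for i, atom_map in enumerate(coords):
        atoms = []
        for name in order:
            if name in atom_map:
                element = "H" if name == "H" else name[0]
                atoms.append(Atom(name=name, element=element, coords=atom_map[name], serial=serial))
                serial += 1
        residues.append(Residue(index=first_index + i, name=resname, chain_id=chain_id, atoms=atoms))
    return residues


def make_ideal_helix(n_residues: int, chain_id: str = "A") -> Frame:
    """Poly-alanine backbone with alpha-helical dihedrals (phi -57, psi -47).

    Amide hydrogens are present, so secondary-structure assignment runs on
    the frame directly.
    """
    if n_residues < 5:
        raise ValueError("an assignable helix needs at least 5 residues")
    coords = _backbone_chain(n_residues, HELIX_PHI, HELIX_PSI)
    return Frame(chains=[_chain_to_residues(coords, chain_id)])


def _rigid(points: np.ndarray, params: np.ndarray) -> np.ndarray:
    rot = Rotation.from_rotvec(params[:3]).as_matrix()
    return points @ rot.T + params[3:]


def _register_targets(orientation: str, n: int) -> list[tuple[str, int, str, int]]:
    """Donor/acceptor residue pairs that define the sheet register.

    Antiparallel: "narrow" H-bond rings pair residue i of A with residue
    2m - i of B (m the register center), donating both ways on alternate
    residues.  Parallel: CO(i-1) of A bonds NH(i) of B and CO(i) of B bonds
    NH(i+1) of A, phase-locked to the backbone pleat.  Entries are
    (donor_chain, donor_index, acceptor_chain, acceptor_index).
    """
    out: list[tuple[str, int, str, int]] = []
    if orientation == "antiparallel":
        m = n // 2
        for i in range(1, n, 2):
            j = 2 * m - i
            if 0 <= j < n:
                out.append(("A", i, "B", j))
                out.append(("B", j, "A", i))
    else:
        for i in range(2, n - 1, 2):
            out.append(("B", i, "A", i - 1))
            out.append(("A", i + 1, "B", i))
    return out


def _registered_partner(
    coords_a: list[dict[str, np.ndarray]],
    orientation: str,
) -> list[dict[str, np.ndarray]]:
    """Rigidly place a second strand so the register's H-bonds become ideal.

    The six rigid parameters are found by minimizing the deviation of each
    register acceptor O from the point 1.95 Å beyond the donor H along the
    N-H direction (near-linear H-bonds), plus a Cα anti-clash term.
    Deterministic: fixed multi-start grid, deterministic simplex optimizer.
    """
    n = len(coords_a)
    stack_ca = np.array([r["CA"] for r in coords_a])
    coords_b = [dict(r) for r in coords_a]
    targets = _register_targets(orientation, n)
    recs = [
        (
            dch,
            (coords_a[di] if dch == "A" else coords_b[di])["N"],
            (coords_a[di] if dch == "A" else coords_b[di])["H"],
            (coords_a[ai] if ach == "A" else coords_b[ai])["O"],
        )
        for dch, di, ach, ai in targets
    ]
    b_ca = np.array([r["CA"] for r in coords_b])

    def cost(params: np.ndarray) -> float:
        rot = Rotation.from_rotvec(params[:3]).as_matrix()
        t = params[3:]
        total = 0.0
        for dch, n_at, h_at, o_at in recs:
            if dch == "B":
                n_at = n_at @ rot.T + t
                h_at = h_at @ rot.T + t
            else:
                o_at = o_at @ rot.T + t
            u = h_at - n_at
            u = u / np.linalg.norm(u)
            total += float(np.sum((o_at - (h_at + 1.95 * u)) ** 2))
        moved_ca = b_ca @ rot.T + t
        dd = np.linalg.norm(stack_ca[:, None, :] - moved_ca[None, :, :], axis=2)
        return total + float(np.sum(np.clip(3.8 - dd, 0.0, None) ** 2))

    # Strand frame: axis, in-plane pairing direction (where odd amides point),
    # sheet normal.  Antiparallel partners are related by a 2-fold about the
    # normal; parallel partners by translation across the pairing direction.
    strand_dir = stack_ca[-1] - stack_ca[0]
    strand_dir /= np.linalg.norm(strand_dir)
    nh = coords_a[1]["H"] - coords_a[1]["N"]
    pair_dir = nh - np.dot(nh, strand_dir) * strand_dir
    pair_dir /= np.linalg.norm(pair_dir)
    normal = np.cross(strand_dir, pair_dir)
    normal /= np.linalg.norm(normal)

    if orientation == "antiparallel":
        start_rot = Rotation.from_rotvec(np.pi * normal)
        anchor = stack_ca[n // 2]
    else:
        start_rot = Rotation.identity()
        anchor = stack_ca.mean(axis=0)
    best_fun, best_x = np.inf, None
    for off in (4.4, 4.8, 5.2):
        for shift in (0.0, -1.7, 1.7, -3.4, 3.4):
            t0 = anchor + off * pair_dir + shift * strand_dir - start_rot.apply(anchor)
            x0 = np.concatenate([start_rot.as_rotvec(), t0])
            res = minimize(
                cost,
                x0,
                method="Nelder-Mead",
                options={"maxiter": 2000, "xatol": 1e-8, "fatol": 1e-12},
            )
            if res.fun < best_fun:
                best_fun, best_x = res.fun, res.x
    assert best_x is not None
    rot = Rotation.from_rotvec(best_x[:3]).as_matrix()
    return [{k: v @ rot.T + best_x[3:] for k, v in r.items()} for r in coords_b]


def make_ideal_sheet(n_per_strand: int, orientation: str = "antiparallel") -> Frame:
    """Two H-bond-registered extended strands as chains A and B."""
    if n_per_strand < 4:
        raise ValueError("a registered sheet needs at least 4 residues per strand")
    if orientation not in {"antiparallel", "parallel"}:
        raise ValueError("orientation must be 'antiparallel' or 'parallel'")
    phi, psi = (STRAND_PHI, STRAND_PSI) if orientation == "antiparallel" else (-119.0, 113.0)
    coords_a = _backbone_chain(n_per_strand, phi, psi)
    coords_b = _registered_partner(coords_a, orientation)
    return Frame(
        chains=[
            _chain_to_residues(coords_a, "A"),
            _chain_to_residues(coords_b, "B"),
        ]
    )


@dataclass(frozen=True)
class ScheduledContact:
    """One residue pair with a prescribed contact occupancy along the run."""

    res_a: int
    res_b: int
    occupancy_pct: float
    contact_distance: float = 5.0
    apart_distance: float = 15.0

    def __post_init__(self) -> None:
        if not (0 <= self.occupancy_pct <= 100):
            raise ValueError("occupancy must lie in [0, 100]")
        if self.contact_distance >= self.apart_distance:
            raise ValueError("contact distance must be below the apart distance")


ContactSchedule = list[ScheduledContact]


def make_dimer_trajectory(
    schedule: ContactSchedule,
    n_frames: int = 100,
    noise_sd: float = 0.0,
    seed: int = 0,
    n_residues: int = 42,
    resname: str = "LEU",
    baseline_separation: float = 25.0,
) -> Trajectory:
    """Two-chain toy dimer whose scheduled pairs hit their occupancy exactly.

    Chains A and B are straight Cα traces (3.8 Å spacing) with one pseudo
    side-chain atom (CB) per residue pointing at the partner chain, so the
    facing criterion always holds.  Each scheduled pair sits at its contact
    distance in exactly ``round(occupancy * n_frames / 100)`` frames (frame
    choice is a seeded permutation, so occupancies are exact, not binomial),
    and at its apart distance otherwise.  Gaussian noise of ``noise_sd`` Å
    is then added to every coordinate.
    """
    rng = np.random.default_rng(seed)
    for sc in schedule:
        if not (1 <= sc.res_a <= n_residues and 1 <= sc.res_b <= n_residues):
            raise ValueError(f"scheduled pair ({sc.res_a},{sc.res_b}) outside 1..{n_residues}")

    contact_frames: dict[tuple[int, int], set[int]] = {}
    for sc in schedule:
        k = int(round(sc.occupancy_pct * n_frames / 100.0))
        achieved = 100.0 * k / n_frames
        if abs(achieved - sc.occupancy_pct) > 1e-9:
            import logging

            logging.getLogger(__name__).info(
                "pair (%d,%d): occupancy %.3f%% not representable over %d frames; using %.3f%%",
                sc.res_a,
                sc.res_b,
                sc.occupancy_pct,
                n_frames,
                achieved,
            )
        order = rng.permutation(n_frames)
        contact_frames[(sc.res_a, sc.res_b)] = set(order[:k].tolist())

    scheduled_b = {sc.res_b: sc for sc in schedule}
    frames = []
    for f in range(n_frames):
        # Alternating z offset keeps the Cα trace non-collinear (superposable).
        base_a = np.array([[3.8 * i, 0.0, 0.5 * (-1) ** i] for i in range(n_residues)])
        base_b = np.array(
            [[3.8 * i, baseline_separation, 0.5 * (-1) ** i] for i in range(n_residues)]
        )
        for sc in schedule:
            in_contact = f in contact_frames[(sc.res_a, sc.res_b)]
            d = sc.contact_distance if in_contact else sc.apart_distance
            base_b[sc.res_b - 1] = base_a[sc.res_a - 1] + np.array([0.0, d, 0.0])

        def build_chain(base, chain_id, partner_base, partner_of):
            residues = []
            for i in range(n_residues):
                ca = base[i]
                target = partner_base[partner_of.get(i + 1, i + 1) - 1]
                direction = target - ca
                nrm = np.linalg.norm(direction)
                direction = direction / nrm if nrm > 1e-9 else np.array([0.0, 1.0, 0.0])
                cb = ca + 1.5 * direction  # pseudo side chain, pointed at the partner
                # Minimal backbone (N, O, amide H) so hydrogen-bond and
                # secondary-structure stages accept the fixture.
                n_at = ca + np.array([-1.2, 0.0, 0.3])
                o_at = ca + np.array([1.2, 0.0, -0.3])
                h_at = n_at + np.array([0.0, 0.0, 1.0])
                coords = {"N": n_at, "H": h_at, "CA": ca, "CB": cb, "O": o_at}
                atoms = [
                    Atom(
                        name,
                        "H" if name == "H" else name[0],
                        xyz + rng.normal(0.0, noise_sd, 3) if noise_sd else xyz,
                    )
                    for name, xyz in coords.items()
                ]
                residues.append(Residue(index=i + 1, name=resname, chain_id=chain_id, atoms=atoms))
            return residues

        partner_of_a = {sc.res_a: sc.res_b for sc in schedule}
        partner_of_b = {sc.res_b: sc.res_a for sc in schedule}
        chain_a = build_chain(base_a, "A", base_b, partner_of_a)
        chain_b = build_chain(base_b, "B", base_a, partner_of_b)
        frames.append(Frame(chains=[chain_a, chain_b], time=10.0 * f))
    return Trajectory(frames=frames, frame_interval=10.0)


# Gauge residues of the four-domain toy, grouped by pseudo-domain.
_TOY_N_HALF = {  # domains 1 and 2 (the N-terminal half): fixed in space
    134: (-8.0, 5.0, 0.0),
    176: (-10.0, -5.0, 0.0),
    43: (-12.0, 3.0, 2.0),
    285: (-11.0, 0.0, -2.0),
    353: (-7.0, 0.0, 5.0),
    403: (-6.0, 0.0, -5.0),
    410: (-7.0, 2.0, -5.0),
    424: (-7.0, -2.0, 6.0),
    286: (-9.0, 4.0, 4.0),
    515: (-9.0, -4.0, -4.0),
}
_TOY_C_HALF = {  # domains 3 and 4 (the C-terminal half): swings about the hinge
    615: (7.0, -2.0, 6.0),
    614: (7.0, 2.0, -5.0),
    657: (7.0, 0.0, 5.0),
    721: (6.0, 0.0, -5.0),
    542: (9.0, 4.0, 4.0),
    768: (9.0, -4.0, -4.0),
    876: (9.0, -5.0, 0.0),
    884: (8.0, 5.0, 0.0),
    769: (11.0, 3.0, 2.0),
    1016: (11.0, 0.0, -2.0),
}
_HINGE = np.array([0.0, 22.0, 0.0])
_OPEN_ANGLE_DEG = 100.0


def make_open_closed_toy(state: str, chain_id: str = "A") -> Frame:
    """Four-pseudo-domain assembly in a closed or open chamber geometry.

    The C-terminal half swings about a hinge above the chamber by 100
    degrees between states, so every cross-chamber gauge distance at least
    doubles on opening and the hinge angles change by more than 20 degrees.
    """
    if state not in {"open", "closed"}:
        raise ValueError("state must be 'open' or 'closed'")
    residues = []
    positions: dict[int, np.ndarray] = {k: np.array(v) for k, v in _TOY_N_HALF.items()}
    rot = Rotation.from_euler("z", _OPEN_ANGLE_DEG if state == "open" else 0.0, degrees=True)
    for idx, pos in _TOY_C_HALF.items():
        p = np.array(pos)
        positions[idx] = _HINGE + rot.apply(p - _HINGE)
    for idx in sorted(positions):
        residues.append(
            Residue(
                index=idx,
                name="ALA",
                chain_id=chain_id,
                atoms=[Atom("CA", "C", positions[idx], serial=idx)],
            )
        )
    return Frame(chains=[residues])


@dataclass(frozen=True)
class EnergyModelSpec:
    """Gaussian energy ensemble: per-conformer (mean, spread, count)."""

    conformers: tuple[tuple[str, float, float, int], ...] = tuple(
        (f"M{i + 1}", float(mean), 1.0, 500) for i, mean in enumerate(np.linspace(0.0, 3.0, 7))
    )
    seed: int = 0

    def __post_init__(self) -> None:
        for label, _, spread, count in self.conformers:
            if count < 1:
                raise ValueError(f"conformer {label!r}: count must be >= 1")
            if spread < 0:
                raise ValueError(f"conformer {label!r}: spread must be >= 0")


def make_conformer_energies(spec: EnergyModelSpec = EnergyModelSpec()) -> ConformerEnergySet:
    """Draw the Gaussian per-conformation energies of an :class:`EnergyModelSpec`.

    The default emulates the study scale: seven conformers with 500 saved
    conformations each, mean conformational energies spanning 3 kcal/mol and
    1 kcal/mol within-conformer spread.
    """
    rng = np.random.default_rng(spec.seed)
    return ConformerEnergySet(
        {
            label: rng.normal(mean, spread, size=count)
            for label, mean, spread, count in spec.conformers
        }
    )


def make_charged_pair_trajectory(nz_oe_distances: list[float]) -> Trajectory:
    """Lys/Glu pair whose NZ...OE1 distance follows the given per-frame values.

    Chain A carries a lysine with its side-chain nitrogen; chain B a
    glutamate with its carboxylate oxygens.  All other inter-residue atom
    distances stay above typical cutoffs, so the electrostatic criterion is
    controlled purely by the scheduled distance.
    """
    frames = []
    for f, d in enumerate(nz_oe_distances):
        lys = Residue(
            index=1,
            name="LYS",
            chain_id="A",
            atoms=[
                Atom("N", "N", (0.0, 3.0, 0.0)),
                Atom("CA", "C", (0.0, 0.0, 0.0)),
                Atom("C", "C", (0.0, -1.5, 0.0)),
                Atom("O", "O", (0.0, -2.7, 0.0)),
                Atom("CB", "C", (1.5, 0.0, 0.0)),
                Atom("NZ", "N", (5.0, 0.0, 0.0)),
            ],
        )
        glu = Residue(
            index=1,
            name="GLU",
            chain_id="B",
            atoms=[
                Atom("N", "N", (5.0 + d + 8.0, 3.0, 0.0)),
                Atom("CA", "C", (5.0 + d + 8.0, 0.0, 0.0)),
                Atom("C", "C", (5.0 + d + 8.0, -1.5, 0.0)),
                Atom("O", "O", (5.0 + d + 8.0, -2.7, 0.0)),
                Atom("CB", "C", (5.0 + d + 6.5, 0.0, 0.0)),
                Atom("OE1", "O", (5.0 + d, 0.0, 0.0)),
                Atom("OE2", "O", (5.0 + d + 1.1, 0.8, 0.0)),
            ],
        )
        frames.append(Frame(chains=[[lys], [glu]], time=10.0 * f))
    return Trajectory(frames=frames)


def make_hbond_pair_trajectory(h_acceptor_distances: list[float]) -> Trajectory:
    """Serine donor vs backbone-oxygen acceptor at scheduled H...O distances."""
    frames = []
    for f, d in enumerate(h_acceptor_distances):
        donor = Residue(
            index=1,
            name="SER",
            chain_id="A",
            atoms=[
                Atom("N", "N", (0.0, 3.0, 0.0)),
                Atom("CA", "C", (0.0, 0.0, 0.0)),
                Atom("C", "C", (0.0, -1.5, 0.0)),
                Atom("O", "O", (0.0, -2.7, 0.0)),
                Atom("CB", "C", (1.5, 0.0, 0.0)),
                Atom("OG", "O", (2.3, 1.2, 0.0)),
                Atom("HG", "H", (3.2, 1.5, 0.0)),
            ],
        )
        acceptor = Residue(
            index=1,
            name="ALA",
            chain_id="B",
            atoms=[
                Atom("O", "O", (3.2 + d, 1.5, 0.0)),
                Atom("C", "C", (3.2 + d + 1.2, 1.5, 0.0)),
                Atom("CA", "C", (3.2 + d + 2.7, 1.5, 0.0)),
                Atom("N", "N", (3.2 + d + 4.0, 1.5, 0.0)),
            ],
        )
        frames.append(Frame(chains=[[donor], [acceptor]], time=10.0 * f))
    return Trajectory(frames=frames)
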