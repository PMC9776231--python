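"""Occurrence maps, facing fractions, and the strong/weak/none rubric."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mdinteract import (
    Atom,
    ContactLevel,
    Frame,
    InteractionCriteria,
    OccurrenceMap,
    RegionScheme,
    Residue,
    Trajectory,
    classify_region_contacts,
    electrostatic_occurrence_map,
    facing_fraction,
    hbond_occurrence_map,
    hydrophobic_occurrence_map,
    make_charged_pair_trajectory,
    make_hbond_pair_trajectory,
)


def pair_traj(distances, resname="LEU", facing=True):
    """Two single-residue chains with Cα separation scheduled per frame.

    Side-chain CB points toward (facing) or away from the partner.
    """
    frames = []
    for k, d in enumerate(distances):
        sign = 1.0 if facing else -1.0
        a = Residue(1, resname, "A", [
            Atom("CA", "C", (0.0, 0.0, 0.0)),
            Atom("CB", "C", (sign * 1.5, 0.0, 0.0)),
        ])
        b = Residue(1, resname, "B", [
            Atom("CA", "C", (d, 0.0, 0.0)),
            Atom("CB", "C", (d - sign * 1.5, 0.0, 0.0)),
        ])
        frames.append(Frame(chains=[[a], [b]], time=10.0 * k))
    return Trajectory(frames=frames)


GROUP_A, GROUP_B = ("A", 1, 1), ("B", 1, 1)


class TestHydrophobicOccurrence:
    def test_constant_contact_is_100(self):
        occ = hydrophobic_occurrence_map(pair_traj([5.0] * 4), GROUP_A, GROUP_B)
        assert occ.get(("A", 1), ("B", 1)) == 100.0

    def test_17_of_20_frames_is_85(self):
        distances = [5.0] * 17 + [12.0] * 3
        occ = hydrophobic_occurrence_map(pair_traj(distances), GROUP_A, GROUP_B)
        assert occ.get(("A", 1), ("B", 1)) == 85.0

    def test_beyond_cutoff_is_0(self):
        occ = hydrophobic_occurrence_map(pair_traj([10.5] * 4), GROUP_A, GROUP_B)
        assert occ.get(("A", 1), ("B", 1)) == 0.0

    @pytest.mark.parametrize(
        "distance,expected", [(9.99, 100.0), (10.0, 100.0), (10.01, 0.0)]
    )
    def test_cutoff_is_inclusive(self, distance, expected):
        occ = hydrophobic_occurrence_map(pair_traj([distance] * 5), GROUP_A, GROUP_B)
        assert occ.get(("A", 1), ("B", 1)) == expected

    def test_non_hydrophobic_residues_excluded(self):
        occ = hydrophobic_occurrence_map(pair_traj([5.0] * 4, resname="SER"), GROUP_A, GROUP_B)
        assert occ.entries == {}

    def test_occurrence_is_exact_frame_fraction(self, scheduled_dimer):
        occ = hydrophobic_occurrence_map(scheduled_dimer, ("A", 1, 42), ("B", 1, 42))
        assert occ.get(("A", 5), ("B", 5)) == 85.0
        assert occ.get(("A", 10), ("B", 10)) == 0.0
        assert occ.get(("A", 20), ("B", 20)) == 100.0
        for value in occ.entries.values():
            frames = value * occ.n_frames / 100.0
            assert frames == pytest.approx(round(frames), abs=1e-9)

    def test_symmetric_under_group_swap(self, scheduled_dimer):
        ab = hydrophobic_occurrence_map(scheduled_dimer, ("A", 1, 42), ("B", 1, 42))
        ba = hydrophobic_occurrence_map(scheduled_dimer, ("B", 1, 42), ("A", 1, 42))
        assert ab.entries == ba.entries
        assert ab.get(("A", 5), ("B", 5)) == ab.get(("B", 5), ("A", 5))


@given(k=st.integers(min_value=0, max_value=20))
@settings(deadline=None, derandomize=True, max_examples=21)
def test_occurrence_equals_contact_frame_fraction(k):
    """For any k of 20 contact frames the occurrence is exactly 5k percent."""
    distances = [5.0] * k + [14.0] * (20 - k)
    occ = hydrophobic_occurrence_map(pair_traj(distances), GROUP_A, GROUP_B)
    assert occ.get(("A", 1), ("B", 1)) == 100.0 * k / 20


class TestFacing:
    def test_facing_toward_is_1(self):
        assert facing_fraction(pair_traj([6.0] * 4), (("A", 1), ("B", 1))) == 1.0

    def test_facing_away_is_0(self):
        assert facing_fraction(pair_traj([6.0] * 4, facing=False), (("A", 1), ("B", 1))) == 0.0

    def test_alternating_frames_give_half(self):
        toward = pair_traj([6.0], facing=True).frames[0]
        away = pair_traj([6.0], facing=False).frames[0]
        frames = []
        for k in range(4):
            src = toward if k % 2 == 0 else away
            frames.append(Frame(chains=src.chains, time=10.0 * k))
        traj = Trajectory(frames=frames)
        assert facing_fraction(traj, (("A", 1), ("B", 1))) == 0.5


class TestElectrostatics:
    def test_salt_bridge_occurrence(self):
        traj = make_charged_pair_trajectory([3.5, 3.5, 3.5, 5.0])
        occ = electrostatic_occurrence_map(traj, GROUP_A, GROUP_B)
        assert occ.get(("A", 1), ("B", 1)) == 75.0

    @pytest.mark.parametrize("d,expected", [(3.99, 100.0), (4.0, 100.0), (4.01, 0.0)])
    def test_cutoff_is_inclusive(self, d, expected):
        traj = make_charged_pair_trajectory([d] * 4)
        occ = electrostatic_occurrence_map(traj, GROUP_A, GROUP_B)
        assert occ.get(("A", 1), ("B", 1)) == expected

    def test_like_charges_excluded(self):
        def lys(chain_id, x):
            return Residue(1, "LYS", chain_id, [
                Atom("CA", "C", (x, 0.0, 0.0)),
                Atom("NZ", "N", (x + 2.0, 0.0, 0.0)),
            ])

        frames = [Frame(chains=[[lys("A", 0.0)], [lys("B", 3.0)]], time=0.0)]
        occ = electrostatic_occurrence_map(Trajectory(frames=frames), GROUP_A, GROUP_B)
        assert occ.entries == {}


class TestHbonds:
    @pytest.mark.parametrize(
        "d,expected", [(2.39, 100.0), (2.4, 100.0), (2.41, 0.0)]
    )
    def test_cutoff_is_inclusive(self, d, expected):
        traj = make_hbond_pair_trajectory([d] * 3)
        occ = hbond_occurrence_map(traj, GROUP_A, GROUP_B)
        assert occ.get(("A", 1), ("B", 1)) == expected

    def test_mixed_schedule(self):
        traj = make_hbond_pair_trajectory([2.0, 3.0, 2.2, 5.0])
        occ = hbond_occurrence_map(traj, GROUP_A, GROUP_B)
        assert occ.get(("A", 1), ("B", 1)) == 50.0

    def test_structure_without_hydrogens_rejected(self):
        traj = pair_traj([2.0] * 2)  # CA/CB only, no H anywhere
        with pytest.raises(ValueError, match="hydrogens"):
            hbond_occurrence_map(traj, GROUP_A, GROUP_B)


def oracle_level(pairs, threshold=85.0, min_interactions=2):
    """Independent literal enumeration of the four contact rules.

    ``pairs`` is a list of (occurrence_pct, facing_fraction).  Rule 1:
    facing >= 0.5; rule 2: nonzero occurrence under the distance cutoff;
    rules 3+4: at least ``min_interactions`` qualifying pairs at or above
    the occurrence threshold -> strong; any qualifying pair -> weak.
    """
    qualifying = [occ for occ, facing in pairs if facing >= 0.5 and occ > 0]
    strong = [occ for occ in qualifying if occ >= threshold]
    if len(strong) >= min_interactions:
        return ContactLevel.STRONG
    if qualifying:
        return ContactLevel.WEAK
    return ContactLevel.NONE


def build_instance(pairs):
    """OccurrenceMap + facing dict over one region pair (A:1-20 vs B:1-20)."""
    entries, facing = {}, {}
    for i, (occ, face) in enumerate(pairs, start=1):
        key = (("A", i), ("B", i))
        entries[key] = occ
        facing[key] = face
    occ_map = OccurrenceMap(entries=entries, n_frames=100, criterion="hydrophobic")
    scheme_a = RegionScheme({"ra": ("A", 1, 20)})
    scheme_b = RegionScheme({"rb": ("B", 1, 20)})
    return occ_map, facing, scheme_a, scheme_b


class TestClassification:
    def test_three_strong_pairs_give_strong(self):
        occ, facing, sa, sb = build_instance([(90.0, 1.0)] * 3)
        levels = classify_region_contacts(occ, facing, sa, sb)
        assert levels[("ra", "rb")] == ContactLevel.STRONG

    def test_single_mid_occurrence_pair_gives_weak(self):
        occ, facing, sa, sb = build_instance([(60.0, 1.0)])
        levels = classify_region_contacts(occ, facing, sa, sb)
        assert levels[("ra", "rb")] == ContactLevel.WEAK

    def test_no_qualifying_pairs_give_none(self):
        occ, facing, sa, sb = build_instance([(0.0, 1.0), (50.0, 0.2)])
        levels = classify_region_contacts(occ, facing, sa, sb)
        assert levels[("ra", "rb")] == ContactLevel.NONE

    def test_boundary_two_pairs_at_85_is_strong(self):
        occ, facing, sa, sb = build_instance([(85.0, 0.5), (85.0, 0.5)])
        levels = classify_region_contacts(occ, facing, sa, sb)
        assert levels[("ra", "rb")] == ContactLevel.STRONG

    def test_matches_enumeration_oracle_on_randomized_instances(self):
        rng = np.random.default_rng(123)
        occurrences = np.array([0.0, 10.0, 50.0, 84.9, 85.0, 85.1, 100.0])
        facings = np.array([0.0, 0.4, 0.5, 0.9, 1.0])
        for _ in range(1000):
            n_pairs = int(rng.integers(0, 7))
            pairs = [
                (float(rng.choice(occurrences)), float(rng.choice(facings)))
                for _ in range(n_pairs)
            ]
            occ, facing, sa, sb = build_instance(pairs)
            levels = classify_region_contacts(occ, facing, sa, sb)
            assert levels[("ra", "rb")] == oracle_level(pairs)

    def test_raising_threshold_never_promotes_to_strong(self):
        rng = np.random.default_rng(321)
        for _ in range(200):
            pairs = [
                (float(rng.uniform(0, 100)), float(rng.choice([0.0, 0.5, 1.0])))
                for _ in range(int(rng.integers(1, 6)))
            ]
            occ, facing, sa, sb = build_instance(pairs)
            low = classify_region_contacts(
                occ, facing, sa, sb, InteractionCriteria(strong_occurrence_threshold=70.0)
            )[("ra", "rb")]
            high = classify_region_contacts(
                occ, facing, sa, sb, InteractionCriteria(strong_occurrence_threshold=95.0)
            )[("ra", "rb")]
            if high == ContactLevel.STRONG:
                assert low == ContactLevel.STRONG

    def test_region_level_on_scheduled_dimer(self, scheduled_dimer):
        from mdinteract import facing_fractions

        occ = hydrophobic_occurrence_map(scheduled_dimer, ("A", 1, 42), ("B", 1, 42))
        facing = facing_fractions(scheduled_dimer, occ)
        sa = RegionScheme({"n_half": ("A", 1, 21), "c_half": ("A", 22, 42)})
        sb = RegionScheme({"partner": ("B", 1, 42)})
        levels = classify_region_contacts(occ, facing, sa, sb)
        # The 85% contact and its chain neighbours sit in A's first half
        # (several qualifying pairs >= 85% -> strong); the second half holds
        # only one 100% pair (A:22-B:20), short of the >=2 count -> weak.
        assert levels[("n_half", "partner")] == ContactLevel.STRONG
        assert levels[("c_half", "partner")] == ContactLevel.WEAK
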