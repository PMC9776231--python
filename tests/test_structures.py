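"""Structure model, multi-model PDB I/O, and residue selection."""

import numpy as np
import pytest

from mdinteract import (
    Atom,
    Frame,
    PdbParseError,
    RegionScheme,
    Residue,
    SelectionError,
    TopologyError,
    Trajectory,
    read_pdb,
    select,
    select_region,
    write_pdb,
)
from mdinteract.structures import ide_domain_scheme


def ca_chain(n, chain_id="A", first=1, spacing=3.8):
    """Simple non-collinear Cα-only chain for selection tests."""
    return [
        Residue(
            index=first + i,
            name="ALA",
            chain_id=chain_id,
            atoms=[Atom("CA", "C", (spacing * i, 0.5 * (i % 2), 0.0), serial=i + 1)],
        )
        for i in range(n)
    ]


class TestTypes:
    def test_atom_rejects_nonfinite_coords(self):
        with pytest.raises(ValueError):
            Atom("CA", "C", (np.nan, 0, 0))

    def test_residue_rejects_duplicate_atom_names(self):
        a = Atom("CA", "C", (0, 0, 0))
        with pytest.raises(ValueError, match="duplicate"):
            Residue(1, "ALA", "A", [a, Atom("CA", "C", (1, 0, 0))])

    def test_trajectory_requires_increasing_times(self):
        f = Frame(chains=[ca_chain(3)], time=0.0)
        g = Frame(chains=[ca_chain(3)], time=0.0)
        with pytest.raises(ValueError, match="strictly increasing"):
            Trajectory(frames=[f, g])

    def test_trajectory_rejects_topology_mismatch(self):
        f = Frame(chains=[ca_chain(3)], time=0.0)
        g = Frame(chains=[ca_chain(4)], time=10.0)
        with pytest.raises(TopologyError):
            Trajectory(frames=[f, g])

    def test_region_scheme_rejects_inverted_range(self):
        with pytest.raises(ValueError):
            RegionScheme({"r": ("A", 10, 5)})


class TestPdbRoundTrip:
    def test_round_trip_coordinates_and_topology(self, scheduled_dimer, tmp_path):
        sub = Trajectory(frames=scheduled_dimer.frames[:3])
        path = write_pdb(sub, tmp_path / "t.pdb")
        back = read_pdb(path)
        assert len(back) == 3
        assert back.frames[0].chain_ids == ["A", "B"]
        for fa, fb in zip(sub.frames, back.frames):
            for ra, rb in zip(fa.residues(), fb.residues()):
                assert (ra.chain_id, ra.index, ra.name) == (rb.chain_id, rb.index, rb.name)
                for aa, ab in zip(ra.atoms, rb.atoms):
                    assert aa.name == ab.name
                    np.testing.assert_allclose(aa.coords, ab.coords, atol=1e-3)

    def test_round_trip_matches_independent_parser(self, helix20, tmp_path):
        """Cross-check the writer against Biopython's reader."""
        from Bio.PDB import PDBParser

        path = write_pdb(Trajectory(frames=[helix20]), tmp_path / "h.pdb")
        structure = PDBParser(QUIET=True).get_structure("h", str(path))
        bio_coords = np.array([a.get_coord() for a in structure.get_atoms()])
        own_coords = np.array(
            [a.coords for r in helix20.residues() for a in r.atoms]
        )
        np.testing.assert_allclose(bio_coords, own_coords, atol=1e-3)

    def test_empty_trajectory_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            write_pdb("not a trajectory", tmp_path / "x.pdb")

    def test_single_model_file(self, tmp_path):
        path = write_pdb(Trajectory(frames=[Frame(chains=[ca_chain(5), ca_chain(5, "B")])]), tmp_path / "s.pdb")
        traj = read_pdb(path)
        assert len(traj) == 1
        assert traj.frames[0].chain_ids == ["A", "B"]

    def test_malformed_atom_line_names_line(self, tmp_path):
        bad = tmp_path / "bad.pdb"
        bad.write_text(
            "ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C\n"
            "ATOM      2  CA  ALA A   2       x.yyy   0.000   0.000  1.00  0.00           C\n"
            "END\n"
        )
        with pytest.raises(PdbParseError, match="line 2"):
            read_pdb(bad)

    def test_model_missing_residue_is_topology_error(self, tmp_path):
        def model(n, k):
            lines = [f"MODEL     {k:4d}"]
            for i in range(1, n + 1):
                lines.append(
                    f"ATOM  {i:5d}  CA  ALA A{i:4d}    {float(i):8.3f}{0.5*(i%2):8.3f}{0.0:8.3f}  1.00  0.00           C"
                )
            lines.append("ENDMDL")
            return "\n".join(lines)

        path = tmp_path / "m.pdb"
        path.write_text(model(4, 1) + "\n" + model(3, 2) + "\nEND\n")
        with pytest.raises(TopologyError):
            read_pdb(path)

    def test_waters_and_hetatms_skipped(self, tmp_path):
        path = tmp_path / "w.pdb"
        path.write_text(
            "ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C\n"
            "ATOM      2  CA  ALA A   2       3.800   0.500   0.000  1.00  0.00           C\n"
            "HETATM    3  O   HOH A 101      10.000  10.000  10.000  1.00  0.00           O\n"
            "HETATM    4 ZN    ZN A 102      12.000  12.000  12.000  1.00  0.00          ZN\n"
            "END\n"
        )
        traj = read_pdb(path)
        assert [r.index for r in traj.frames[0].residues()] == [1, 2]

    def test_frame_times_follow_frame_interval(self, scheduled_dimer, tmp_path):
        sub = Trajectory(frames=scheduled_dimer.frames[:3])
        path = write_pdb(sub, tmp_path / "t.pdb")
        traj = read_pdb(path, frame_interval=10.0)
        np.testing.assert_allclose(traj.times, [0.0, 10.0, 20.0])


class TestSelect:
    @pytest.fixture()
    def frame(self):
        return Frame(chains=[ca_chain(42), ca_chain(10, "B")])

    def test_ca_range_selection(self, frame):
        coords, idx = select(frame, "A", 1, 16, ("CA",))
        assert coords.shape == (16, 3)
        assert idx == list(range(1, 17))

    def test_all_atoms_of_one_residue(self, frame):
        coords, idx = select(frame, "A", 3, 3)
        assert coords.shape == (1, 3)  # CA-only chain

    def test_region_scheme_domain_size(self):
        # The first protease domain spans residues 43-285: 243 residues.
        frame = Frame(chains=[ca_chain(300, first=1)])
        coords, idx = select_region(frame, ide_domain_scheme("A"), "domain1", ("CA",))
        assert coords.shape == (243, 3)
        assert idx[0] == 43 and idx[-1] == 285

    def test_missing_chain_and_range_errors(self, frame):
        with pytest.raises(SelectionError):
            select(frame, "C", 1, 5)
        with pytest.raises(SelectionError):
            select(frame, "B", 5, 20)

    def test_missing_atom_names_residue(self, frame):
        with pytest.raises(SelectionError, match="CB"):
            select(frame, "A", 1, 3, ("CB",))

    def test_selection_idempotent_and_ordered(self, frame):
        first = select(frame, "A", 10, 20, ("CA",))
        second = select(frame, "A", 10, 20, ("CA",))
        np.testing.assert_array_equal(first[0], second[0])
        assert first[1] == sorted(first[1])
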