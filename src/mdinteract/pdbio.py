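"""Multi-model PDB input and output.

Reading is backed by Biopython's strict PDB parser (which names the offending
line on malformed records); the parsed models are converted into the package's
:class:`~mdinteract.structures.Trajectory`, and topology consistency across
models is enforced there.  Writing emits fixed-width ATOM records directly;
PDB precision limits coordinates to 0.001 Å, which bounds the round-trip error.

HETATM records, waters and ions are skipped on read (a count is logged).
Alternate locations keep the highest-occupancy conformer, Biopython's default.
Insertion codes are rejected: the systems this package targets do not use them,
and silently merging them would corrupt 1-based residue numbering.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path

from Bio.PDB import PDBParser
from Bio.PDB.PDBExceptions import PDBConstructionException, PDBConstructionWarning

from .structures import Atom, Frame, Residue, Trajectory

__all__ = ["PdbParseError", "read_pdb", "write_pdb"]

logger = logging.getLogger(__name__)


class PdbParseError(ValueError):
    """The PDB file could not be parsed into a consistent trajectory."""


def read_pdb(path: str | Path, frame_interval: float = 10.0) -> Trajectory:
    """Read a (multi-model) PDB file into a :class:`Trajectory`.

    Each MODEL becomes one frame; a file without MODEL records yields a
    single-frame trajectory.  Frames are stamped ``(model_index - 1) *
    frame_interval`` ps, matching saved-frame spacing (default 10 ps).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    parser = PDBParser(PERMISSIVE=0, QUIET=True)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", PDBConstructionWarning)
            structure = parser.get_structure(path.stem, str(path))
    except PDBConstructionException as exc:
        raise PdbParseError(f"{path}: {exc}") from exc

    frames: list[Frame] = []
    n_skipped = 0
    for m, model in enumerate(structure):
        chains: list[list[Residue]] = []
        for chain in model:
            residues: list[Residue] = []
            for res in chain:
                hetflag, resseq, icode = res.id
                if hetflag != " ":
                    n_skipped += 1
                    continue
                if icode != " ":
                    raise PdbParseError(
                        f"{path}: residue {res.resname}{resseq} chain {chain.id} carries "
                        f"insertion code {icode!r}; insertion codes are not supported"
                    )
                atoms = [
                    Atom(
                        name=a.get_name(),
                        element=(a.element or "").strip() or _infer_element(a.get_name()),
                        coords=a.get_coord(),
                        serial=int(a.get_serial_number() or 0),
                    )
                    for a in res  # DisorderedAtom yields its highest-occupancy child
                ]
                residues.append(Residue(resseq, res.resname.strip(), chain.id, atoms))
            if residues:
                chains.append(residues)
        if not chains:
            raise PdbParseError(f"{path}: model {m + 1} contains no protein residues")
        frames.append(Frame(chains=chains, time=m * frame_interval))
    if n_skipped:
        logger.info("%s: skipped %d HETATM/water/ion residues", path, n_skipped)
    if not frames:
        raise PdbParseError(f"{path}: no coordinate models found")
    return Trajectory(frames=frames, frame_interval=frame_interval)


def _infer_element(atom_name: str) -> str:
    """Element from the leading letters of the atom name (PDB fallback)."""
    stripped = atom_name.strip().lstrip("0123456789")
    if len(stripped) >= 2 and stripped[:2].upper() in {"CL", "BR", "FE", "ZN", "MG", "NA", "SE"}:
        return stripped[:2].capitalize()
    return stripped[:1].upper()


def _format_atom_name(name: str, element: str) -> str:
    # Names shorter than 4 chars start in column 14 when the element symbol is
    # a single letter; 4-char names and 2-letter elements start in column 13.
    if len(name) >= 4 or len(element) == 2:
        return f"{name:<4s}"[:4]
    return f" {name:<3s}"


def write_pdb(traj: Trajectory, path: str | Path) -> Path:
    """Write a trajectory as a multi-model PDB file and return the path."""
    if not isinstance(traj, Trajectory) or len(traj.frames) == 0:
        raise ValueError("write_pdb requires a non-empty Trajectory")
    path = Path(path)
    lines: list[str] = []
    multi = len(traj) > 1
    for m, frame in enumerate(traj.frames, start=1):
        if multi:
            lines.append(f"MODEL     {m:4d}")
        serial = 0
        for chain in frame.chains:
            for res in chain:
                for atom in res.atoms:
                    serial += 1
                    x, y, z = atom.coords
                    lines.append(
                        f"ATOM  {serial:5d} {_format_atom_name(atom.name, atom.element)} "
                        f"{res.name:>3s} {res.chain_id:1s}{res.index:4d}    "
                        f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                        f"          {atom.element:>2s}"
                    )
            lines.append("TER")
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")
    return path
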