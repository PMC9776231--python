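"""Rigid-body superposition and the RMSD/RMSF convergence metrics.

The optimal rotation is the Kabsch solution, obtained via
``scipy.spatial.transform.Rotation.align_vectors`` on centered coordinates,
which guarantees a proper rotation (determinant +1).  RMSD series are fitted
per frame against a reference frame; RMSF uses an iteratively refined mean
structure as reference, since a single arbitrary frame would bias the
per-residue fluctuations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .structures import AnalysisWindow, Trajectory, select

__all__ = [
    "GeometryError",
    "RmsdSeries",
    "RmsfProfile",
    "kabsch_superpose",
    "rmsd_series",
    "rmsf",
]


class GeometryError(ValueError):
    """Point sets are too small or degenerate for a unique superposition."""


@dataclass
class RmsdSeries:
    """Per-frame RMSD (Å) against a fitted reference."""

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have equal length")
        if np.any(self.values < 0):
            raise ValueError("RMSD values must be non-negative")


@dataclass
class RmsfProfile:
    """Per-residue root-mean-square fluctuation (Å) about the mean structure."""

    residue_indices: list[int]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.residue_indices) != self.values.size:
            raise ValueError("residue_indices and values must have equal length")
        if np.any(self.values < 0):
            raise ValueError("RMSF values must be non-negative")


def kabsch_superpose(
    mobile: np.ndarray, reference: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    Returns ``(rotation, translation, rmsd)`` such that
    ``mobile @ rotation.T + translation`` best matches ``reference``.  The
    rotation is proper (det +1) and the RMSD is the global minimum over all
    rigid motions.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise GeometryError("mobile and reference must be matching (n, 3) arrays")
    n = mobile.shape[0]
    if n < 3:
        raise GeometryError("superposition needs at least 3 points")
    if not (np.all(np.isfinite(mobile)) and np.all(np.isfinite(reference))):
        raise GeometryError("coordinates must be finite")
    mob_center = mobile.mean(axis=0)
    ref_center = reference.mean(axis=0)
    mob_c = mobile - mob_center
    ref_c = reference - ref_center
    if np.linalg.matrix_rank(mob_c, tol=1e-8) < 2 or np.linalg.matrix_rank(ref_c, tol=1e-8) < 2:
        raise GeometryError("degenerate (collinear) point set: rotation is not unique")
    if np.array_equal(mobile, reference):
        # Identical inputs need no fit; short-circuit keeps the zero exact.
        return np.eye(3), np.zeros(3), 0.0
    rot, _ = Rotation.align_vectors(ref_c, mob_c)
    rotation = rot.as_matrix()
    # Recompute the residual from the fitted coordinates: the SVD-derived
    # residual loses half the significant digits near zero.
    rmsd = float(np.sqrt(np.mean(np.sum((mob_c @ rotation.T - ref_c) ** 2, axis=1))))
    translation = ref_center - rotation @ mob_center
    return rotation, translation, rmsd


def _traj_coords(
    traj: Trajectory, selection: tuple[str, int, int], atom_names: Sequence[str]
) -> tuple[np.ndarray, list[int]]:
    """Stack selected coordinates over frames: (n_frames, n_atoms, 3)."""
    chain_id, first, last = selection
    coords = []
    indices: list[int] = []
    for frame in traj.frames:
        xyz, idx = select(frame, chain_id, first, last, atom_names)
        coords.append(xyz)
        indices = idx
    return np.array(coords), indices


def rmsd_series(
    traj: Trajectory,
    reference_frame: int = 0,
    selection: tuple[str, int, int] | None = None,
    atom_names: Sequence[str] = ("CA",),
) -> RmsdSeries:
    """Cα RMSD of every frame against a reference frame, after optimal fit.

    ``selection`` is ``(chain_id, first, last)``; ``None`` uses the whole
    first chain.  The fitted atom set defaults to Cα.
    """
    if not (-len(traj) <= reference_frame < len(traj)):
        raise IndexError(f"reference frame {reference_frame} out of range for {len(traj)} frames")
    if selection is None:
        chain = traj.frames[0].chains[0]
        selection = (chain[0].chain_id, chain[0].index, chain[-1].index)
    coords, _ = _traj_coords(traj, selection, atom_names)
    ref = coords[reference_frame]
    values = np.array([kabsch_superpose(frame_xyz, ref)[2] for frame_xyz in coords])
    return RmsdSeries(times=traj.times, values=values)


def rmsf(
    traj: Trajectory,
    selection: tuple[str, int, int] | None = None,
    window: AnalysisWindow | None = None,
    atom_names: Sequence[str] = ("CA",),
    max_iter: int = 10,
    tol: float = 1e-6,
) -> RmsfProfile:
    """Per-residue RMSF about the iteratively refined mean structure.

    Every window frame is superposed onto the running mean; the mean is
    recomputed until it moves less than ``tol`` Å (two iterations typically
    suffice).  The RMSF of a residue is the root of the mean squared
    deviation of its selected atom from its mean position.
    """
    if selection is None:
        chain = traj.frames[0].chains[0]
        selection = (chain[0].chain_id, chain[0].index, chain[-1].index)
    coords, indices = _traj_coords(traj, selection, atom_names)
    if window is not None:
        coords = coords[traj.window_indices(window)]
    if coords.shape[0] < 2:
        raise ValueError("RMSF needs at least 2 frames in the window")

    if np.all(coords == coords[0]):
        # Constant ensemble: fluctuations are exactly zero by definition.
        uniq = sorted(set(indices), key=indices.index)
        return RmsfProfile(residue_indices=uniq, values=np.zeros(len(uniq)))

    fitted = coords.copy()
    mean = fitted[0].copy()
    for _ in range(max_iter):
        for k in range(fitted.shape[0]):
            rotation, translation, _ = kabsch_superpose(fitted[k], mean)
            fitted[k] = fitted[k] @ rotation.T + translation
        new_mean = fitted.mean(axis=0)
        shift = float(np.max(np.linalg.norm(new_mean - mean, axis=1)))
        mean = new_mean
        if shift < tol:
            break

    sq_dev = np.sum((fitted - mean) ** 2, axis=2)  # (n_frames, n_atoms)
    per_atom = np.sqrt(sq_dev.mean(axis=0))
    if len(atom_names) == 1:
        return RmsfProfile(residue_indices=indices, values=per_atom)
    # Multiple atoms per residue: aggregate by residue (mean square over atoms).
    uniq = sorted(set(indices), key=indices.index)
    agg = []
    idx_arr = np.array(indices)
    msd_atoms = sq_dev.mean(axis=0)
    for u in uniq:
        agg.append(np.sqrt(msd_atoms[idx_arr == u].mean()))
    return RmsfProfile(residue_indices=uniq, values=np.array(agg))
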