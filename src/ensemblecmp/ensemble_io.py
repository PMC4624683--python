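"""Loading, writing and superposing conformational ensembles.

An :class:`Ensemble` is an ordered set of conformations of one molecule:
a ``(frames, atoms, 3)`` coordinate array in Å plus minimal atom metadata.
File reading/writing is delegated to MDAnalysis, which handles multi-model
PDB files and the common MD trajectory formats (DCD/XTC/TRR with a PDB/GRO
topology) and always reports coordinates in Å.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .exceptions import (
    DataError,
    FormatError,
    NumericalError,
    SelectionError,
    ShapeError,
    TopologyError,
)

__all__ = [
    "AtomSelection",
    "Ensemble",
    "load_ensemble",
    "write_ensemble_pdb",
    "superpose_ensemble",
    "kabsch_rotation",
    "kabsch_rmsd",
]

DEFAULT_SELECTION = "name CA"


@dataclass
class AtomSelection:
    """An atom selection: an MDAnalysis-style expression plus, once applied
    to a concrete topology, the resolved atom indices (0-based, increasing)."""

    expression: str = DEFAULT_SELECTION
    resolved_indices: np.ndarray | None = None

    def resolve(self, universe) -> np.ndarray:
        try:
            group = universe.select_atoms(self.expression)
        except Exception as exc:  # MDAnalysis raises bare SelectionError/ValueError
            raise SelectionError(
                f"cannot parse selection {self.expression!r}: {exc}"
            ) from exc
        if len(group) == 0:
            raise SelectionError(
                f"selection {self.expression!r} resolves to 0 atoms"
            )
        self.resolved_indices = np.asarray(group.ix, dtype=np.int64)
        return self.resolved_indices


@dataclass
class Ensemble:
    """An ordered conformational ensemble of one molecule.

    Attributes
    ----------
    label : text identifier used in reports.
    coords : ``(n_frames, n_atoms, 3)`` float64 array, Å.
    atom_names, residue_ids : per-atom metadata, identical for every frame.
    frame_times : optional per-frame times in ns.
    """

    label: str
    coords: np.ndarray
    atom_names: Sequence[str] = field(default_factory=list)
    residue_ids: Sequence[int] = field(default_factory=list)
    frame_times: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.float64)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ShapeError(
                f"coords must be (frames, atoms, 3), got {self.coords.shape}"
            )
        if self.coords.shape[0] < 1 or self.coords.shape[1] < 1:
            raise DataError("an ensemble needs at least one frame and one atom")
        if not np.isfinite(self.coords).all():
            raise DataError("ensemble coordinates contain non-finite values")
        if not self.atom_names:
            self.atom_names = ["CA"] * self.n_atoms
        if len(self.residue_ids) == 0:
            self.residue_ids = list(range(1, self.n_atoms + 1))
        if len(self.atom_names) != self.n_atoms or len(self.residue_ids) != self.n_atoms:
            raise ShapeError("atom metadata length does not match atom count")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    @property
    def flat(self) -> np.ndarray:
        """Frames as flattened 3N-vectors, shape ``(n_frames, 3 * n_atoms)``."""
        return self.coords.reshape(self.n_frames, -1)

    def subset(self, frame_indices, label: str | None = None) -> "Ensemble":
        """A new ensemble restricted to (or resampled over) the given frames."""
        idx = np.asarray(frame_indices, dtype=np.int64)
        return Ensemble(
            label=label or self.label,
            coords=self.coords[idx].copy(),
            atom_names=list(self.atom_names),
            residue_ids=list(self.residue_ids),
            frame_times=None if self.frame_times is None else self.frame_times[idx],
        )


def load_ensemble(
    topology_path,
    trajectory_paths: Sequence = (),
    selection: AtomSelection | str = DEFAULT_SELECTION,
    frame_stride: int = 1,
    label: str | None = None,
) -> Ensemble:
    """Load an ensemble from a topology plus optional trajectory files.

    A multi-model PDB can be passed alone (its MODEL records become frames).
    ``frame_stride`` keeps every ``stride``-th frame starting at the first,
    so the result has ``ceil(total_frames / stride)`` frames. Coordinates
    are in Å regardless of the source format's native unit (MDAnalysis
    converts nm-based formats on read).
    """
    import MDAnalysis as mda

    if frame_stride < 1:
        raise DataError("frame_stride must be a positive integer")
    if isinstance(selection, str):
        selection = AtomSelection(selection)
    paths = [str(topology_path)] + [str(p) for p in trajectory_paths]
    for p in paths:
        if not Path(p).exists():
            raise FormatError(f"file not found: {p}")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if trajectory_paths:
                universe = mda.Universe(paths[0], *paths[1:])
            else:
                universe = mda.Universe(paths[0])
    except Exception as exc:
        msg = str(exc)
        if "atom" in msg.lower() or "topology" in msg.lower():
            raise TopologyError(
                f"inconsistent topology across {paths}: {msg}"
            ) from exc
        raise FormatError(f"cannot read {paths}: {msg}") from exc

    indices = selection.resolve(universe)
    group = universe.atoms[indices]
    frames = []
    times = []
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for ts in universe.trajectory[::frame_stride]:
                frames.append(group.positions.astype(np.float64).copy())
                times.append(getattr(ts, "time", 0.0))
    except Exception as exc:
        raise TopologyError(
            f"trajectory frame incompatible with topology in {paths}: {exc}"
        ) from exc

    coords = np.asarray(frames)
    frame_times = np.asarray(times, dtype=np.float64) / 1000.0  # ps -> ns
    if not np.any(np.diff(frame_times) > 0):
        frame_times = None
    return Ensemble(
        label=label or Path(paths[-1]).stem,
        coords=coords,
        atom_names=[str(n) for n in group.names],
        residue_ids=[int(r) for r in group.resids],
        frame_times=frame_times,
    )


def write_ensemble_pdb(ens: Ensemble, path) -> None:
    """Write an ensemble as a multi-model PDB file (one MODEL per frame)."""
    import MDAnalysis as mda

    resids = np.asarray(ens.residue_ids, dtype=np.int64)
    unique_resids, resindex = np.unique(resids, return_inverse=True)
    universe = mda.Universe.empty(
        ens.n_atoms,
        n_residues=len(unique_resids),
        atom_resindex=resindex,
        residue_segindex=np.zeros(len(unique_resids), dtype=np.int64),
        trajectory=True,
    )
    universe.add_TopologyAttr("names", list(ens.atom_names))
    universe.add_TopologyAttr("resids", unique_resids)
    universe.add_TopologyAttr("resnames", ["ALA"] * len(unique_resids))
    universe.add_TopologyAttr("segids", ["A"])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(str(path), n_atoms=ens.n_atoms, multiframe=True) as writer:
            for frame in ens.coords:
                universe.atoms.positions = frame
                writer.write(universe.atoms)


# ---------------------------------------------------------------------------
# Rigid-body superposition (Kabsch least squares)
# ---------------------------------------------------------------------------

def kabsch_rotation(mobile_centered: np.ndarray, ref_centered: np.ndarray) -> np.ndarray:
    """Least-squares rotation ``R`` with ``mobile @ R ~= ref`` (both centered)."""
    h = mobile_centered.T @ ref_centered
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(u @ vt))
    return (u * np.array([1.0, 1.0, d])) @ vt


def kabsch_rmsd(frame_a: np.ndarray, frame_b: np.ndarray) -> float:
    """Minimum RMSD between two frames via an explicit SVD Kabsch solve.

    Slower than the production kernel in :mod:`ensemblecmp.distance_matrix`
    but fully independent of it; used as a reference in the tests.
    """
    a = np.asarray(frame_a, float)
    b = np.asarray(frame_b, float)
    if a.shape != b.shape:
        raise ShapeError(f"atom counts differ: {a.shape} vs {b.shape}")
    ac = a - a.mean(axis=0)
    bc = b - b.mean(axis=0)
    rot = kabsch_rotation(ac, bc)
    diff = ac @ rot - bc
    return float(np.sqrt((diff * diff).sum() / a.shape[0]))


def _check_reference_nondegenerate(ref: np.ndarray) -> None:
    centered = ref - ref.mean(axis=0)
    # gyration spectrum: two vanishing directions = collinear or coincident
    svals = np.linalg.svd(centered, compute_uv=False)
    if svals[0] == 0.0 or svals[1] / svals[0] < 1e-10:
        raise NumericalError(
            "reference structure is degenerate (atoms coincident or collinear); "
            "rotation is underdetermined"
        )


def superpose_ensemble(ens: Ensemble, reference="average") -> Ensemble:
    """Rigid-body superpose every frame onto a reference.

    ``reference`` is either a single-frame ``(n_atoms, 3)`` coordinate array
    or ``"average"``, which iteratively aligns to the ensemble mean (align,
    recompute mean, repeat until the mean moves < 1e-6 Å or 10 iterations).
    """
    coords = ens.coords.copy()
    if isinstance(reference, str):
        if reference != "average":
            raise DataError(f"unknown reference mode {reference!r}")
        ref = coords.mean(axis=0)
        _check_reference_nondegenerate(coords[0])
        for _ in range(10):
            coords = _align_all(coords, ref)
            new_ref = coords.mean(axis=0)
            shift = np.sqrt(((new_ref - ref) ** 2).sum(axis=1).mean())
            ref = new_ref
            if shift < 1e-6:
                break
    else:
        ref = np.asarray(reference, dtype=np.float64)
        if ref.shape != (ens.n_atoms, 3):
            raise ShapeError(
                f"reference shape {ref.shape} != (n_atoms, 3) = ({ens.n_atoms}, 3)"
            )
        _check_reference_nondegenerate(ref)
        coords = _align_all(coords, ref)
    return Ensemble(
        label=ens.label,
        coords=coords,
        atom_names=list(ens.atom_names),
        residue_ids=list(ens.residue_ids),
        frame_times=None if ens.frame_times is None else ens.frame_times.copy(),
    )


def _align_all(coords: np.ndarray, ref: np.ndarray) -> np.ndarray:
    ref_centroid = ref.mean(axis=0)
    ref_centered = ref - ref_centroid
    out = np.empty_like(coords)
    for k in range(coords.shape[0]):
        frame = coords[k]
        centered = frame - frame.mean(axis=0)
        rot = kabsch_rotation(centered, ref_centered)
        out[k] = centered @ rot + ref_centroid
    return out
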