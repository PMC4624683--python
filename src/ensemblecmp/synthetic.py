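"""Synthetic ensembles with known ground truth.

Fixtures emulate conformations sampled from one or more harmonic wells:
each state is a reference conformation (a self-avoiding random chain with
protein-Calpha-like 3.8 Å spacing) plus isotropic Gaussian displacements
of controllable amplitude, and multi-state ensembles draw each frame's
state from stated population fractions. State choice and displacement
noise use separate random streams so that changing populations does not
perturb the within-state geometry for a given seed. These are statistical
stand-ins for MD ensembles, not physical ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .distance_matrix import pairwise_rmsd
from .ensemble_io import Ensemble
from .exceptions import DataError

__all__ = [
    "SyntheticSpec",
    "make_chain_center",
    "displaced_center",
    "make_harmonic_ensemble",
    "make_multistate_ensemble",
]

CHAIN_BOND_LENGTH = 3.8  # Å, Calpha-Calpha virtual bond
CHAIN_MIN_SEPARATION = 3.0  # Å, self-avoidance radius


@dataclass
class SyntheticSpec:
    """Ground-truth description of a synthetic ensemble.

    ``states`` is a sequence of ``(center, amplitude, population)`` tuples:
    a ``(n_atoms, 3)`` reference conformation, the per-coordinate Gaussian
    fluctuation amplitude in Å, and the state's population fraction.
    """

    n_atoms: int
    states: Sequence[tuple]
    n_frames: int
    seed: int = 0
    label: str = "synthetic"
    n_modes: int | None = None

    def __post_init__(self) -> None:
        if self.n_frames < 1 or self.n_atoms < 1:
            raise DataError("n_frames and n_atoms must be positive")
        if not self.states:
            raise DataError("at least one state is required")
        pops = np.array([s[2] for s in self.states], dtype=np.float64)
        if (pops < 0).any() or abs(pops.sum() - 1.0) > 1e-9:
            raise DataError("populations must be non-negative and sum to 1")
        for center, amplitude, _ in self.states:
            if np.asarray(center).shape != (self.n_atoms, 3):
                raise DataError("every state center must be (n_atoms, 3)")
            if amplitude <= 0:
                raise DataError("fluctuation amplitudes must be positive")
        if self.n_modes is not None and not 1 <= self.n_modes <= 3 * self.n_atoms:
            raise DataError("n_modes must be in [1, 3 * n_atoms]")

    @property
    def populations(self) -> np.ndarray:
        return np.array([s[2] for s in self.states], dtype=np.float64)


def make_chain_center(n_atoms: int, seed: int = 0) -> np.ndarray:
    """A self-avoiding random chain with 3.8 Å spacing (Calpha-like scale)."""
    rng = np.random.default_rng(seed)
    coords = np.zeros((n_atoms, 3))
    for a in range(1, n_atoms):
        for _ in range(1000):
            step = rng.standard_normal(3)
            step *= CHAIN_BOND_LENGTH / np.linalg.norm(step)
            candidate = coords[a - 1] + step
            dists = np.linalg.norm(coords[: a - 1] - candidate, axis=1)
            if a == 1 or dists.min() >= CHAIN_MIN_SEPARATION:
                coords[a] = candidate
                break
        else:  # pragma: no cover - effectively unreachable
            raise DataError("failed to grow a self-avoiding chain")
    return coords


def displaced_center(
    center: np.ndarray, target_rmsd: float, seed: int = 0, tol: float = 1e-3
) -> np.ndarray:
    """A second reference conformation at a requested minimum RMSD.

    A random internal deformation of ``center`` is scaled (by bisection on
    the superposition-minimized RMSD) until it sits ``target_rmsd`` Å away.
    """
    if target_rmsd <= 0:
        raise DataError("target_rmsd must be positive")
    center = np.asarray(center, dtype=np.float64)
    rng = np.random.default_rng(seed)
    direction = rng.standard_normal(center.shape)
    lo, hi = 0.0, 1.0
    while pairwise_rmsd(center, center + hi * direction) < target_rmsd:
        hi *= 2.0
        if hi > 1e6:
            raise DataError("cannot reach the requested separation")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if pairwise_rmsd(center, center + mid * direction) < target_rmsd:
            lo = mid
        else:
            hi = mid
        if hi - lo < tol / max(1.0, np.abs(direction).max()):
            break
    return center + 0.5 * (lo + hi) * direction


def _noise_stream(seed: int):
    state_rng, noise_rng, mode_rng = [
        np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(3)
    ]
    return state_rng, noise_rng, mode_rng


def _state_modes(spec: SyntheticSpec, mode_rng) -> list[np.ndarray] | None:
    """Random orthonormal collective-mode bases, one per state.

    ``n_modes`` restricts each well's fluctuation to that many collective
    degrees of freedom (MD basins are low-dimensional); mode amplitudes
    are scaled so the total variance matches the isotropic case, i.e. the
    per-coordinate fluctuation still averages ``amplitude**2``.
    """
    if spec.n_modes is None:
        return None
    d = 3 * spec.n_atoms
    bases = []
    for _ in spec.states:
        q, _ = np.linalg.qr(mode_rng.standard_normal((d, spec.n_modes)))
        bases.append(q)
    return bases


def _well_displacements(noise, amplitude, d, basis):
    """Map unit-normal draws to well displacements (isotropic or low-rank)."""
    if basis is None:
        return noise * amplitude
    k = basis.shape[1]
    return (noise[:, :k] * (amplitude * np.sqrt(d / k))) @ basis.T


def make_harmonic_ensemble(spec: SyntheticSpec) -> Ensemble:
    """Frames from a single harmonic well: center + Gaussian displacements."""
    if len(spec.states) != 1:
        raise DataError("make_harmonic_ensemble expects exactly one state")
    _, noise_rng, mode_rng = _noise_stream(spec.seed)
    bases = _state_modes(spec, mode_rng)
    center, amplitude, _ = spec.states[0]
    d = 3 * spec.n_atoms
    noise = noise_rng.standard_normal((spec.n_frames, d))
    disp = _well_displacements(noise, amplitude, d, None if bases is None else bases[0])
    coords = np.asarray(center).reshape(1, -1) + disp
    return Ensemble(label=spec.label, coords=coords.reshape(spec.n_frames, spec.n_atoms, 3))


def make_multistate_ensemble(spec: SyntheticSpec):
    """Frames from a mixture of harmonic wells; returns (Ensemble, state labels).

    Frame ``t`` draws its state from the population fractions (one stream)
    and its displacement from an independent noise stream, so the same seed
    yields the same within-state geometry under different populations.
    """
    if len(spec.states) < 2:
        raise DataError("make_multistate_ensemble expects >= 2 states")
    state_rng, noise_rng, mode_rng = _noise_stream(spec.seed)
    bases = _state_modes(spec, mode_rng)
    labels = state_rng.choice(
        len(spec.states), size=spec.n_frames, p=spec.populations
    )
    d = 3 * spec.n_atoms
    noise = noise_rng.standard_normal((spec.n_frames, d))
    coords = np.empty((spec.n_frames, d))
    for s, (center, amplitude, _) in enumerate(spec.states):
        members = labels == s
        disp = _well_displacements(
            noise[members], amplitude, d, None if bases is None else bases[s]
        )
        coords[members] = np.asarray(center).reshape(1, -1) + disp
    return (
        Ensemble(label=spec.label, coords=coords.reshape(spec.n_frames, spec.n_atoms, 3)),
        labels,
    )
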