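"""Dimensionality-reduction ensemble similarity (DRES).

All frames are projected into a low-dimensional space (default 3D) with
stochastic proximity embedding (SPE): random frame pairs are repeatedly
pulled toward their target RMSD whenever the target is within the
neighborhood cutoff, or pushed apart when the embedded distance
underestimates a far pair; the learning rate anneals linearly over the
cycles and the number of pair updates per cycle scales linearly with the
number of frames. Per-ensemble Gaussian kernel densities (diagonal
Silverman bandwidth) are then compared with a resubstitution Monte-Carlo
estimate of the Jensen-Shannon divergence, clipped to [0, ln 2].
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from numba import njit

from .ces import LN2
from .distance_matrix import CondensedDistanceMatrix, rmsd_matrix
from .ensemble_io import Ensemble
from .exceptions import DataError, InputError, InsufficientDataError

__all__ = [
    "EmbeddedSpace",
    "DensityModel",
    "spe_embed",
    "fit_kde",
    "js_divergence_kde",
    "dres_divergence",
]

logger = logging.getLogger(__name__)

DEFAULT_DIM = 3
DEFAULT_CYCLES = 100
#: pair updates per annealing cycle, as a multiple of the point count
UPDATES_PER_CYCLE_FACTOR = 10
DEFAULT_LEARNING_RATE_INITIAL = 2.0
DEFAULT_LEARNING_RATE_FINAL = 0.05
#: multiple of the median pairwise RMSD used for the default cutoff
DEFAULT_CUTOFF_FACTOR = 1.5
#: density floor applied before taking logs
DENSITY_FLOOR = 1e-300
#: bandwidth floor (embedding units) for zero-variance dimensions
BANDWIDTH_FLOOR = 1e-3


@dataclass
class EmbeddedSpace:
    """Low-dimensional coordinates for all frames of the concatenation."""

    dim: int
    points: np.ndarray
    final_stress: float
    ensemble_offsets: np.ndarray | None = None


@dataclass
class DensityModel:
    """Gaussian-kernel density over one ensemble's embedded points."""

    support_points: np.ndarray
    bandwidth: np.ndarray  # per-dimension

    def evaluate(self, x: np.ndarray) -> np.ndarray:
        """Density at query points ``x`` (m, dim), blocked for memory."""
        x = np.atleast_2d(np.asarray(x, dtype=np.float64))
        sup = self.support_points
        h = self.bandwidth
        norm = sup.shape[0] * np.prod(h * np.sqrt(2.0 * np.pi))
        out = np.empty(x.shape[0])
        block = max(1, int(2_000_000 // max(sup.shape[0], 1)))
        for s in range(0, x.shape[0], block):
            z = (x[s : s + block, None, :] - sup[None, :, :]) / h
            out[s : s + block] = np.exp(-0.5 * (z * z).sum(axis=2)).sum(axis=1) / norm
        return out


@njit(cache=True, fastmath=False)
def _spe_updates(points, values, n, pairs_i, pairs_j, rates, cutoff):
    """Sequential SPE pair updates; ``rates`` holds one learning rate per update."""
    dim = points.shape[1]
    eps = 1e-10
    for t in range(pairs_i.shape[0]):
        i = pairs_i[t]
        j = pairs_j[t]
        lo = i if i < j else j
        hi = j if i < j else i
        d_target = values[lo * n - lo * (lo + 1) // 2 + (hi - lo - 1)]
        d2 = 0.0
        for c in range(dim):
            diff = points[i, c] - points[j, c]
            d2 += diff * diff
        d_embed = np.sqrt(d2)
        if d_target <= cutoff or d_embed < d_target:
            coef = rates[t] * 0.5 * (d_target - d_embed) / (d_embed + eps)
            for c in range(dim):
                diff = points[i, c] - points[j, c]
                points[i, c] += coef * diff
                points[j, c] -= coef * diff


@njit(cache=True, fastmath=False)
def _spe_stress(points, values, n, cutoff):
    """Stress S = [sum_in_scope (d_e - d_t)^2 / d_t] / sum_in_scope d_t."""
    dim = points.shape[1]
    num = 0.0
    den = 0.0
    k = 0
    for i in range(n - 1):
        for j in range(i + 1, n):
            d_target = values[k]
            k += 1
            d2 = 0.0
            for c in range(dim):
                diff = points[i, c] - points[j, c]
                d2 += diff * diff
            d_embed = np.sqrt(d2)
            # zero-target pairs carry no weight in the relative stress
            if d_target > 0.0 and (d_target <= cutoff or d_embed < d_target):
                num += (d_embed - d_target) ** 2 / d_target
                den += d_target
    if den == 0.0:
        return 0.0
    return num / den


def spe_embed(
    matrix: CondensedDistanceMatrix,
    dim: int = DEFAULT_DIM,
    n_cycles: int = DEFAULT_CYCLES,
    neighborhood_cutoff: float | None = None,
    learning_rate_initial: float = DEFAULT_LEARNING_RATE_INITIAL,
    learning_rate_final: float = DEFAULT_LEARNING_RATE_FINAL,
    seed: int = 0,
) -> EmbeddedSpace:
    """Stochastic proximity embedding of the distance matrix into ``dim`` D.

    The number of pair updates per cycle is linear in the point count
    (10n); the learning rate anneals linearly from initial to final and
    the result is deterministic given ``seed``. The default cutoff is
    1.5x the median pairwise distance.
    """
    if dim < 1 or n_cycles < 1:
        raise DataError("dim and n_cycles must be >= 1")
    if learning_rate_final > learning_rate_initial:
        raise DataError("learning rates must anneal downward")
    n = matrix.n
    rng = np.random.default_rng(seed)
    if n == 1:
        return EmbeddedSpace(dim, np.zeros((1, dim)), 0.0, matrix.ensemble_offsets)
    max_d = float(matrix.values.max())
    if max_d == 0.0:
        warnings.warn(
            "all pairwise distances are zero; all points embedded at one location",
            stacklevel=2,
        )
        return EmbeddedSpace(dim, np.zeros((n, dim)), 0.0, matrix.ensemble_offsets)
    if neighborhood_cutoff is None:
        neighborhood_cutoff = DEFAULT_CUTOFF_FACTOR * float(np.median(matrix.values))
    if neighborhood_cutoff <= 0:
        raise DataError("neighborhood_cutoff must be positive")

    per_cycle = UPDATES_PER_CYCLE_FACTOR * n
    total = n_cycles * per_cycle
    pairs_i = rng.integers(0, n, total)
    pairs_j = (pairs_i + rng.integers(1, n, total)) % n  # uniform over j != i
    if n_cycles == 1:
        per_cycle_rates = np.array([learning_rate_initial])
    else:
        per_cycle_rates = np.linspace(
            learning_rate_initial, learning_rate_final, n_cycles
        )
    rates = np.repeat(per_cycle_rates, per_cycle)
    points = rng.uniform(0.0, max_d, size=(n, dim))
    _spe_updates(
        points, matrix.values, n,
        pairs_i.astype(np.int64), pairs_j.astype(np.int64),
        rates, float(neighborhood_cutoff),
    )
    stress = float(_spe_stress(points, matrix.values, n, float(neighborhood_cutoff)))
    logger.info("SPE: %d points -> %dD, final stress %.4g", n, dim, stress)
    return EmbeddedSpace(dim, points, stress, matrix.ensemble_offsets)


def silverman_bandwidth(points: np.ndarray) -> np.ndarray:
    """Per-dimension Silverman rule: h_k = sd_k (4 / ((d+2) n))^(1/(d+4))."""
    n, d = points.shape
    sd = points.std(axis=0, ddof=1)
    factor = (4.0 / ((d + 2.0) * n)) ** (1.0 / (d + 4.0))
    h = sd * factor
    if np.any(h < BANDWIDTH_FLOOR):
        warnings.warn(
            "zero-variance embedding dimension; bandwidth floored at "
            f"{BANDWIDTH_FLOOR}",
            stacklevel=2,
        )
        h = np.maximum(h, BANDWIDTH_FLOOR)
    return h


def fit_kde(
    space: EmbeddedSpace, offsets, ensemble_index: int
) -> DensityModel:
    """Gaussian KDE over one ensemble's slice of the embedded points."""
    offsets = np.asarray(offsets, dtype=np.int64)
    a, b = offsets[ensemble_index], offsets[ensemble_index + 1]
    pts = space.points[a:b]
    if pts.shape[0] < 2:
        raise InsufficientDataError(
            "kernel density estimation needs at least 2 points"
        )
    return DensityModel(support_points=pts, bandwidth=silverman_bandwidth(pts))


def js_divergence_kde(da: DensityModel, db: DensityModel) -> float:
    """Resubstitution Monte-Carlo JS divergence of two densities, in [0, ln 2].

    D = 1/2 <ln(p_a/p_m)>_{a points} + 1/2 <ln(p_b/p_m)>_{b points},
    p_m = (p_a + p_b)/2, densities floored at 1e-300 before logs.
    """
    pa_a = np.maximum(da.evaluate(da.support_points), DENSITY_FLOOR)
    pb_a = np.maximum(db.evaluate(da.support_points), DENSITY_FLOOR)
    pa_b = np.maximum(da.evaluate(db.support_points), DENSITY_FLOOR)
    pb_b = np.maximum(db.evaluate(db.support_points), DENSITY_FLOOR)
    pm_a = 0.5 * (pa_a + pb_a)
    pm_b = 0.5 * (pa_b + pb_b)
    val = 0.5 * float(np.mean(np.log(pa_a / pm_a)))
    val += 0.5 * float(np.mean(np.log(pb_b / pm_b)))
    return min(max(val, 0.0), LN2)


def dres_divergence(
    ensembles: Sequence[Ensemble],
    matrix: CondensedDistanceMatrix | None = None,
    dim: int = DEFAULT_DIM,
    n_cycles: int = DEFAULT_CYCLES,
    neighborhood_cutoff: float | None = None,
    learning_rate_initial: float = DEFAULT_LEARNING_RATE_INITIAL,
    learning_rate_final: float = DEFAULT_LEARNING_RATE_FINAL,
    seed: int = 0,
    n_workers: int = 1,
):
    """Full DRES pipeline; returns ``(k x k divergences, EmbeddedSpace)``."""
    if len(ensembles) < 2:
        raise InputError("DRES needs at least two ensembles")
    if matrix is None:
        matrix = rmsd_matrix(ensembles, n_workers=n_workers)
    space = spe_embed(
        matrix,
        dim=dim,
        n_cycles=n_cycles,
        neighborhood_cutoff=neighborhood_cutoff,
        learning_rate_initial=learning_rate_initial,
        learning_rate_final=learning_rate_final,
        seed=seed,
    )
    offsets = matrix.ensemble_offsets
    k = len(offsets) - 1
    models = [fit_kde(space, offsets, e) for e in range(k)]
    div = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            div[i, j] = div[j, i] = js_divergence_kde(models[i], models[j])
    return div, space
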