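"""Clustering ensemble similarity (CES).

All frames of all ensembles are clustered together with affinity
propagation on similarities s(i,k) = -RMSD(i,k) (self-similarity =
"preference"), each ensemble is summarized by the fraction of its frames
in each cluster, and ensemble pairs are scored with the discrete
Jensen-Shannon divergence of those population vectors (natural log,
bounded by ln 2).

The message-passing loop follows the standard responsibility/availability
updates with damping; a fixed infinitesimal seed-controlled jitter on the
similarities breaks exact ties, making the partition deterministic given
(matrix, parameters, seed).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from numba import njit

from .distance_matrix import CondensedDistanceMatrix, rmsd_matrix
from .ensemble_io import Ensemble
from .exceptions import DataError, InputError, ShapeError

__all__ = [
    "ClusterPartition",
    "affinity_propagation",
    "ensemble_cluster_populations",
    "js_divergence_discrete",
    "ces_divergence",
]

logger = logging.getLogger(__name__)

LN2 = float(np.log(2.0))

DEFAULT_DAMPING = 0.9
DEFAULT_MAX_ITER = 500
DEFAULT_CONVERGENCE_ITER = 50


@dataclass
class ClusterPartition:
    """Exemplar-based partition of the frame concatenation."""

    labels: np.ndarray
    exemplars: np.ndarray
    n_clusters: int
    converged: bool
    iterations_run: int

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        self.exemplars = np.asarray(self.exemplars, dtype=np.int64)


@njit(cache=True, fastmath=False)
def _ap_messages(s, damping, max_iter, convergence_iter):
    """Responsibility/availability passing; returns (R+A diag>0 mask source).

    Runs until the exemplar set is unchanged for ``convergence_iter``
    consecutive iterations or ``max_iter`` is reached.
    """
    n = s.shape[0]
    r = np.zeros((n, n))
    a = np.zeros((n, n))
    exemplar = np.zeros(n, dtype=np.bool_)
    stable = 0
    it = 0
    converged = False
    for it in range(max_iter):
        # responsibilities: r(i,k) <- s(i,k) - max_{k'!=k} (a(i,k') + s(i,k'))
        for i in range(n):
            m1 = -1e300
            m2 = -1e300
            k1 = -1
            for k in range(n):
                v = a[i, k] + s[i, k]
                if v > m1:
                    m2 = m1
                    m1 = v
                    k1 = k
                elif v > m2:
                    m2 = v
            for k in range(n):
                sub = m2 if k == k1 else m1
                r[i, k] = damping * r[i, k] + (1.0 - damping) * (s[i, k] - sub)
        # availabilities: a(i,k) <- min(0, r(k,k) + sum_{i' not in {i,k}} r+(i',k))
        for k in range(n):
            tot = 0.0
            for i in range(n):
                if i != k and r[i, k] > 0.0:
                    tot += r[i, k]
            for i in range(n):
                if i == k:
                    new = tot
                else:
                    rp = r[i, k] if r[i, k] > 0.0 else 0.0
                    new = r[k, k] + tot - rp
                    if new > 0.0:
                        new = 0.0
                a[i, k] = damping * a[i, k] + (1.0 - damping) * new
        # exemplar set stability
        changed = False
        count = 0
        for k in range(n):
            e = (a[k, k] + r[k, k]) > 0.0
            if e != exemplar[k]:
                exemplar[k] = e
                changed = True
            if e:
                count += 1
        if changed or count == 0:
            stable = 0
        else:
            stable += 1
            if stable >= convergence_iter:
                converged = True
                break
    diag = np.empty(n)
    for k in range(n):
        diag[k] = a[k, k] + r[k, k]
    return diag, it + 1, converged


def _finalize_partition(s: np.ndarray, diag: np.ndarray):
    """Assign points to exemplars and refine exemplars within clusters."""
    n = s.shape[0]
    exemplars = np.flatnonzero(diag > 0)
    if exemplars.size == 0:
        exemplars = np.array([int(np.argmax(diag))])
    labels = np.argmax(s[:, exemplars], axis=1)
    labels[exemplars] = np.arange(exemplars.size)
    # refinement pass: within each cluster re-elect the member with the
    # largest summed similarity, then reassign (as in the reference scheme)
    new_exemplars = np.empty_like(exemplars)
    for c in range(exemplars.size):
        members = np.flatnonzero(labels == c)
        sub = s[np.ix_(members, members)]
        new_exemplars[c] = members[int(np.argmax(sub.sum(axis=0)))]
    new_exemplars = np.unique(new_exemplars)  # sorted; ties -> lowest index
    labels = np.argmax(s[:, new_exemplars], axis=1)
    labels[new_exemplars] = np.arange(new_exemplars.size)
    return labels.astype(np.int64), new_exemplars.astype(np.int64)


def affinity_propagation(
    matrix: CondensedDistanceMatrix,
    preference: float | str = "median",
    damping: float = DEFAULT_DAMPING,
    max_iter: int = DEFAULT_MAX_ITER,
    convergence_iter: int = DEFAULT_CONVERGENCE_ITER,
    seed: int = 0,
) -> ClusterPartition:
    """Cluster all frames by affinity propagation on s(i,k) = -RMSD(i,k).

    ``preference`` is the self-similarity controlling the cluster count;
    ``"median"`` uses the median of the off-diagonal similarities.
    Non-convergence returns the final partition with ``converged=False``
    and a warning, never an exception.
    """
    if not 0.5 <= damping < 1.0:
        raise DataError(f"damping must be in [0.5, 1), got {damping}")
    if max_iter < convergence_iter or convergence_iter < 1:
        raise DataError("require max_iter >= convergence_iter >= 1")
    n = matrix.n
    if n == 1:
        return ClusterPartition(
            labels=np.zeros(1), exemplars=np.zeros(1), n_clusters=1,
            converged=True, iterations_run=0,
        )
    if matrix.values.max() == 0.0:
        warnings.warn(
            "all pairwise distances are zero; returning a single cluster",
            stacklevel=2,
        )
        return ClusterPartition(
            labels=np.zeros(n), exemplars=np.zeros(1), n_clusters=1,
            converged=True, iterations_run=0,
        )
    s = -matrix.as_square()
    pref = float(np.median(-matrix.values)) if preference == "median" else float(preference)
    np.fill_diagonal(s, pref)
    # fixed infinitesimal jitter: breaks exact message ties deterministically
    rng = np.random.default_rng(seed)
    scale = float(np.abs(s).max())
    s = s + scale * 1e-13 * rng.standard_normal((n, n))
    diag, iterations, converged = _ap_messages(
        s, float(damping), int(max_iter), int(convergence_iter)
    )
    if not converged:
        warnings.warn(
            f"affinity propagation did not converge within {max_iter} "
            "iterations; using the final partition",
            stacklevel=2,
        )
    labels, exemplars = _finalize_partition(s, diag)
    return ClusterPartition(
        labels=labels,
        exemplars=exemplars,
        n_clusters=exemplars.size,
        converged=bool(converged),
        iterations_run=int(iterations),
    )


def ensemble_cluster_populations(
    partition: ClusterPartition, offsets
) -> list[np.ndarray]:
    """Per-ensemble cluster population vectors over a joint partition."""
    offsets = np.asarray(offsets, dtype=np.int64)
    if offsets[-1] != partition.labels.size:
        raise InputError(
            f"offsets end at {offsets[-1]} but partition has "
            f"{partition.labels.size} frames"
        )
    vectors = []
    for a, b in zip(offsets[:-1], offsets[1:]):
        if b <= a:
            raise InputError("empty ensemble slice")
        counts = np.bincount(
            partition.labels[a:b], minlength=partition.n_clusters
        ).astype(np.float64)
        vectors.append(counts / counts.sum())
    return vectors


def js_divergence_discrete(p, q) -> float:
    """Jensen-Shannon divergence of two discrete distributions, in nats.

    D_JS = 1/2 sum p_i ln(p_i/m_i) + 1/2 sum q_i ln(q_i/m_i), m = (p+q)/2,
    with 0 ln(0/x) = 0. Symmetric, in [0, ln 2].
    """
    p = np.asarray(p, dtype=np.float64)
    q = np.asarray(q, dtype=np.float64)
    if p.shape != q.shape:
        raise ShapeError(f"length mismatch: {p.shape} vs {q.shape}")
    if (p < 0).any() or (q < 0).any():
        raise DataError("population vectors must be non-negative")
    if abs(p.sum() - 1.0) > 1e-6 or abs(q.sum() - 1.0) > 1e-6:
        raise DataError("population vectors must each sum to 1")
    m = 0.5 * (p + q)
    mask_p = p > 0
    mask_q = q > 0
    val = 0.5 * float(np.sum(p[mask_p] * np.log(p[mask_p] / m[mask_p])))
    val += 0.5 * float(np.sum(q[mask_q] * np.log(q[mask_q] / m[mask_q])))
    return min(max(val, 0.0), LN2)


def ces_divergence(
    ensembles: Sequence[Ensemble],
    matrix: CondensedDistanceMatrix | None = None,
    preference: float | str = "median",
    damping: float = DEFAULT_DAMPING,
    max_iter: int = DEFAULT_MAX_ITER,
    convergence_iter: int = DEFAULT_CONVERGENCE_ITER,
    seed: int = 0,
    n_workers: int = 1,
):
    """Full CES pipeline; returns ``(k x k divergences, ClusterPartition)``."""
    if len(ensembles) < 2:
        raise InputError("CES needs at least two ensembles")
    if matrix is None:
        matrix = rmsd_matrix(ensembles, n_workers=n_workers)
    partition = affinity_propagation(
        matrix,
        preference=preference,
        damping=damping,
        max_iter=max_iter,
        convergence_iter=convergence_iter,
        seed=seed,
    )
    logger.info(
        "CES: %d frames -> %d clusters (converged=%s, %d iterations)",
        matrix.n, partition.n_clusters, partition.converged,
        partition.iterations_run,
    )
    populations = ensemble_cluster_populations(partition, matrix.ensemble_offsets)
    k = len(populations)
    div = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            div[i, j] = div[j, i] = js_divergence_discrete(
                populations[i], populations[j]
            )
    return div, partition
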