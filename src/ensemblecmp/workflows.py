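"""Orchestration: all-vs-all comparison, bootstrap, convergence, sparsification.

These operations compose the three similarity estimators. The pairwise
RMSD matrix over the concatenation is computed once and reused wherever
possible: bootstrap replicates, prefix windows and sparsified subensembles
are all index subsets (possibly with repetition) of already-computed
frames, so their matrices are gathered from the cached one and only the
clustering/embedding stage is recomputed, which keeps the procedures
faithful (re-clustering per replicate) without redundant RMSD work.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from . import ces as _ces
from . import dres as _dres
from . import hes as _hes
from .distance_matrix import CondensedDistanceMatrix, rmsd_matrix
from .ensemble_io import Ensemble, superpose_ensemble
from .exceptions import InputError, TopologyError

__all__ = [
    "SimilarityMatrix",
    "BootstrapReport",
    "ConvergenceProfile",
    "SparsificationCurve",
    "compare_all",
    "bootstrap_uncertainty",
    "convergence_profile",
    "sparsify_ensemble",
    "sparsification_curve",
    "project_similarity_2d",
]

logger = logging.getLogger(__name__)

METHODS = ("hes", "ces", "dres")


@dataclass
class SimilarityMatrix:
    """Symmetric k x k table of pairwise ensemble divergences (nats)."""

    method: str
    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "labels": list(self.labels),
            "values": [[round(v, 4) for v in row] for row in self.values],
        }


@dataclass
class BootstrapReport:
    """Divergence uncertainty over frame-resampling replicates."""

    point_estimate: float
    replicates: np.ndarray
    mean: float
    std: float
    n_replicates: int


@dataclass
class ConvergenceProfile:
    """Divergence of time-ordered prefixes against the full ensemble."""

    window_lengths: np.ndarray
    divergences: np.ndarray


@dataclass
class SparsificationCurve:
    """Divergence of uniformly decimated subensembles against the full one."""

    keep_every: np.ndarray
    n_frames: np.ndarray
    divergences: np.ndarray


def _check_method(method: str) -> str:
    method = method.lower()
    if method not in METHODS:
        raise InputError(f"unknown method {method!r}; choose from {METHODS}")
    return method


def _canonical_orientation(ref: np.ndarray) -> np.ndarray:
    """Rotate a reference structure into its principal-axes frame.

    Centered at the origin, axes ordered by decreasing gyration eigenvalue
    with a deterministic sign convention (the largest projection along each
    of the first two axes is positive; the third completes a right-handed
    frame). Removes the arbitrary global orientation so that scores built
    on the superposed coordinates do not depend on how the input happened
    to be oriented — the diagonal shrinkage target of the Gaussian fit is
    basis-dependent, so this matters beyond cosmetics.
    """
    centered = ref - ref.mean(axis=0)
    _, evecs = np.linalg.eigh(centered.T @ centered)
    axes = evecs[:, ::-1].copy()
    for k in range(2):
        proj = centered @ axes[:, k]
        if proj[np.argmax(np.abs(proj))] < 0:
            axes[:, k] = -axes[:, k]
    axes[:, 2] = np.cross(axes[:, 0], axes[:, 1])
    return centered @ axes


def _hes_models(ensembles: Sequence[Ensemble]):
    """Superpose all ensembles to one shared reference and fit Gaussians.

    The reference is the iteratively-aligned mean of the pooled frames of
    all ensembles, in canonical orientation: pooling makes the score
    independent of the input order, and divergences are meaningless across
    inconsistent frames of reference.
    """
    pooled = Ensemble(
        "pooled", np.concatenate([ens.coords for ens in ensembles], axis=0)
    )
    aligned = superpose_ensemble(pooled, "average")
    reference = _canonical_orientation(aligned.coords.mean(axis=0))
    superposed = [superpose_ensemble(ens, reference) for ens in ensembles]
    return [_hes.fit_gaussian_model(ens) for ens in superposed]


def compare_all(
    ensembles: Sequence[Ensemble],
    method: str = "ces",
    matrix: CondensedDistanceMatrix | None = None,
    n_workers: int = 1,
    seed: int = 0,
    **params,
) -> SimilarityMatrix:
    """All-vs-all divergence table for >= 2 ensembles.

    CES/DRES compute (or reuse) one RMSD matrix over the concatenation;
    HES bypasses the matrix and fits per-ensemble Gaussian models.
    """
    method = _check_method(method)
    if len(ensembles) < 2:
        raise InputError("need at least two ensembles to compare")
    n_atoms = ensembles[0].n_atoms
    if any(e.n_atoms != n_atoms for e in ensembles):
        raise TopologyError("ensembles have mixed atom counts")
    labels = [e.label for e in ensembles]
    logger.info(
        "compare_all: method=%s seed=%d frames=%s matrix=%s params=%s",
        method, seed, [e.n_frames for e in ensembles],
        "cached" if matrix is not None else "fresh", params,
    )
    if method == "hes":
        models = _hes_models(ensembles)
        k = len(models)
        values = np.zeros((k, k))
        for i in range(k):
            for j in range(i + 1, k):
                values[i, j] = values[j, i] = _hes.hes_divergence(
                    models[i], models[j]
                )
    elif method == "ces":
        values, _ = _ces.ces_divergence(
            ensembles, matrix=matrix, seed=seed, n_workers=n_workers, **params
        )
    else:
        values, _ = _dres.dres_divergence(
            ensembles, matrix=matrix, seed=seed, n_workers=n_workers, **params
        )
    return SimilarityMatrix(method=method, labels=labels, values=values)


def _pair_divergence_from_submatrix(
    method: str, sub: CondensedDistanceMatrix, seed: int, params: dict
) -> float:
    if method == "ces":
        partition = _ces.affinity_propagation(sub, seed=seed, **params)
        pops = _ces.ensemble_cluster_populations(partition, sub.ensemble_offsets)
        return _ces.js_divergence_discrete(pops[0], pops[1])
    space = _dres.spe_embed(sub, seed=seed, **params)
    da = _dres.fit_kde(space, sub.ensemble_offsets, 0)
    db = _dres.fit_kde(space, sub.ensemble_offsets, 1)
    return _dres.js_divergence_kde(da, db)


def _hes_pair(ens_a: Ensemble, ens_b: Ensemble) -> float:
    models = _hes_models([ens_a, ens_b])
    return _hes.hes_divergence(models[0], models[1])


def bootstrap_uncertainty(
    ens_a: Ensemble,
    ens_b: Ensemble,
    method: str = "ces",
    n_replicates: int = 100,
    seed: int = 0,
    n_workers: int = 1,
    matrix: CondensedDistanceMatrix | None = None,
    **params,
) -> BootstrapReport:
    """Bootstrap the divergence of one ensemble pair.

    Each replicate independently resamples the frames of BOTH ensembles
    with replacement to their original sizes and recomputes the divergence
    end-to-end (re-clustering / re-embedding / re-fitting); the report's
    ``std`` is the sample standard deviation over replicates.
    """
    method = _check_method(method)
    if n_replicates < 2:
        raise InputError("n_replicates must be >= 2")
    na, nb = ens_a.n_frames, ens_b.n_frames
    rng = np.random.default_rng(seed)
    if method in ("ces", "dres"):
        if matrix is None:
            matrix = rmsd_matrix([ens_a, ens_b], n_workers=n_workers)
        point = _pair_divergence_from_submatrix(
            method,
            matrix.gather(np.arange(na + nb), [0, na, na + nb]),
            seed=int(rng.integers(2**31)),
            params=params,
        )
    else:
        point = _hes_pair(ens_a, ens_b)
    replicates = np.empty(n_replicates)
    for r in range(n_replicates):
        idx_a = rng.integers(0, na, na)
        idx_b = rng.integers(0, nb, nb)
        rep_seed = int(rng.integers(2**31))
        if method == "hes":
            replicates[r] = _hes_pair(ens_a.subset(idx_a), ens_b.subset(idx_b))
        else:
            sub = matrix.gather(
                np.concatenate([idx_a, idx_b + na]), [0, na, na + nb]
            )
            replicates[r] = _pair_divergence_from_submatrix(
                method, sub, seed=rep_seed, params=params
            )
    logger.info(
        "bootstrap: method=%s n_replicates=%d mean=%.4f std=%.4f",
        method, n_replicates, replicates.mean(), replicates.std(ddof=1),
    )
    return BootstrapReport(
        point_estimate=float(point),
        replicates=replicates,
        mean=float(replicates.mean()),
        std=float(replicates.std(ddof=1)),
        n_replicates=n_replicates,
    )


def convergence_profile(
    ens: Ensemble,
    window_lengths=None,
    method: str = "ces",
    seed: int = 0,
    n_workers: int = 1,
    **params,
) -> ConvergenceProfile:
    """Divergence of time-ordered prefix windows against the full ensemble.

    Windows are prefixes [0, w); the default is 10 evenly spaced lengths
    ending at the full length. The full-length entry is 0 by construction
    (the prefix is the full ensemble).
    """
    method = _check_method(method)
    n = ens.n_frames
    if window_lengths is None:
        window_lengths = np.unique(
            np.linspace(n / 10.0, n, 10).round().astype(np.int64)
        )
    windows = np.asarray(window_lengths, dtype=np.int64)
    if windows.size == 0 or windows[0] < 1:
        raise InputError("windows must be non-empty prefixes")
    if np.any(np.diff(windows) <= 0) or windows[-1] > n:
        raise InputError("windows must increase strictly and fit the ensemble")
    rng = np.random.default_rng(seed)
    matrix = None
    if method in ("ces", "dres"):
        matrix = rmsd_matrix([ens], n_workers=n_workers)
    divergences = np.empty(windows.size)
    for w_idx, w in enumerate(windows):
        if w == n:
            divergences[w_idx] = 0.0
            continue
        rep_seed = int(rng.integers(2**31))
        if method == "hes":
            divergences[w_idx] = _hes_pair(ens.subset(np.arange(w)), ens)
        else:
            sub = matrix.gather(
                np.concatenate([np.arange(w), np.arange(n)]), [0, w, w + n]
            )
            divergences[w_idx] = _pair_divergence_from_submatrix(
                method, sub, seed=rep_seed, params=params
            )
    return ConvergenceProfile(window_lengths=windows, divergences=divergences)


def sparsify_ensemble(ens: Ensemble, keep_every: int) -> Ensemble:
    """Uniform decimation: keep every ``keep_every``-th frame, order preserved."""
    if keep_every < 1:
        raise InputError("keep_every must be >= 1")
    idx = np.arange(0, ens.n_frames, keep_every)
    if idx.size < 2:
        raise InputError(
            f"keep_every={keep_every} leaves {idx.size} frame(s); need >= 2"
        )
    return ens.subset(idx, label=f"{ens.label}/every{keep_every}")


def sparsification_curve(
    ens: Ensemble,
    method: str = "ces",
    keep_every=(2, 4, 8, 16),
    seed: int = 0,
    n_workers: int = 1,
    **params,
) -> SparsificationCurve:
    """Divergence of each decimated subensemble against the full ensemble."""
    method = _check_method(method)
    factors = np.asarray(keep_every, dtype=np.int64)
    n = ens.n_frames
    rng = np.random.default_rng(seed)
    matrix = None
    if method in ("ces", "dres"):
        matrix = rmsd_matrix([ens], n_workers=n_workers)
    divergences = np.empty(factors.size)
    n_frames = np.empty(factors.size, dtype=np.int64)
    for f_idx, factor in enumerate(factors):
        sub_idx = np.arange(0, n, factor)
        if sub_idx.size < 2:
            raise InputError(f"keep_every={factor} leaves < 2 frames")
        n_frames[f_idx] = sub_idx.size
        rep_seed = int(rng.integers(2**31))
        if method == "hes":
            divergences[f_idx] = _hes_pair(ens.subset(sub_idx), ens)
        else:
            sub = matrix.gather(
                np.concatenate([sub_idx, np.arange(n)]),
                [0, sub_idx.size, sub_idx.size + n],
            )
            divergences[f_idx] = _pair_divergence_from_submatrix(
                method, sub, seed=rep_seed, params=params
            )
    return SparsificationCurve(
        keep_every=factors, n_frames=n_frames, divergences=divergences
    )


# ---------------------------------------------------------------------------
# 2D projection of a similarity matrix (classical MDS + stress majorization)
# ---------------------------------------------------------------------------

def _stress(coords: np.ndarray, d: np.ndarray) -> float:
    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.sqrt((diff * diff).sum(axis=2))
    iu = np.triu_indices(d.shape[0], 1)
    return float(((dist[iu] - d[iu]) ** 2).sum())


def _smacof(d: np.ndarray, coords: np.ndarray, n_iter: int = 300) -> np.ndarray:
    k = d.shape[0]
    for _ in range(n_iter):
        diff = coords[:, None, :] - coords[None, :, :]
        dist = np.sqrt((diff * diff).sum(axis=2))
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(dist > 0, d / np.where(dist > 0, dist, 1.0), 0.0)
        b = -ratio
        np.fill_diagonal(b, 0.0)
        np.fill_diagonal(b, -b.sum(axis=1))
        new = (b @ coords) / k
        if np.abs(new - coords).max() < 1e-12:
            coords = new
            break
        coords = new
    return coords


def project_similarity_2d(sm: SimilarityMatrix, seed: int = 0) -> np.ndarray:
    """Project a divergence matrix to 2D coordinates (centered at origin).

    Classical metric scaling seeds a stress-majorization refinement; a few
    random restarts guard against poor local minima. Axes carry no physical
    meaning beyond their scale, and the layout is defined only up to
    rotation, translation and inversion.
    """
    d = np.asarray(sm.values, dtype=np.float64)
    k = d.shape[0]
    if k < 2 or d.shape != (k, k):
        raise InputError("need a square similarity matrix with k >= 2")
    # classical MDS on the double-centered squared distances
    j = np.eye(k) - np.ones((k, k)) / k
    b = -0.5 * j @ (d * d) @ j
    evals, evecs = np.linalg.eigh(b)
    order = np.argsort(evals)[::-1][:2]
    init = evecs[:, order] * np.sqrt(np.maximum(evals[order], 0.0))
    if init.shape[1] < 2:  # pragma: no cover
        init = np.pad(init, ((0, 0), (0, 2 - init.shape[1])))
    rng = np.random.default_rng(seed)
    candidates = [init] + [
        rng.uniform(-d.max() or 1.0, d.max() or 1.0, size=(k, 2)) for _ in range(2)
    ]
    best, best_stress = None, np.inf
    for cand in candidates:
        refined = _smacof(d, cand.copy())
        s = _stress(refined, d)
        if s < best_stress:
            best, best_stress = refined, s
    return best - best.mean(axis=0)
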