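"""All-vs-all pairwise RMSD matrix over the concatenation of ensembles.

The matrix is stored condensed (upper triangle, row-major) because frame
counts reach tens of thousands. Each entry is the minimum RMSD over rigid
superpositions of a frame pair, computed with a quaternion characteristic
polynomial kernel (Theobald-style: the optimal Kabsch score equals the
largest eigenvalue of a 4x4 key matrix, found by Newton iteration from
above). The kernel is numba-compiled and the row range can be farmed out
to worker processes; entries are computed independently of the work
partition, so results are bit-identical for any worker count.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from numba import njit

from .ensemble_io import Ensemble
from .exceptions import DataError, FormatError, ShapeError, TopologyError

__all__ = [
    "CondensedDistanceMatrix",
    "pairwise_rmsd",
    "rmsd_matrix",
    "save_matrix",
    "load_matrix",
]

MATRIX_FORMAT_TAG = "ensemblecmp-rmsd-matrix-v1"


@dataclass
class CondensedDistanceMatrix:
    """Upper-triangular pairwise RMSD store (Å) with ensemble boundaries.

    ``values[k]`` holds the distance between frames ``i < j`` of the
    concatenation at ``k = i*n - i*(i+1)/2 + (j - i - 1)``.
    ``ensemble_offsets`` marks where each ensemble starts; it begins at 0
    and its last boundary equals ``n``.
    """

    n: int
    values: np.ndarray
    ensemble_offsets: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.ascontiguousarray(self.values, dtype=np.float64)
        if self.values.shape != (self.n * (self.n - 1) // 2,):
            raise ShapeError(
                f"condensed matrix for n={self.n} needs "
                f"{self.n * (self.n - 1) // 2} values, got {self.values.shape}"
            )
        if self.values.size and (
            not np.isfinite(self.values).all() or self.values.min() < 0
        ):
            raise DataError("distances must be finite and non-negative")
        if self.ensemble_offsets is None:
            self.ensemble_offsets = np.array([0, self.n], dtype=np.int64)
        self.ensemble_offsets = np.asarray(self.ensemble_offsets, dtype=np.int64)
        off = self.ensemble_offsets
        if off[0] != 0 or off[-1] != self.n or np.any(np.diff(off) <= 0):
            raise DataError(
                f"ensemble_offsets {off.tolist()} must increase strictly "
                f"from 0 to n={self.n}"
            )

    @property
    def n_ensembles(self) -> int:
        return len(self.ensemble_offsets) - 1

    def condensed_index(self, i: int, j: int) -> int:
        if i == j:
            raise ShapeError("diagonal entries are implicitly zero")
        lo, hi = (i, j) if i < j else (j, i)
        return lo * self.n - lo * (lo + 1) // 2 + (hi - lo - 1)

    def entry(self, i: int, j: int) -> float:
        if i == j:
            return 0.0
        return float(self.values[self.condensed_index(i, j)])

    def as_square(self) -> np.ndarray:
        from scipy.spatial.distance import squareform

        if self.n == 1:
            return np.zeros((1, 1))
        return squareform(self.values)

    def gather(self, indices, ensemble_offsets) -> "CondensedDistanceMatrix":
        """Condensed matrix over a re-indexed (possibly repeated) frame list.

        Repeated indices get distance 0 between their copies, so bootstrap
        resamples and window/sparsification comparisons reuse the matrix
        without recomputing any RMSD.
        """
        idx = np.asarray(indices, dtype=np.int64)
        m = len(idx)
        out = np.empty(m * (m - 1) // 2, dtype=np.float64)
        pos = 0
        n = self.n
        for p in range(m - 1):
            a = idx[p]
            b = idx[p + 1 :]
            lo = np.minimum(a, b)
            hi = np.maximum(a, b)
            k = lo * n - lo * (lo + 1) // 2 + (hi - lo - 1)
            row = np.where(a == b, 0.0, self.values[np.where(a == b, 0, k)])
            out[pos : pos + m - 1 - p] = row
            pos += m - 1 - p
        return CondensedDistanceMatrix(
            n=m, values=out, ensemble_offsets=np.asarray(ensemble_offsets)
        )


# ---------------------------------------------------------------------------
# Quaternion characteristic polynomial RMSD kernel
# ---------------------------------------------------------------------------

@njit(cache=True, fastmath=False)
def _qcp_msd(ca, cb, ga, gb):
    """Minimum MSD between two centered frames with inner products ga, gb."""
    natoms = ca.shape[0]
    sxx = 0.0; sxy = 0.0; sxz = 0.0
    syx = 0.0; syy = 0.0; syz = 0.0
    szx = 0.0; szy = 0.0; szz = 0.0
    for a in range(natoms):
        x1 = ca[a, 0]; y1 = ca[a, 1]; z1 = ca[a, 2]
        x2 = cb[a, 0]; y2 = cb[a, 1]; z2 = cb[a, 2]
        sxx += x1 * x2; sxy += x1 * y2; sxz += x1 * z2
        syx += y1 * x2; syy += y1 * y2; syz += y1 * z2
        szx += z1 * x2; szy += z1 * y2; szz += z1 * z2

    k = np.empty((4, 4))
    k[0, 0] = sxx + syy + szz
    k[0, 1] = syz - szy
    k[0, 2] = szx - sxz
    k[0, 3] = sxy - syx
    k[1, 1] = sxx - syy - szz
    k[1, 2] = sxy + syx
    k[1, 3] = szx + sxz
    k[2, 2] = -sxx + syy - szz
    k[2, 3] = syz + szy
    k[3, 3] = -sxx - syy + szz
    for i in range(4):
        for j in range(i):
            k[i, j] = k[j, i]

    # characteristic polynomial l^4 + e2 l^2 - e3 l + e4 via power traces
    k2 = k @ k
    p2 = k2[0, 0] + k2[1, 1] + k2[2, 2] + k2[3, 3]
    p3 = 0.0
    p4 = 0.0
    for i in range(4):
        for j in range(4):
            p3 += k2[i, j] * k[i, j]
            p4 += k2[i, j] * k2[i, j]
    e2 = -0.5 * p2
    e3 = p3 / 3.0
    e4 = 0.25 * (0.5 * p2 * p2 - p4)

    # Newton from the upper bound (ga+gb)/2 down to the largest eigenvalue
    lam = 0.5 * (ga + gb)
    if lam <= 1e-18:
        return 0.0
    for _ in range(100):
        f = ((lam * lam + e2) * lam - e3) * lam + e4
        fp = (4.0 * lam * lam + 2.0 * e2) * lam - e3
        if fp == 0.0:
            break
        step = f / fp
        lam -= step
        if abs(step) < 1e-15 * max(1.0, abs(lam)):
            break
    msd = (ga + gb - 2.0 * lam) / natoms
    if msd < 0.0:
        msd = 0.0
    return msd


@njit(cache=True, fastmath=False)
def _rmsd_rows(centered, traces, r0, r1, out):
    """Fill condensed entries for rows [r0, r1) of the pair matrix."""
    n = centered.shape[0]
    pos = 0
    for i in range(r0, r1):
        for j in range(i + 1, n):
            out[pos] = np.sqrt(
                _qcp_msd(centered[i], centered[j], traces[i], traces[j])
            )
            pos += 1
    return out


def _center_frames(coords: np.ndarray):
    centered = coords - coords.mean(axis=1, keepdims=True)
    traces = np.einsum("fad,fad->f", centered, centered)
    return np.ascontiguousarray(centered), traces


def pairwise_rmsd(frame_a, frame_b) -> float:
    """Minimum RMSD (Å) between two single frames over rigid superpositions."""
    a = np.asarray(frame_a, dtype=np.float64)
    b = np.asarray(frame_b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise ShapeError(f"frame shapes {a.shape} vs {b.shape} must match (atoms, 3)")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise DataError("frames contain non-finite coordinates")
    centered, traces = _center_frames(np.stack([a, b]))
    out = np.empty(1, dtype=np.float64)
    _rmsd_rows(centered, traces, 0, 1, out)
    return float(out[0])


def _row_chunks(n: int, target_chunks: int = 64):
    """Split rows 0..n-2 into contiguous chunks of ~equal pair counts.

    The chunking depends only on n (never on the worker count) so the
    assembled result is identical however the chunks are scheduled.
    """
    total = n * (n - 1) // 2
    if total == 0:
        return []
    per_chunk = max(1, total // target_chunks)
    chunks = []
    r0 = 0
    acc = 0
    for i in range(n - 1):
        acc += n - 1 - i
        if acc >= per_chunk or i == n - 2:
            chunks.append((r0, i + 1))
            r0 = i + 1
            acc = 0
    return chunks


_WORKER_DATA: tuple | None = None


def _worker_init(centered, traces):
    global _WORKER_DATA
    _WORKER_DATA = (centered, traces)


def _worker_chunk(chunk):
    r0, r1 = chunk
    centered, traces = _WORKER_DATA
    n = centered.shape[0]
    count = sum(n - 1 - i for i in range(r0, r1))
    out = np.empty(count, dtype=np.float64)
    _rmsd_rows(centered, traces, r0, r1, out)
    return r0, out


def rmsd_matrix(
    ensembles: Sequence[Ensemble], n_workers: int = 1
) -> CondensedDistanceMatrix:
    """Pairwise RMSD between all frames of all ensembles, condensed.

    ``n_workers`` > 1 distributes row chunks over forked processes; the
    result is bit-identical for any worker count.
    """
    if n_workers < 1:
        raise DataError("n_workers must be >= 1")
    n_atoms = ensembles[0].n_atoms
    for ens in ensembles:
        if ens.n_atoms != n_atoms:
            raise TopologyError(
                f"ensemble {ens.label!r} has {ens.n_atoms} atoms, expected {n_atoms}"
            )
    coords = np.concatenate([ens.coords for ens in ensembles], axis=0)
    offsets = np.concatenate(
        [[0], np.cumsum([ens.n_frames for ens in ensembles])]
    ).astype(np.int64)
    n = coords.shape[0]
    centered, traces = _center_frames(coords)
    values = np.empty(n * (n - 1) // 2, dtype=np.float64)
    chunks = _row_chunks(n)

    def chunk_slice(r0, r1):
        start = r0 * n - r0 * (r0 + 1) // 2
        stop = r1 * n - r1 * (r1 + 1) // 2
        return start, stop

    if n_workers == 1 or len(chunks) <= 1:
        for r0, r1 in chunks:
            start, stop = chunk_slice(r0, r1)
            _rmsd_rows(centered, traces, r0, r1, values[start:stop])
    else:
        import multiprocessing as mp

        # warm the JIT cache in the parent so forked children inherit it
        warm = np.empty(1, dtype=np.float64)
        _rmsd_rows(centered[:2], traces[:2], 0, 1, warm)
        ctx = mp.get_context("fork")
        with ctx.Pool(
            n_workers, initializer=_worker_init, initargs=(centered, traces)
        ) as pool:
            for r0, out in pool.imap_unordered(_worker_chunk, chunks):
                r1 = r0 + 1
                for c0, c1 in chunks:
                    if c0 == r0:
                        r1 = c1
                        break
                start, stop = chunk_slice(r0, r1)
                values[start:stop] = out
    return CondensedDistanceMatrix(n=n, values=values, ensemble_offsets=offsets)


# ---------------------------------------------------------------------------
# Disk cache (HDF5)
# ---------------------------------------------------------------------------

def save_matrix(matrix: CondensedDistanceMatrix, path) -> None:
    """Write the matrix to an HDF5 container (lossless float64)."""
    import h5py

    with h5py.File(str(path), "w") as handle:
        handle.attrs["format"] = MATRIX_FORMAT_TAG
        handle.attrs["n"] = matrix.n
        handle.create_dataset("values", data=matrix.values)
        handle.create_dataset("ensemble_offsets", data=matrix.ensemble_offsets)


def load_matrix(path) -> CondensedDistanceMatrix:
    """Read a matrix written by :func:`save_matrix`; validates the header."""
    import h5py

    try:
        with h5py.File(str(path), "r") as handle:
            if handle.attrs.get("format") != MATRIX_FORMAT_TAG:
                raise FormatError(
                    f"{path} is not an ensemblecmp RMSD matrix file"
                )
            n = int(handle.attrs["n"])
            values = handle["values"][...]
            offsets = handle["ensemble_offsets"][...]
    except (OSError, KeyError) as exc:
        raise FormatError(f"cannot read matrix file {path}: {exc}") from exc
    if values.shape != (n * (n - 1) // 2,):
        raise FormatError(
            f"matrix file {path} is corrupted: header n={n} does not match "
            f"{values.shape[0]} stored values"
        )
    return CondensedDistanceMatrix(n=n, values=values, ensemble_offsets=offsets)
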