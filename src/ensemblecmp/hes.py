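"""Harmonic ensemble similarity (HES).

Each ensemble (superposed to a common reference) is modelled as one
multivariate Gaussian N(mu, Sigma) over the flattened 3N coordinates.
Because the number of frames is usually far below 3N the sample covariance
is singular, so Sigma is estimated with Schafer-Strimmer analytic shrinkage
toward its own diagonal: off-diagonal entries are damped by the data-driven
intensity lambda* and a small eigenvalue floor guarantees positive
definiteness even for a zero-variance ensemble.

Two models are scored with the symmetrized Kullback-Leibler divergence,
taken as the SUM of the two directed KLs. For Gaussians the log-determinant
terms cancel in the sum, leaving the closed form

    D = 1/2 [ tr(S1^-1 S2) + tr(S2^-1 S1) - 2d
              + (mu1-mu2)^T (S1^-1 + S2^-1) (mu1-mu2) ],  d = 3N.

D is symmetric, zero iff the models coincide, and unbounded above.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ensemble_io import Ensemble
from .exceptions import DataError, InsufficientDataError, NumericalError, ShapeError

__all__ = ["GaussianModel", "fit_gaussian_model", "hes_divergence"]

#: relative eigenvalue floor applied when inverting a covariance
EIGENVALUE_FLOOR_REL = 1e-10
#: absolute floor (A^2) so a zero-variance ensemble still yields a PD model
EIGENVALUE_FLOOR_ABS = 1e-12


@dataclass
class GaussianModel:
    """Gaussian representation of one superposed ensemble.

    mu : 3N mean vector (Å); sigma : 3N x 3N covariance (Å^2), symmetric
    positive definite after shrinkage; shrinkage_intensity : lambda in [0,1].
    """

    mu: np.ndarray
    sigma: np.ndarray
    shrinkage_intensity: float = 0.0

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=np.float64)
        self.sigma = np.asarray(self.sigma, dtype=np.float64)
        if self.sigma.shape != (self.mu.size, self.mu.size):
            raise ShapeError(
                f"sigma shape {self.sigma.shape} does not match mu length {self.mu.size}"
            )

    @property
    def dim(self) -> int:
        return self.mu.size


def shrinkage_covariance(x: np.ndarray):
    """Schafer-Strimmer covariance with a diagonal shrinkage target.

    Returns ``(sigma, lambda_star)`` where off-diagonal entries of the
    unbiased sample covariance are scaled by ``1 - lambda_star`` and
    ``lambda_star`` is the analytic intensity
    ``sum Var(s_ij) / sum s_ij^2`` over ``i != j``, clipped to [0, 1].
    """
    n, d = x.shape
    xc = x - x.mean(axis=0)
    s = (xc.T @ xc) / (n - 1)
    # Var-hat(s_ij) = n/(n-1)^3 * sum_k (w_kij - wbar_ij)^2, w_kij = xc_ki xc_kj
    xc2 = xc * xc
    sum_w2 = xc2.T @ xc2                      # sum_k w_kij^2
    wbar = (xc.T @ xc) / n
    var_s = (n / (n - 1.0) ** 3) * (sum_w2 - n * wbar * wbar)
    off = ~np.eye(d, dtype=bool)
    denom = float((s[off] ** 2).sum())
    lam = 1.0 if denom == 0.0 else float(np.clip(var_s[off].sum() / denom, 0.0, 1.0))
    sigma = s.copy()
    sigma[off] *= 1.0 - lam
    return sigma, lam


def fit_gaussian_model(ens: Ensemble) -> GaussianModel:
    """Fit N(mu, Sigma) to a superposed ensemble's flattened coordinates."""
    if ens.n_frames < 2:
        raise InsufficientDataError(
            f"need >= 2 frames to estimate a covariance, got {ens.n_frames}"
        )
    x = ens.flat
    if not np.isfinite(x).all():
        raise DataError("non-finite coordinates")
    sigma, lam = shrinkage_covariance(x)
    # guarantee positive definiteness (sigma is PSD; lift the spectrum floor)
    floor = max(EIGENVALUE_FLOOR_REL * float(sigma.diagonal().max()), EIGENVALUE_FLOOR_ABS)
    sigma[np.diag_indices_from(sigma)] += floor
    return GaussianModel(mu=x.mean(axis=0), sigma=sigma, shrinkage_intensity=lam)


def _inverse_pd(sigma: np.ndarray) -> np.ndarray:
    """Invert a symmetric PD matrix via eigendecomposition with a floor."""
    evals, evecs = np.linalg.eigh(sigma)
    if evals[-1] <= 0:
        raise NumericalError(
            "covariance is not positive definite; refit the model "
            "(fit_gaussian_model applies shrinkage and a spectral floor)"
        )
    floor = max(EIGENVALUE_FLOOR_REL * evals[-1], EIGENVALUE_FLOOR_ABS)
    if evals[0] <= 0:
        raise NumericalError(
            "covariance has a non-positive eigenvalue; refit the model"
        )
    evals = np.maximum(evals, floor)
    return (evecs / evals) @ evecs.T


def hes_divergence(g1: GaussianModel, g2: GaussianModel) -> float:
    """Symmetrized (summed) Gaussian KL divergence between two models, >= 0."""
    if g1.dim != g2.dim:
        raise ShapeError(f"dimension mismatch: {g1.dim} vs {g2.dim}")
    inv1 = _inverse_pd(g1.sigma)
    inv2 = _inverse_pd(g2.sigma)
    d = g1.dim
    # tr(A B) for symmetric A, B as an elementwise sum: symmetric in arguments
    tr12 = float(np.sum(inv1 * g2.sigma))
    tr21 = float(np.sum(inv2 * g1.sigma))
    dmu = g1.mu - g2.mu
    quad = float(dmu @ (inv1 + inv2) @ dmu)
    value = 0.5 * (tr12 + tr21 - 2.0 * d + quad)
    return max(value, 0.0)
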