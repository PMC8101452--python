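"""Mahalanobis fundamental-niche ellipsoids with bootstrap uncertainty.

A fundamental niche is modelled as a multivariate-normal ellipsoid in the
k-dimensional PCA environmental space: mean vector ``mu`` and covariance
``sigma`` estimated from a species' occurrence scores. Under multivariate
normality the squared Mahalanobis distance D² of a point from ``mu`` follows
a chi-square distribution with k degrees of freedom, so the upper-tail
probability ``P(chi²_k >= D²)`` is a within-niche probability: 1 at the
centroid, decreasing monotonically outwards, with the p >= 0.9 ellipsoid
nested inside p >= 0.5 inside p >= 0.1.

Sampling uncertainty is propagated by the classical bootstrap: B
with-replacement resamples of the occurrence set, each refit to its own
ellipsoid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, stats

from climniche._rng import substream

__all__ = [
    "DegenerateCovarianceError",
    "NicheModel",
    "BootstrapEnsemble",
    "fit_niche",
    "bootstrap_niches",
    "mahalanobis_sq",
    "niche_probability",
    "ellipsoid_threshold",
]

# Relative eigenvalue floor below which a covariance is treated as degenerate.
_DEGENERACY_RTOL = 1e-10


class DegenerateCovarianceError(ValueError):
    """Raised when a point set has a (numerically) singular covariance."""


@dataclass
class NicheModel:
    """One fitted niche ellipsoid: mean, covariance and its provenance.

    ``df`` (the chi-square degrees of freedom) equals the dimension of
    ``mu``. ``bootstrap_id`` is the resample index, or ``"point-estimate"``
    for a fit on the original points.
    """

    mu: np.ndarray
    sigma: np.ndarray
    n_points: int
    bootstrap_id: int | str = "point-estimate"
    _chol: np.ndarray = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.mu = np.atleast_1d(np.asarray(self.mu, dtype=float))
        self.sigma = np.atleast_2d(np.asarray(self.sigma, dtype=float))
        k = self.mu.shape[0]
        if self.sigma.shape != (k, k):
            raise ValueError("sigma must be k x k for a k-vector mu")
        if not np.allclose(self.sigma, self.sigma.T):
            raise ValueError("sigma must be symmetric")
        try:
            self._chol = linalg.cholesky(self.sigma, lower=True)
        except linalg.LinAlgError:
            raise DegenerateCovarianceError(
                "sigma is not positive definite"
            ) from None

    @property
    def df(self) -> int:
        return self.mu.shape[0]


def _sample_mean_cov(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = points.mean(axis=0)
    centered = points - mu
    sigma = centered.T @ centered / (points.shape[0] - 1)
    return mu, np.atleast_2d(sigma)


def _is_degenerate(sigma: np.ndarray) -> bool:
    eig = np.linalg.eigvalsh(np.atleast_2d(sigma))
    return bool(eig[0] <= _DEGENERACY_RTOL * max(eig[-1], 1.0))


def fit_niche(points) -> NicheModel:
    """Fit a niche ellipsoid to k-dimensional points.

    ``mu`` is the componentwise mean and ``sigma`` the sample covariance with
    the n-1 denominator. Requires at least k+1 points in general position.

    Raises
    ------
    DegenerateCovarianceError
        If there are too few points or the covariance is singular.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.ndim != 2:
        raise ValueError("points must be an (n, k) array")
    n, k = pts.shape
    if n < k + 1:
        raise DegenerateCovarianceError(
            f"need at least k+1={k + 1} points, got {n}"
        )
    mu, sigma = _sample_mean_cov(pts)
    if _is_degenerate(sigma):
        raise DegenerateCovarianceError(
            "points are collinear/degenerate: covariance is singular"
        )
    return NicheModel(mu=mu, sigma=sigma, n_points=n)


@dataclass
class BootstrapEnsemble:
    """B bootstrap niche models for one species, plus the RNG record."""

    species_id: str
    models: list[NicheModel]
    seed: int | None = None
    stream: str | None = None

    def __post_init__(self) -> None:
        if not self.models:
            raise ValueError("ensemble must contain at least one model")
        ks = {m.df for m in self.models}
        if len(ks) != 1:
            raise ValueError("all ensemble members must share the dimension k")

    @property
    def B(self) -> int:
        return len(self.models)

    @property
    def k(self) -> int:
        return self.models[0].df

    def to_frame(self) -> pd.DataFrame:
        """Serialize to a long table (sigma entries row-major)."""
        k = self.k
        rows = []
        for m in self.models:
            row: dict = {
                "species": self.species_id,
                "bootstrap_id": m.bootstrap_id,
                "n_points": m.n_points,
            }
            for i in range(k):
                row[f"mu_{i + 1}"] = m.mu[i]
            for i in range(k):
                for j in range(k):
                    row[f"sigma_{i + 1}_{j + 1}"] = m.sigma[i, j]
            rows.append(row)
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "BootstrapEnsemble":
        species = frame["species"].unique()
        if len(species) != 1:
            raise ValueError("frame must describe exactly one species")
        k = sum(c.startswith("mu_") for c in frame.columns)
        models = []
        for _, row in frame.iterrows():
            mu = np.array([row[f"mu_{i + 1}"] for i in range(k)])
            sigma = np.array(
                [[row[f"sigma_{i + 1}_{j + 1}"] for j in range(k)] for i in range(k)]
            )
            models.append(
                NicheModel(
                    mu=mu,
                    sigma=sigma,
                    n_points=int(row["n_points"]),
                    bootstrap_id=row["bootstrap_id"],
                )
            )
        return cls(species_id=str(species[0]), models=models)


def bootstrap_niches(
    points,
    B: int = 1000,
    seed: int = 0,
    species_id: str = "species",
    max_redraws: int = 100,
    ridge_delta: float = 1e-8,
) -> BootstrapEnsemble:
    """Fit B niche models on with-replacement resamples of size n.

    Degenerate resamples are redrawn up to ``max_redraws`` times; if still
    singular the covariance is ridge-regularized by adding
    ``ridge_delta * trace(sigma) / k`` to the diagonal, with a warning.

    The original points must themselves be non-degenerate (checked before any
    resampling). Identical ``(seed, species_id)`` reproduces the ensemble
    bit-for-bit.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    fit_niche(pts)  # refuse degenerate inputs up front
    n, k = pts.shape
    stream = f"bootstrap/{species_id}"
    rng = substream(seed, stream)
    models = []
    for b in range(B):
        for _attempt in range(max_redraws + 1):
            idx = rng.integers(0, n, size=n)
            mu, sigma = _sample_mean_cov(pts[idx])
            if not _is_degenerate(sigma):
                break
        if _is_degenerate(sigma):
            warnings.warn(
                f"{species_id}: bootstrap {b} degenerate after "
                f"{max_redraws} redraws; ridge-regularizing",
                RuntimeWarning,
                stacklevel=2,
            )
            sigma = sigma + np.eye(k) * ridge_delta * max(
                np.trace(sigma) / k, 1.0
            )
        models.append(NicheModel(mu=mu, sigma=sigma, n_points=n, bootstrap_id=b))
    return BootstrapEnsemble(
        species_id=species_id, models=models, seed=seed, stream=stream
    )


def mahalanobis_sq(model: NicheModel, x) -> np.ndarray | float:
    """Squared Mahalanobis distance D² of point(s) x from the niche centre.

    Computed via the Cholesky factor of sigma and a triangular solve (no
    explicit matrix inverse). ``x`` may be a single k-vector or an (n, k)
    array.
    """
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    pts = np.atleast_2d(x)
    diff = pts - model.mu
    z = linalg.solve_triangular(model._chol, diff.T, lower=True)
    d2 = np.einsum("ij,ij->j", z, z)
    return float(d2[0]) if single else d2


def niche_probability(model: NicheModel, x) -> np.ndarray | float:
    """Within-niche probability of point(s) x.

    The upper-tail chi-square probability of D² at df = k degrees of
    freedom: 1 exactly at the centroid, strictly decreasing along any ray
    leaving it, in [0, 1] everywhere.
    """
    d2 = mahalanobis_sq(model, x)
    return stats.chi2.sf(d2, df=model.df)


def ellipsoid_threshold(model: NicheModel, p_level: float) -> float:
    """D² threshold of the probability-p_level ellipsoid surface.

    Points with within-niche probability >= p_level satisfy D² <= t, where t
    is the chi-square upper-tail quantile of p_level at df = k. Thresholds
    for p = 0.9, 0.5, 0.1 are strictly increasing (nested ellipsoids, the
    0.9 surface innermost).
    """
    if not 0.0 < p_level < 1.0:
        raise ValueError("p_level must lie strictly between 0 and 1")
    return float(stats.chi2.isf(p_level, df=model.df))
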