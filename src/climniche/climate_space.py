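"""PCA environmental space fitted to the current-climate stack.

The 19 bioclimatic variables are highly collinear, so the environmental
space is built by principal components analysis: rainfall-derived variables
are log-transformed (log1p, tolerating zero precipitation), every variable
is z-scored over the valid study-area cells, and the correlation-scale
covariance of the z-scores is eigen-decomposed. The first k components
(default 3) define the space; future climate stacks are projected with the
*current-climate* transform — same log set, centering, scaling and loadings —
so current and future conditions are directly comparable, with extrapolation
beyond the training range permitted.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import stats

from climniche.grids import PRECIP_VARS, BioclimStack, GridSpec, PCStack, RasterStack

__all__ = [
    "ClimateTransform",
    "CoreEllipsoid",
    "fit_climate_transform",
    "to_env_space",
    "climate_core_ellipsoid",
    "distribution_diagnostics",
]

logger = logging.getLogger(__name__)


@dataclass
class ClimateTransform:
    """Frozen preprocessing + PCA rotation fitted on current climate.

    ``loadings`` is the 19 x k matrix of orthonormal eigenvector columns;
    ``variance_fraction`` reports the fraction of total variance carried by
    each of all 19 components (non-increasing, summing to 1). ``center`` and
    ``scale`` are on the post-log scale.
    """

    variables: tuple[str, ...]
    log_vars: tuple[str, ...]
    center: np.ndarray
    scale: np.ndarray
    loadings: np.ndarray
    variance_fraction: np.ndarray
    k: int

    def __post_init__(self) -> None:
        self.variables = tuple(self.variables)
        self.log_vars = tuple(self.log_vars)
        self.center = np.asarray(self.center, dtype=float)
        self.scale = np.asarray(self.scale, dtype=float)
        self.loadings = np.asarray(self.loadings, dtype=float)
        self.variance_fraction = np.asarray(self.variance_fraction, dtype=float)
        p = len(self.variables)
        if self.center.shape != (p,) or self.scale.shape != (p,):
            raise ValueError("center/scale must have one entry per variable")
        if np.any(self.scale <= 0):
            raise ValueError("scale entries must be positive")
        if self.loadings.shape != (p, self.k):
            raise ValueError("loadings must be (n_variables, k)")

    @property
    def cumulative_fraction(self) -> float:
        """Fraction of total variance carried by the k retained components."""
        return float(self.variance_fraction[: self.k].sum())

    def preprocess(self, table: np.ndarray) -> np.ndarray:
        """Apply log1p to the rainfall set and z-score an (n, 19) table."""
        x = np.asarray(table, dtype=float).copy()
        for name in self.log_vars:
            j = self.variables.index(name)
            x[:, j] = np.log1p(x[:, j])
        return (x - self.center) / self.scale

    def transform(self, table: np.ndarray) -> np.ndarray:
        """Project an (n, 19) raw-value table to (n, k) PC scores."""
        return self.preprocess(table) @ self.loadings

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "variables": list(self.variables),
            "log_vars": list(self.log_vars),
            "center": self.center.tolist(),
            "scale": self.scale.tolist(),
            "loadings": self.loadings.tolist(),
            "variance_fraction": self.variance_fraction.tolist(),
            "k": self.k,
        }
        path.write_text(json.dumps(payload, indent=2))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "ClimateTransform":
        d = json.loads(Path(path).read_text())
        return cls(
            variables=tuple(d["variables"]),
            log_vars=tuple(d["log_vars"]),
            center=np.array(d["center"]),
            scale=np.array(d["scale"]),
            loadings=np.array(d["loadings"]),
            variance_fraction=np.array(d["variance_fraction"]),
            k=int(d["k"]),
        )


@dataclass
class CoreEllipsoid:
    """Core-climate ellipsoid of an environmental cloud at a p-level.

    Summarizes where the bulk of a climate's conditions sit in PC space:
    points whose chi-square niche probability (w.r.t. the cloud's own mean
    and covariance) is at least ``p_level`` lie inside, i.e. D² <=
    ``d2_threshold`` with the threshold the chi-square upper-tail quantile
    of ``p_level`` at k degrees of freedom.
    """

    center: np.ndarray
    covariance: np.ndarray
    p_level: float
    d2_threshold: float

    def contains(self, x) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        diff = x - self.center
        d2 = np.einsum(
            "ij,ij->i", diff @ np.linalg.inv(self.covariance), diff
        )
        return d2 <= self.d2_threshold


def fit_climate_transform(
    stack: BioclimStack,
    mask: np.ndarray | RasterStack | None = None,
    log_vars: tuple[str, ...] = PRECIP_VARS,
    k: int = 3,
) -> ClimateTransform:
    """Fit the log/z-score/PCA transform on valid study-area cells.

    ``mask`` optionally restricts fitting to a study area (boolean array of
    grid shape, or a one-layer raster whose valid cells define the area); it
    is intersected with the stack's own nodata mask.

    Raises
    ------
    ValueError
        If a variable is constant over the valid cells (zero scale, named in
        the message), a log variable is negative somewhere, or fewer than
        k+1 valid cells remain.
    """
    valid = stack.mask.copy()
    if mask is not None:
        m = mask.mask if isinstance(mask, RasterStack) else np.asarray(mask, bool)
        valid &= m
    table = stack.data[:, valid].T
    n = table.shape[0]
    if n < k + 1:
        raise ValueError(f"need at least k+1={k + 1} valid cells, got {n}")
    names = stack.names
    x = table.copy()
    for name in log_vars:
        j = names.index(name)
        if np.any(x[:, j] < 0):
            raise ValueError(f"log variable {name} has negative values")
        x[:, j] = np.log1p(x[:, j])
    center = x.mean(axis=0)
    scale = x.std(axis=0, ddof=1)
    # a constant layer leaves only rounding residue in its std
    tol = 100 * np.finfo(float).eps * np.maximum(1.0, np.abs(center))
    zero = [names[j] for j in np.nonzero(scale <= tol)[0]]
    if zero:
        raise ValueError(
            f"variable(s) constant over valid cells (zero scale): {zero}"
        )
    z = (x - center) / scale
    corr = z.T @ z / (n - 1)
    eigvals, eigvecs = np.linalg.eigh(corr)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    eigvecs = eigvecs[:, order]
    # sign convention: the largest-|loading| entry of each column is positive
    flip = np.sign(eigvecs[np.argmax(np.abs(eigvecs), axis=0), np.arange(len(names))])
    flip[flip == 0] = 1.0
    eigvecs = eigvecs * flip
    variance_fraction = eigvals / eigvals.sum()
    transform = ClimateTransform(
        variables=names,
        log_vars=tuple(log_vars),
        center=center,
        scale=scale,
        loadings=eigvecs[:, :k],
        variance_fraction=variance_fraction,
        k=k,
    )
    logger.info(
        "climate transform fitted on %d cells: retained k=%d components "
        "explaining %.1f%% of variance",
        n,
        k,
        100 * transform.cumulative_fraction,
    )
    return transform


def to_env_space(stack: BioclimStack, transform: ClimateTransform) -> PCStack:
    """Project any bioclim stack into the fitted environmental space.

    Future stacks are transformed with the current-climate transform, so
    scores remain comparable across scenarios; values outside the training
    range are extrapolated linearly (scores stay finite). Nodata propagates:
    the output mask equals the source stack mask.
    """
    missing = [v for v in transform.variables if v not in stack.names]
    if missing:
        raise ValueError(f"stack is missing required variable(s): {missing}")
    order = [stack.names.index(v) for v in transform.variables]
    table = stack.data[order][:, stack.mask].T
    scores = transform.transform(table)
    data = np.full((transform.k,) + stack.grid.shape, np.nan)
    data[:, stack.mask] = scores.T
    return PCStack(
        names=tuple(f"PC{i + 1}" for i in range(transform.k)),
        data=data,
        mask=stack.mask.copy(),
        grid=stack.grid,
        transform=transform,
    )


def climate_core_ellipsoid(env: PCStack, p_level: float = 0.75) -> CoreEllipsoid:
    """Fit the core-climate ellipsoid of an environmental cloud.

    Center is the mean of valid-cell scores and covariance their sample
    covariance (n-1); the threshold is chosen so points with niche
    probability >= p_level fall inside. As p_level -> 1 the ellipsoid
    shrinks to the center.
    """
    if not 0.0 < p_level < 1.0:
        raise ValueError("p_level must lie strictly between 0 and 1")
    scores = env.scores()
    k = env.k
    if scores.shape[0] < k + 1:
        raise ValueError(f"need at least k+1={k + 1} valid cells")
    center = scores.mean(axis=0)
    cov = np.cov(scores, rowvar=False, ddof=1)
    cov = np.atleast_2d(cov)
    eig = np.linalg.eigvalsh(cov)
    if eig[0] <= 1e-12 * max(eig[-1], 1.0):
        raise ValueError("degenerate covariance of cell scores")
    return CoreEllipsoid(
        center=center,
        covariance=cov,
        p_level=p_level,
        d2_threshold=float(stats.chi2.isf(p_level, df=k)),
    )


def distribution_diagnostics(
    stack: BioclimStack, log_vars: tuple[str, ...] = PRECIP_VARS
):
    """Per-variable skewness before/after the log transform (diagnostic only).

    Returns a table useful for judging whether the configured log set leaves
    every variable unimodal and not overly skewed; it is advisory and never
    gates the fit.
    """
    import pandas as pd

    rows = []
    for i, name in enumerate(stack.names):
        vals = stack.data[i][stack.mask]
        raw_skew = float(stats.skew(vals))
        logged = name in log_vars
        post = float(stats.skew(np.log1p(vals))) if logged else raw_skew
        rows.append(
            {
                "variable": name,
                "log_transformed": logged,
                "skewness_raw": raw_skew,
                "skewness_used": post,
            }
        )
    return pd.DataFrame(rows)
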