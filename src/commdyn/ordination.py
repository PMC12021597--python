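"""Bray-Curtis dissimilarity, principal coordinate analysis and non-metric
multidimensional scaling.

PCoA follows the classical recipe: Gower double-centering of -d^2/2,
eigendecomposition, coordinates = eigenvectors scaled by the square roots of
the (positive) eigenvalues.  Negative eigenvalues are reported and their
axes dropped — no Cailliez/Lingoes correction.

NMDS minimizes Kruskal stress-1,

    stress = sqrt( sum (d_config - d_fitted)^2 / sum d_config^2 ),

alternating a monotone (isotonic) regression of configuration distances on
the dissimilarities with a Guttman-transform configuration update, over
``n_starts`` random initializations plus one PCoA initialization; the lowest
final stress wins.  Within a run the recorded stress sequence is
non-increasing: an iteration that would raise stress terminates the run on
the previous configuration.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.isotonic import IsotonicRegression

logger = logging.getLogger(__name__)

__all__ = ["DistanceMatrix", "Ordination", "bray_curtis", "pcoa", "nmds"]


@dataclass
class DistanceMatrix:
    """Symmetric pairwise dissimilarity matrix with a zero diagonal."""

    values: np.ndarray
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = self.values.shape[0]
        if self.values.shape != (n, n):
            raise ValueError("distance matrix must be square")
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length must match matrix size")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 0.0, atol=1e-12):
            raise ValueError("distance matrix must have a zero diagonal")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "DistanceMatrix":
        return cls(frame.to_numpy(dtype=float), [str(c) for c in frame.columns])

    def condensed(self) -> np.ndarray:
        """Upper-triangle entries (i < j) in row-major order."""
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]


@dataclass
class Ordination:
    """Low-dimensional sample configuration from PCoA or NMDS."""

    coordinates: np.ndarray
    sample_ids: list[str]
    method: str
    eigenvalues: np.ndarray | None = None
    negative_eigenvalues: np.ndarray | None = None
    stress: float | None = None
    converged: bool = True
    stress_history: list[float] = field(default_factory=list)

    @property
    def k(self) -> int:
        return self.coordinates.shape[1]

    def to_frame(self) -> pd.DataFrame:
        cols = [f"axis_{i + 1}" for i in range(self.k)]
        return pd.DataFrame(self.coordinates, index=self.sample_ids, columns=cols)


def bray_curtis(matrix: pd.DataFrame) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarities between sample columns.

    d(u, v) = sum |u_i - v_i| / sum (u_i + v_i); values lie in [0, 1], are 0
    for identical columns and 1 for disjoint supports.
    """
    x = matrix.to_numpy(dtype=float)
    if (x < 0).any():
        raise ValueError("abundance values must be non-negative")
    colsum = x.sum(axis=0)
    zero = colsum <= 0
    if zero.any():
        raise ValueError(f"all-zero sample(s): {list(matrix.columns[zero])}")
    n = x.shape[1]
    cols = np.ascontiguousarray(x.T)  # contiguous per-sample vectors
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = np.abs(cols[i] - cols[j]).sum() / (cols[i] + cols[j]).sum()
    d = d + d.T
    return DistanceMatrix(d, [str(c) for c in matrix.columns])


def pcoa(dist: DistanceMatrix, k: int = 2) -> Ordination:
    """Principal coordinate analysis of a distance matrix.

    Gower-centers -d^2/2, eigendecomposes, and returns the top-``k`` axes
    scaled by sqrt(eigenvalue).  If fewer than ``k`` positive eigenvalues
    exist, the returned dimensionality shrinks with a warning.  For
    Euclidean-embeddable input the pairwise distances among the full-rank
    coordinates reproduce the input to numerical precision.
    """
    n = dist.n
    if k > n - 1:
        raise ValueError("k must be at most n - 1")
    d2 = dist.values**2
    a = -0.5 * d2
    centering = np.eye(n) - np.ones((n, n)) / n
    b = centering @ a @ centering
    eigvals, eigvecs = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]

    tol = max(1e-10, 1e-10 * abs(eigvals[0])) if n else 0.0
    positive = eigvals > tol
    n_pos = int(positive.sum())
    k_eff = min(k, n_pos)
    if k_eff < k:
        warnings.warn(
            f"requested k={k} but only {n_pos} positive eigenvalues; returning k={k_eff}",
            stacklevel=2,
        )
    coords = eigvecs[:, :k_eff] * np.sqrt(eigvals[:k_eff])
    return Ordination(
        coordinates=coords,
        sample_ids=list(dist.sample_ids),
        method="PCoA",
        eigenvalues=eigvals[:n_pos],
        negative_eigenvalues=eigvals[eigvals < -tol],
    )


def _stress1(d_config: np.ndarray, d_fitted: np.ndarray) -> float:
    denom = (d_config**2).sum()
    if denom <= 0:
        return 0.0
    return float(np.sqrt(((d_config - d_fitted) ** 2).sum() / denom))


def _pairwise(coords: np.ndarray, iu) -> np.ndarray:
    diff = coords[iu[0]] - coords[iu[1]]
    return np.sqrt((diff**2).sum(axis=1))


def _guttman(coords: np.ndarray, d_fitted: np.ndarray, iu) -> np.ndarray:
    """Single SMACOF majorization step toward the fitted disparities."""
    n = coords.shape[0]
    d = _pairwise(coords, iu)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(d > 0, d_fitted / np.where(d > 0, d, 1.0), 0.0)
    b = np.zeros((n, n))
    b[iu] = -ratio
    b = b + b.T
    np.fill_diagonal(b, -b.sum(axis=1))
    return b @ coords / n


def nmds(
    dist: DistanceMatrix,
    k: int = 2,
    n_starts: int = 20,
    max_iter: int = 300,
    tol: float = 1e-6,
    seed: int | None = None,
) -> Ordination:
    """Non-metric multidimensional scaling by Kruskal stress-1 minimization.

    Runs ``n_starts`` random initializations plus one PCoA initialization and
    returns the configuration with the lowest stress; coordinates are
    centered.  A run stops when the stress improvement falls below ``tol``
    (converged) or ``max_iter`` is hit (flagged); if every start fails to
    converge the lowest-stress configuration is still returned with
    ``converged=False``.
    """
    n = dist.n
    if n < k + 2:
        raise ValueError("NMDS needs at least k + 2 samples")
    rng = np.random.default_rng(seed)
    iu = np.triu_indices(n, k=1)
    dissim = dist.values[iu]
    order = np.argsort(dissim, kind="stable")
    iso = IsotonicRegression(increasing=True, out_of_bounds="clip")

    inits = []
    try:
        p = pcoa(dist, k=min(k, n - 1))
        c = p.coordinates
        if c.shape[1] < k:  # pad missing axes with zeros
            c = np.hstack([c, np.zeros((n, k - c.shape[1]))])
        inits.append(c)
    except Exception:  # pragma: no cover - PCoA init is best-effort
        pass
    for _ in range(n_starts):
        inits.append(rng.normal(size=(n, k)))

    best = None
    best_stress = np.inf
    best_converged = False
    best_history: list[float] = []
    for coords in inits:
        coords = coords - coords.mean(axis=0)
        scale = np.sqrt((coords**2).sum())
        if scale > 0:
            coords = coords / scale
        history: list[float] = []
        converged = False
        prev_stress = np.inf
        for _ in range(max_iter):
            d = _pairwise(coords, iu)
            # monotone regression of configuration distances on dissimilarity
            # ranks; ties averaged within blocks (primary approach)
            fitted_sorted = iso.fit_transform(dissim[order], d[order])
            d_fitted = np.empty_like(d)
            d_fitted[order] = fitted_sorted
            stress = _stress1(d, d_fitted)
            if stress > prev_stress:  # would increase: stop on previous iterate
                coords = prev_coords
                break
            history.append(stress)
            if prev_stress - stress < tol:
                converged = True
                break
            prev_stress = stress
            prev_coords = coords
            coords = _guttman(coords, d_fitted, iu)
            norm = np.sqrt((coords**2).sum())
            if norm > 0:
                coords = coords / norm
        final_stress = history[-1] if history else np.inf
        if final_stress < best_stress:
            best_stress = final_stress
            best = coords - coords.mean(axis=0)
            best_converged = converged
            best_history = history
    if not best_converged:
        logger.warning("NMDS: no start converged; returning lowest-stress configuration")
    return Ordination(
        coordinates=best,
        sample_ids=list(dist.sample_ids),
        method="NMDS",
        stress=best_stress,
        converged=best_converged,
        stress_history=best_history,
    )


def plot_ordination(ord_result: Ordination, groups=None, ax=None):
    """2-D scatter of the first two axes with optional 95% group ellipses.

    Ellipse radii use the chi-square(2) 95% quantile of each group's
    covariance.  Requires matplotlib; imported lazily.
    """
    import matplotlib.pyplot as plt
    from matplotlib.patches import Ellipse

    if ax is None:
        _, ax = plt.subplots()
    xy = ord_result.coordinates[:, :2]
    if groups is None:
        ax.scatter(xy[:, 0], xy[:, 1], s=12)
    else:
        groups = np.asarray(groups)
        for g in pd.unique(groups):
            pts = xy[groups == g]
            ax.scatter(pts[:, 0], pts[:, 1], s=12, label=str(g))
            if len(pts) >= 3:
                cov = np.cov(pts.T)
                vals, vecs = np.linalg.eigh(cov)
                angle = np.degrees(np.arctan2(vecs[1, -1], vecs[0, -1]))
                radius = np.sqrt(5.991)  # chi2(2) 0.95 quantile
                ax.add_patch(
                    Ellipse(
                        pts.mean(axis=0),
                        2 * radius * np.sqrt(max(vals[-1], 0)),
                        2 * radius * np.sqrt(max(vals[0], 0)),
                        angle=angle,
                        fill=False,
                    )
                )
        ax.legend()
    ax.set_xlabel("axis 1")
    ax.set_ylabel("axis 2")
    ax.set_title(ord_result.method)
    return ax
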