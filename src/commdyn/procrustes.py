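"""Procrustes superimposition, the M^2 congruence statistic, and its
permutation significance test (protest).

The default protocol is symmetric: both configurations are centered and
scaled to unit total sum of squares before the optimal rotation is found
from the singular value decomposition of Y^T X, so

    M^2 = 1 - (sum of singular values)^2,   0 <= M^2 <= 1,

and exchanging the arguments leaves M^2 unchanged.  An asymmetric mode
(only Y normalized onto X) is available but off by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["ProcrustesResult", "procrustes_fit", "protest"]


@dataclass
class ProcrustesResult:
    """Optimal superimposition of configuration Y onto configuration X."""

    m_squared: float
    rotation: np.ndarray
    scale: float
    translation: np.ndarray
    p_value: float | None = None
    n_permutations: int | None = None


def _prepare(config: np.ndarray, name: str) -> tuple[np.ndarray, np.ndarray, float]:
    x = np.asarray(config, dtype=float)
    if x.ndim != 2:
        raise ValueError(f"{name} must be a 2-D configuration")
    centroid = x.mean(axis=0)
    centered = x - centroid
    norm = np.sqrt((centered**2).sum())
    if norm <= 0:
        raise ValueError(f"degenerate configuration {name}: all rows identical")
    return centered, centroid, norm


def _pad_columns(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    if x.shape[1] == y.shape[1]:
        return x, y
    k = max(x.shape[1], y.shape[1])
    warnings.warn(
        f"configurations have different dimensionality ({x.shape[1]} vs {y.shape[1]}); "
        f"zero-padding the smaller one to k={k}",
        stacklevel=3,
    )
    def pad(a):
        return np.hstack([a, np.zeros((a.shape[0], k - a.shape[1]))])
    return pad(x), pad(y)


def procrustes_fit(
    X: np.ndarray, Y: np.ndarray, symmetric: bool = True
) -> ProcrustesResult:
    """Optimally align configuration Y onto X by translation, rotation and
    uniform scaling; return the residual M^2 and the transformation.

    Both inputs are n x k coordinate matrices over the same n samples.  With
    ``symmetric=True`` (default) each configuration is scaled to unit total
    sum of squares first, so M^2 is bounded in [0, 1] and symmetric under
    argument exchange.  M^2 = 0 means Y is exactly a rotated/translated/
    scaled copy of X.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape[0] != Y.shape[0]:
        raise ValueError("configurations must have the same number of rows")
    X, Y = _pad_columns(X, Y)
    xc, x_centroid, x_norm = _prepare(X, "X")
    yc, y_centroid, y_norm = _prepare(Y, "Y")
    if symmetric:
        xc = xc / x_norm
        yc = yc / y_norm
        y_scaled = yc
    else:
        y_scaled = yc
    u, s, vt = np.linalg.svd(y_scaled.T @ xc)
    rotation = u @ vt
    trace = s.sum()
    if symmetric:
        scale = trace  # ||Y|| = 1 after normalization
        m_squared = max(0.0, 1.0 - trace**2)  # clamp float jitter at 0
    else:
        scale = trace / y_norm**2
        m_squared = float((xc**2).sum() - trace**2 / y_norm**2)
    translation = x_centroid - scale * (y_centroid @ rotation)
    return ProcrustesResult(
        m_squared=float(m_squared),
        rotation=rotation,
        scale=float(scale),
        translation=translation,
    )


def _batched_m2(xc: np.ndarray, yc: np.ndarray, perms: np.ndarray) -> np.ndarray:
    """M^2 for many row permutations of Y at once (symmetric protocol).

    Centering and total sum of squares are invariant under row permutation,
    so the pre-normalized matrices can be indexed directly.
    """
    yp = yc[perms]  # (n_perm, n, k)
    cross = np.einsum("pnk,nl->pkl", yp, xc)
    sv = np.linalg.svd(cross, compute_uv=False)
    return 1.0 - sv.sum(axis=1) ** 2


def protest(
    X: np.ndarray,
    Y: np.ndarray,
    n_permutations: int = 999,
    seed: int | None = None,
) -> ProcrustesResult:
    """Permutation test of Procrustes congruence (symmetric protocol).

    The observed M^2 is compared against M^2 values obtained after randomly
    reordering the rows of Y; the p-value uses the add-one estimator

        p = (1 + #{permuted M^2 <= observed M^2}) / (1 + n_permutations),

    so it can never be exactly zero.  Reproducible given ``seed``.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    result = procrustes_fit(X, Y, symmetric=True)
    Xa = np.asarray(X, dtype=float)
    Ya = np.asarray(Y, dtype=float)
    Xa, Ya = _pad_columns(Xa, Ya)
    xc, _, xn = _prepare(Xa, "X")
    yc, _, yn = _prepare(Ya, "Y")
    xc, yc = xc / xn, yc / yn
    rng = np.random.default_rng(seed)
    n = xc.shape[0]
    perms = np.array([rng.permutation(n) for _ in range(n_permutations)])
    m2_perm = _batched_m2(xc, yc, perms)
    n_le = int((m2_perm <= result.m_squared + 1e-12).sum())
    result.p_value = (1 + n_le) / (1 + n_permutations)
    result.n_permutations = n_permutations
    return result
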