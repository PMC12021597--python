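"""Regularized S-map inference of time-varying interaction strengths.

The S-map (sequential locally weighted global linear map) fits, at every
target time point n*, a linear model of each taxon's next-step abundance on
the full community state, with training transitions weighted by their
state-space proximity to the target state:

    c_hat = argmin_c (1/N) sum_n w_n (y_{n+1} - X_n c)^2
                     + lambda * ( alpha * ||c||_2^2 + (1 - alpha) * |c|_1 )

    w_n = exp( -theta * ||X_n - X_n*|| / mean_n ||X_n - X_n*|| )

The fitted coefficient of taxon j in the regression predicting taxon i is
the Jacobian element J[i, j, n*] — the local interaction strength of j on i.
theta controls locality (theta = 0 recovers a single global linear fit);
lambda and alpha control the elastic-net penalty.  Note the penalty is
parameterized with alpha on the squared-norm (ridge) term and 1 - alpha on
the absolute-norm (lasso) term — the mirror image of the glmnet convention
(glmnet's alpha equals 1 - alpha here).

Series are standardized to zero mean / unit variance per taxon before
fitting; Jacobians are reported in standardized units with an optional
back-transform J_raw[i, j] = J_std[i, j] * sd_i / sd_j.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd

from .containers import CommunityTimeSeries

logger = logging.getLogger(__name__)

__all__ = [
    "SMapHyperparams",
    "JacobianSeries",
    "standardize_series",
    "smap_weights",
    "weighted_elastic_net",
    "infer_interactions",
    "tune_hyperparams",
    "summarize_interactions",
]

DEFAULT_THETA_GRID = (0.0, 0.1, 0.5, 1.0, 2.0, 4.0, 8.0)
DEFAULT_LAMBDA_GRID = tuple(np.logspace(-4, 0, 7))


@dataclass
class SMapHyperparams:
    """Locality and elastic-net settings for the regularized S-map.

    theta >= 0 sets how sharply training weight decays with state-space
    distance from the target state; lam >= 0 is the overall penalty weight;
    alpha in [0, 1] mixes the penalty (alpha = 1: pure squared-norm/ridge,
    alpha = 0: pure absolute-norm/lasso).
    """

    theta: float = 0.0
    lam: float = 0.0
    alpha: float = 0.5

    def __post_init__(self) -> None:
        if self.theta < 0:
            raise ValueError("theta must be >= 0")
        if self.lam < 0:
            raise ValueError("lam must be >= 0")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")


@dataclass
class JacobianSeries:
    """Time-indexed interaction-strength matrices from the S-map.

    ``values[i, j, t]`` is the coefficient of predictor taxon j in the local
    regression predicting taxon i at time t+1, localized at the state X_t;
    intercepts are stored separately.  ``scale`` records whether entries are
    in standardized units or back-transformed to the raw abundance scale.
    """

    values: np.ndarray  # (n_taxa, n_taxa, n_targets)
    intercepts: np.ndarray  # (n_taxa, n_targets)
    time_indices: np.ndarray
    taxon_ids: list[str]
    hyperparams: SMapHyperparams
    scale: str = "standardized"
    failures: list[tuple[int, int]] = field(default_factory=list)

    @property
    def n_taxa(self) -> int:
        return self.values.shape[0]

    def time_averaged(self) -> np.ndarray:
        return self.values.mean(axis=2)

    def median_over_time(self) -> np.ndarray:
        return np.median(self.values, axis=2)

    def to_long_frame(self) -> pd.DataFrame:
        """Long-format table: (target, predictor, time, coefficient)."""
        rows = []
        for i, ti in enumerate(self.taxon_ids):
            for j, tj in enumerate(self.taxon_ids):
                for s, t in enumerate(self.time_indices):
                    rows.append((ti, tj, int(t), self.values[i, j, s]))
        return pd.DataFrame(rows, columns=["target", "predictor", "time", "coefficient"])


def standardize_series(
    series: CommunityTimeSeries,
) -> tuple[CommunityTimeSeries, pd.Series, pd.Series]:
    """Standardize each taxon to zero mean and unit variance across time.

    Zero-variance taxa are removed (logged); the returned means/sds allow an
    exact inverse transform for the retained taxa.  Raises if every taxon is
    constant or the series is shorter than 3 points.
    """
    if series.n_time < 3:
        raise ValueError("standardization needs at least 3 time points")
    x = series.abundances
    means = x.mean(axis=1)
    sds = x.std(axis=1)
    keep = sds > 0
    if not keep.any():
        raise ValueError("all taxa have zero variance")
    dropped = [series.taxon_ids[i] for i in np.where(~keep)[0]]
    if dropped:
        logger.info("standardize_series removed zero-variance taxa: %s", dropped)
    z = (x[keep] - means[keep, None]) / sds[keep, None]
    kept_ids = [tid for tid, k in zip(series.taxon_ids, keep) if k]
    kept_domains = (
        None
        if series.domain_labels is None
        else [d for d, k in zip(series.domain_labels, keep) if k]
    )
    out = CommunityTimeSeries(
        abundances=z,
        time_stamps=series.time_stamps.copy(),
        taxon_ids=kept_ids,
        domain_labels=kept_domains,
        standardized=True,
    )
    return out, pd.Series(means[keep], index=kept_ids), pd.Series(sds[keep], index=kept_ids)


def smap_weights(
    series: CommunityTimeSeries,
    target_index: int,
    theta: float,
    include_target_in_mean: bool = True,
) -> np.ndarray:
    """Locality weights for the training transitions of one local regression.

    Training transitions are the N-1 state pairs (X_n -> y_{n+1}),
    n = 0..N-2.  Each gets

        w_n = exp( -theta * ||X_n - X_n*|| / d_bar ),

    where ||.|| is the Euclidean distance in community state space and
    d_bar is the mean distance from the target state over the training
    states.  ``include_target_in_mean`` controls whether the target's own
    zero self-distance enters d_bar when the target is itself a training
    state (the printed formula's sum is ambiguous on this point).

    theta = 0 gives uniform weights of 1; the target transition, when
    included, always has weight exp(0) = 1.
    """
    if theta < 0:
        raise ValueError("theta must be >= 0")
    if not 0 <= target_index < series.n_time:
        raise ValueError("target_index outside the series")
    states = series.abundances.T  # (N, n_taxa)
    train = states[:-1]  # states with a successor
    target = states[target_index]
    dists = np.sqrt(((train - target) ** 2).sum(axis=1))
    if theta == 0:
        return np.ones(len(train))
    if include_target_in_mean or target_index >= len(train):
        mean_dist = dists.mean()
    else:
        mask = np.ones(len(train), dtype=bool)
        mask[target_index] = False
        mean_dist = dists[mask].mean()
    if mean_dist <= 0:
        raise ValueError("all community states identical: mean distance is zero")
    return np.exp(-theta * dists / mean_dist)


def _objective(
    X: np.ndarray, y: np.ndarray, w: np.ndarray, coef: np.ndarray, intercept: float,
    lam: float, alpha: float, n_factor: float,
) -> float:
    resid = y - intercept - X @ coef
    return float(
        (w * resid**2).sum() / n_factor
        + lam * (alpha * (coef**2).sum() + (1 - alpha) * np.abs(coef).sum())
    )


def weighted_elastic_net(
    X: np.ndarray,
    y: np.ndarray,
    w: np.ndarray,
    hyper: SMapHyperparams,
    n_factor: float | None = None,
    max_iter: int = 100_000,
    tol: float = 1e-8,
    coef_init: np.ndarray | None = None,
) -> dict:
    """Solve the weighted elastic-net problem of the S-map for one target.

    Minimizes

        (1/N) sum_n w_n (y_n - b - x_n . c)^2
        + lam * ( alpha * ||c||_2^2 + (1 - alpha) * |c|_1 )

    with an unpenalized intercept b handled by weighted centering.
    ``n_factor`` is the N of the 1/N factor (defaults to the number of rows;
    the S-map passes the series length, which only rescales lam).

    Cyclic coordinate descent with soft-thresholding handles any nonzero
    absolute-norm weight; when lam * (1 - alpha) == 0 the problem is a pure
    weighted ridge/OLS and is solved in closed form.  The objective is
    non-increasing across coordinate-descent sweeps; convergence is declared
    when the largest coefficient change in a sweep falls below ``tol``.

    Returns a dict with ``coef``, ``intercept``, ``converged``,
    ``n_iter``, ``effective_n`` (sum of weights) and ``objective``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.asarray(w, dtype=float)
    n, p = X.shape
    if y.shape != (n,) or w.shape != (n,):
        raise ValueError("X, y and w have inconsistent shapes")
    if (w < 0).any():
        raise ValueError("weights must be non-negative")
    if w.sum() <= 0:
        raise ValueError("weights sum to zero")
    N = float(n_factor) if n_factor is not None else float(n)
    lam, alpha = hyper.lam, hyper.alpha

    # unpenalized intercept: weighted centering
    wsum = w.sum()
    x_mean = (w[:, None] * X).sum(axis=0) / wsum
    y_mean = (w * y).sum() / wsum
    Xc = X - x_mean
    yc = y - y_mean

    l1 = lam * (1 - alpha)
    l2 = lam * alpha
    s = w / N

    if l1 == 0.0:
        # weighted ridge / OLS closed form
        gram = (Xc * s[:, None]).T @ Xc + l2 * np.eye(p)
        rhs = (Xc * s[:, None]).T @ yc
        coef = np.linalg.solve(gram, rhs)
        converged, n_iter = True, 0
    else:
        coef = (
            np.zeros(p)
            if coef_init is None
            else np.asarray(coef_init, dtype=float).copy()
        )
        sx = s[:, None] * Xc
        col_sq = 2.0 * (sx * Xc).sum(axis=0)  # 2 * sum s x_j^2
        denom = col_sq + 2.0 * l2
        resid = yc - Xc @ coef
        converged = False
        n_iter = 0
        for n_iter in range(1, max_iter + 1):
            max_delta = 0.0
            for j in range(p):
                cj_old = coef[j]
                # partial gradient with coordinate j removed
                z = 2.0 * (sx[:, j] @ resid) + col_sq[j] * cj_old
                cj_new = _soft_threshold(z, l1) / denom[j]
                if cj_new != cj_old:
                    resid += Xc[:, j] * (cj_old - cj_new)
                    coef[j] = cj_new
                    max_delta = max(max_delta, abs(cj_new - cj_old))
            if max_delta < tol:
                converged = True
                break
        if not converged:
            warnings.warn(
                f"weighted_elastic_net did not converge in {max_iter} sweeps "
                f"(last max coefficient change above {tol}); returning last iterate",
                stacklevel=2,
            )
    intercept = float(y_mean - x_mean @ coef)
    return {
        "coef": coef,
        "intercept": intercept,
        "converged": converged,
        "n_iter": n_iter,
        "effective_n": float(wsum),
        "objective": _objective(X, y, w, coef, intercept, lam, alpha, N),
    }


def _soft_threshold(z: float, threshold: float) -> float:
    if z > threshold:
        return z - threshold
    if z < -threshold:
        return z + threshold
    return 0.0


def infer_interactions(
    series: CommunityTimeSeries,
    hyper: SMapHyperparams,
    standardize: bool = True,
    raw_scale: bool = False,
    include_target_in_mean: bool = True,
) -> JacobianSeries:
    """Infer time-varying Jacobian interaction strengths for a whole series.

    For every target time t (0..N-2) and every target taxon i, fits the
    locally weighted elastic net of y_i(t+1) on the community state X_t's
    neighborhood; the coefficient of taxon j becomes J[i, j, t].

    With ``standardize=True`` (default) the series is z-scored per taxon
    first and coefficients are in standardized units; ``raw_scale=True``
    additionally back-transforms J_raw[i, j] = J_std[i, j] * sd_i / sd_j.
    Solver failures for individual (taxon, time) cells are recorded in
    ``failures`` (cell left NaN), never fatal.
    """
    if series.n_time < 10:
        warnings.warn(
            "series shorter than 10 points: S-map estimates will be unstable",
            stacklevel=2,
        )
    if standardize:
        work, _, sds = standardize_series(series)
    else:
        work, sds = series, pd.Series(np.ones(series.n_taxa), index=series.taxon_ids)

    states = work.abundances.T  # (N, p)
    n_time, p = states.shape
    n_targets = n_time - 1
    X = states[:-1]
    Y = states[1:]

    values = np.full((p, p, n_targets), np.nan)
    intercepts = np.full((p, n_targets), np.nan)
    failures: list[tuple[int, int]] = []
    warm: list[np.ndarray | None] = [None] * p
    for t in range(n_targets):
        w = smap_weights(work, t, hyper.theta, include_target_in_mean)
        for i in range(p):
            try:
                fit = weighted_elastic_net(
                    X, Y[:, i], w, hyper, n_factor=n_time, coef_init=warm[i]
                )
            except Exception:
                failures.append((i, t))
                continue
            values[i, :, t] = fit["coef"]
            intercepts[i, t] = fit["intercept"]
            warm[i] = fit["coef"]
    scale = "standardized"
    if raw_scale:
        sd = sds.to_numpy()
        values = values * (sd[:, None, None] / sd[None, :, None])
        scale = "raw"
    return JacobianSeries(
        values=values,
        intercepts=intercepts,
        time_indices=np.asarray(work.time_stamps[:-1]),
        taxon_ids=list(work.taxon_ids),
        hyperparams=hyper,
        scale=scale,
        failures=failures,
    )


def tune_hyperparams(
    series: CommunityTimeSeries,
    theta_grid=DEFAULT_THETA_GRID,
    lambda_grid=DEFAULT_LAMBDA_GRID,
    alpha_grid=(0.5,),
    standardize: bool = True,
    include_target_in_mean: bool = True,
) -> tuple[SMapHyperparams, pd.DataFrame]:
    """Select S-map hyperparameters by leave-one-out forecast skill.

    For each grid point, every transition is held out in turn: the local
    model for its target state is trained on the remaining transitions and
    used to forecast the held-out next-step abundances.  The grid point with
    the lowest mean forecast RMSE across taxa wins; ties break toward
    smaller theta, then larger lambda (the simpler model).

    Returns the selected hyperparameters and the full score table.
    """
    if not (len(theta_grid) and len(lambda_grid) and len(alpha_grid)):
        raise ValueError("hyperparameter grids must be non-empty")
    if series.n_time < 6:
        raise ValueError("series too short for leave-one-out tuning")
    work = standardize_series(series)[0] if standardize else series
    states = work.abundances.T
    n_time, p = states.shape
    X_all = states[:-1]
    Y_all = states[1:]
    n_trans = n_time - 1

    rows = []
    for theta, lam, alpha in product(theta_grid, lambda_grid, alpha_grid):
        hyper = SMapHyperparams(theta=theta, lam=lam, alpha=alpha)
        sq_err = np.zeros(p)
        for t in range(n_trans):
            w = smap_weights(work, t, theta, include_target_in_mean)
            mask = np.ones(n_trans, dtype=bool)
            mask[t] = False
            for i in range(p):
                fit = weighted_elastic_net(
                    X_all[mask], Y_all[mask, i], w[mask], hyper, n_factor=n_time
                )
                pred = fit["intercept"] + X_all[t] @ fit["coef"]
                sq_err[i] += (Y_all[t, i] - pred) ** 2
        rmse = float(np.sqrt(sq_err / n_trans).mean())
        rows.append({"theta": theta, "lam": lam, "alpha": alpha, "loo_rmse": rmse})
    table = pd.DataFrame(rows)
    # ties toward smaller theta then larger lambda
    best_order = table.sort_values(
        ["loo_rmse", "theta", "lam"], ascending=[True, True, False]
    )
    best = best_order.iloc[0]
    return SMapHyperparams(theta=best["theta"], lam=best["lam"], alpha=best["alpha"]), table


def summarize_interactions(jac: JacobianSeries) -> pd.DataFrame:
    """Summarize each ordered taxon pair's interaction strength over time.

    Reports median and interquartile range of J[i, j, .] per ordered pair
    (i != j) and classifies pairs whose two directed IQRs both exclude zero:
    ``exploitation`` (one median positive, one negative; the predator is the
    taxon whose growth benefits), ``mutualistic-like`` (both positive) or
    ``competition-like`` (both negative).  All other pairs are labelled
    ``none``.
    """
    ids = jac.taxon_ids
    p = jac.n_taxa
    med = np.median(jac.values, axis=2)
    q1 = np.percentile(jac.values, 25, axis=2)
    q3 = np.percentile(jac.values, 75, axis=2)
    excl0 = (q1 > 0) | (q3 < 0)
    rows = []
    for i in range(p):
        for j in range(p):
            if i == j:
                continue
            label, predator = "none", ""
            if excl0[i, j] and excl0[j, i]:
                if med[i, j] > 0 and med[j, i] < 0:
                    label, predator = "exploitation", ids[i]
                elif med[i, j] < 0 and med[j, i] > 0:
                    label, predator = "exploitation", ids[j]
                elif med[i, j] > 0 and med[j, i] > 0:
                    label = "mutualistic-like"
                else:
                    label = "competition-like"
            rows.append(
                {
                    "target": ids[i],
                    "predictor": ids[j],
                    "median": med[i, j],
                    "q1": q1[i, j],
                    "q3": q3[i, j],
                    "iqr_excludes_zero": bool(excl0[i, j]),
                    "pair_type": label,
                    "predator": predator,
                }
            )
    return pd.DataFrame(rows)
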