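"""Environmental-driver and seasonal-association statistics.

Pearson screens of taxa against operational covariates with Bonferroni
control, Mantel correlation between distance matrices, one-factor PERMANOVA,
and lagged cross-correlation for seasonal phase relationships.  All
permutation tests use the add-one p-value estimator, so p is never exactly
zero, and are reproducible under a seed.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .ordination import DistanceMatrix

logger = logging.getLogger(__name__)

__all__ = ["pearson_screen", "mantel", "permanova", "cross_correlation"]


def pearson_screen(
    matrix: pd.DataFrame,
    covariates: pd.DataFrame,
    method: str = "bonferroni",
) -> pd.DataFrame:
    """Correlate every feature with every covariate across shared samples.

    Both tables are features/parameters-by-samples; the sample intersection
    is used.  Pairs with a zero-variance member are skipped (logged).  Raw
    two-sided p-values come from the t transform with n - 2 degrees of
    freedom; the Bonferroni multiplier is the number of tests actually
    performed (``method='bh'`` switches to Benjamini-Hochberg).
    """
    shared = matrix.columns.intersection(covariates.columns)
    if len(shared) == 0:
        raise ValueError("no shared samples between abundance matrix and covariates")
    if len(shared) < 3:
        raise ValueError("need at least 3 shared samples")
    x = matrix[shared]
    c = covariates[shared]
    rows = []
    for feat in x.index:
        xv = x.loc[feat].to_numpy(dtype=float)
        if xv.std() == 0:
            logger.info("pearson_screen skipped zero-variance feature %s", feat)
            continue
        for cov in c.index:
            cv = c.loc[cov].to_numpy(dtype=float)
            if cv.std() == 0:
                logger.info("pearson_screen skipped zero-variance covariate %s", cov)
                continue
            r, p = stats.pearsonr(xv, cv)
            rows.append(
                {"feature": feat, "covariate": cov, "pearson_r": r, "p_raw": p, "n": len(shared)}
            )
    table = pd.DataFrame(rows)
    if table.empty:
        return table
    m = len(table)
    if method == "bonferroni":
        table["p_adjusted"] = np.minimum(1.0, table["p_raw"] * m)
    elif method == "bh":
        order = np.argsort(table["p_raw"].to_numpy())
        adj = np.empty(m)
        ranked = table["p_raw"].to_numpy()[order] * m / (np.arange(m) + 1)
        adj[order] = np.minimum.accumulate(ranked[::-1])[::-1]
        table["p_adjusted"] = np.minimum(1.0, adj)
    else:
        raise ValueError("method must be 'bonferroni' or 'bh'")
    return table


def mantel(
    d1: DistanceMatrix,
    d2: DistanceMatrix,
    n_permutations: int = 999,
    seed: int | None = None,
) -> tuple[float, float]:
    """Mantel correlation between two distance matrices over the same samples.

    r is the Pearson correlation of the upper-triangle entries; p comes from
    simultaneously permuting rows and columns of one matrix (add-one
    estimator, two-sided on |r|).
    """
    if d1.sample_ids != d2.sample_ids:
        raise ValueError("distance matrices have mismatched sample ids")
    if d1.n < 4:
        raise ValueError("Mantel test needs at least 4 samples")
    v1 = d1.condensed()
    v2 = d2.condensed()
    r_obs = float(np.corrcoef(v1, v2)[0, 1])
    rng = np.random.default_rng(seed)
    iu = np.triu_indices(d1.n, k=1)
    count = 0
    m2 = d2.values
    for _ in range(n_permutations):
        perm = rng.permutation(d1.n)
        v2p = m2[np.ix_(perm, perm)][iu]
        r_perm = np.corrcoef(v1, v2p)[0, 1]
        if abs(r_perm) >= abs(r_obs) - 1e-12:
            count += 1
    p = (1 + count) / (1 + n_permutations)
    return r_obs, p


def _ss_within(d2_sq: np.ndarray, onehot: np.ndarray, sizes: np.ndarray) -> float:
    # sum over groups of (within-group pairwise d^2) / group size
    per_group = np.einsum("ng,nm,mg->g", onehot, d2_sq, onehot)
    return float((per_group / (2.0 * sizes)).sum())


def permanova(
    dist: DistanceMatrix,
    groups,
    n_permutations: int = 999,
    seed: int | None = None,
) -> tuple[float, float, float]:
    """One-factor permutational multivariate ANOVA on a distance matrix.

    Partitions SS_total = sum_{i<j} d_ij^2 / n into within- and
    between-group components; pseudo-F = (SS_between / (g - 1)) /
    (SS_within / (n - g)); R^2 = SS_between / SS_total.  Significance by
    random relabelling (add-one estimator).

    Returns (pseudo_F, R2, p).
    """
    labels = np.asarray(groups)
    n = dist.n
    if len(labels) != n:
        raise ValueError("group labels length must match matrix size")
    uniq, inv = np.unique(labels, return_inverse=True)
    g = len(uniq)
    if g < 2:
        raise ValueError("PERMANOVA needs at least 2 groups")
    sizes = np.bincount(inv)
    if (sizes < 2).any():
        bad = uniq[sizes < 2]
        raise ValueError(f"group(s) with fewer than 2 members: {list(bad)}")
    d2_sq = dist.values**2
    ss_total = d2_sq[np.triu_indices(n, k=1)].sum() / n

    def f_stat(inv_labels: np.ndarray) -> tuple[float, float]:
        onehot = np.zeros((n, g))
        onehot[np.arange(n), inv_labels] = 1.0
        ssw = _ss_within(d2_sq, onehot, np.bincount(inv_labels, minlength=g).astype(float))
        ssb = ss_total - ssw
        return (ssb / (g - 1)) / (ssw / (n - g)), ssb

    f_obs, ssb_obs = f_stat(inv)
    r2 = ssb_obs / ss_total
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_permutations):
        f_perm, _ = f_stat(rng.permutation(inv))
        if f_perm >= f_obs - 1e-12:
            count += 1
    p = (1 + count) / (1 + n_permutations)
    return float(f_obs), float(r2), float(p)


def cross_correlation(
    x, y, max_lag: int = 6
) -> tuple[pd.DataFrame, int, float]:
    """Lagged Pearson cross-correlation between two equal-length series.

    Both series are z-scored internally.  For each lag l in
    [-max_lag, max_lag], r(l) correlates x_t with y_{t+l} over the
    overlapping window; positive lag means y lags x (y's value l steps
    *later* is compared with x now).  The significance envelope is
    +-1.96 / sqrt(N - |l|); the best lag maximizes |r|.

    Returns (lag table, best lag, r at best lag).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D series")
    n = len(x)
    if n <= 2 * max_lag + 2:
        raise ValueError("series too short for the requested max_lag")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("constant series have no defined correlation")
    zx = (x - x.mean()) / x.std()
    zy = (y - y.mean()) / y.std()
    rows = []
    for lag in range(-max_lag, max_lag + 1):
        if lag >= 0:
            a, b = zx[: n - lag], zy[lag:]
        else:
            a, b = zx[-lag:], zy[: n + lag]
        r = float(np.corrcoef(a, b)[0, 1])
        envelope = 1.96 / np.sqrt(n - abs(lag))
        rows.append({"lag": lag, "r": r, "envelope": envelope, "n": n - abs(lag)})
    table = pd.DataFrame(rows)
    best_idx = int(table["r"].abs().idxmax())
    best_lag = int(table.loc[best_idx, "lag"])
    return table, best_lag, float(table.loc[best_idx, "r"])
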