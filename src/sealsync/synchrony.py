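"""Community synchrony statistics with permutation-test p-values.

Three bounded synchrony measures over an m-series x n-years matrix:

* Kendall's coefficient of concordance W (rank agreement over time, with
  tie correction), in [0, 1];
* the mean pairwise Pearson correlation rho-bar, in [-1, 1];
* the Loreau & de Mazancourt community statistic
  phi = Var(sum_i y_i) / (sum_i SD(y_i))^2, in [0, 1].

Each can be evaluated on raw counts or on interannual log differences
x_t - x_{t-1}, x = ln(y) (ln(y+1) when zeros are present, logged notice).
Significance is one-sided (synchrony greater than the null) from
permutations that independently shuffle each series' time order, with the
add-one rule p = (1 + #{perm >= obs}) / (n_perm + 1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

logger = logging.getLogger(__name__)

__all__ = [
    "SyncResult",
    "logdiff",
    "kendalls_w",
    "mean_pairwise_corr",
    "community_phi",
    "permutation_pvalue",
    "STATISTICS",
]


@dataclass(frozen=True)
class SyncResult:
    statistic: str
    value: float
    p_value: float
    n_permutations: int
    transform: str = "none"


def _as_matrix(matrix, min_series=2, min_times=3) -> np.ndarray:
    x = np.asarray(matrix, float)
    if x.ndim != 2:
        raise ValueError("expected an m-series x n-times matrix")
    # listwise deletion: a time point is used only if every series has it
    keep = np.all(np.isfinite(x), axis=0)
    x = x[:, keep]
    if x.shape[0] < min_series:
        raise ValueError(f"need at least {min_series} series")
    if x.shape[1] < min_times:
        raise ValueError(f"need at least {min_times} shared time points")
    return x


def logdiff(series) -> np.ndarray:
    """Interannual log change x_t - x_{t-1} with x = ln(y).

    Falls back to ln(y+1) when any zero is present (logged).  NaN gaps
    propagate: no difference is formed across a gap.  Rows of a matrix are
    differenced independently.
    """
    y = np.asarray(series, float)
    if np.any(y[np.isfinite(y)] < 0):
        raise ValueError("counts must be non-negative")
    if np.any(y[np.isfinite(y)] == 0):
        logger.info("zero counts present: using ln(y+1) for log differences")
        x = np.log(y + 1.0)
    else:
        x = np.log(y)
    return np.diff(x, axis=-1)


def kendalls_w(matrix) -> float:
    """Kendall's W from rank sums over time points, tie-corrected.

    m series rank n time points; W = 1 for identical rankings, 0 for no
    concordance.  Fully tied (constant) series enter through the tie
    correction rather than being dropped.
    """
    x = _as_matrix(matrix)
    m, n = x.shape
    ranks = np.vstack([rankdata(row) for row in x])
    rank_sums = ranks.sum(axis=0)
    s = np.sum((rank_sums - rank_sums.mean()) ** 2)
    ties = 0.0
    for row in x:
        _, counts = np.unique(row, return_counts=True)
        ties += np.sum(counts**3 - counts)
    denom = m**2 * (n**3 - n) - m * ties
    if denom <= 0:
        return 1.0  # every series fully tied: perfect (degenerate) agreement
    return float(12.0 * s / denom)


def mean_pairwise_corr(matrix) -> float:
    """Mean of the m(m-1)/2 pairwise Pearson correlations."""
    x = _as_matrix(matrix)
    sds = x.std(axis=1, ddof=0)
    flat = np.flatnonzero(sds == 0)
    if flat.size:
        raise ValueError(f"constant series at row(s) {flat.tolist()}")
    c = np.corrcoef(x)
    iu = np.triu_indices_from(c, k=1)
    return float(c[iu].mean())


def community_phi(matrix) -> float:
    """Loreau & de Mazancourt phi = Var(aggregate) / (sum of SDs)^2."""
    x = _as_matrix(matrix)
    sds = x.std(axis=1, ddof=1)
    denom = sds.sum() ** 2
    if denom == 0:
        raise ValueError("phi undefined: all series constant")
    return float(np.var(x.sum(axis=0), ddof=1) / denom)


STATISTICS = {
    "kendalls_w": kendalls_w,
    "mean_pairwise_corr": mean_pairwise_corr,
    "community_phi": community_phi,
}


def permutation_pvalue(matrix, statistic, n_perm: int = 4999, seed: int = 0,
                       transform: str = "none",
                       scheme: str = "shuffle") -> SyncResult:
    """One-sided permutation test of a synchrony statistic.

    Each permutation independently reshuffles every series' time order
    (``scheme="shuffle"``) or applies independent cyclic shifts
    (``scheme="cyclic"``, robust to autocorrelation).
    ``transform="logdiff"`` differences the matrix first and permutes the
    differenced series (the statistic's direct input).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if callable(statistic):
        stat_fn, stat_name = statistic, getattr(statistic, "__name__", "custom")
    else:
        stat_fn, stat_name = STATISTICS[statistic], statistic
    x = np.asarray(matrix, float)
    if transform == "logdiff":
        x = logdiff(x)
    x = _as_matrix(x)
    rng = np.random.default_rng(seed)
    observed = stat_fn(x)
    m, n = x.shape
    count = 0
    perm = x.copy()
    for _ in range(n_perm):
        if scheme == "shuffle":
            for i in range(m):
                perm[i] = x[i, rng.permutation(n)]
        elif scheme == "cyclic":
            for i in range(m):
                perm[i] = np.roll(x[i], rng.integers(n))
        else:
            raise ValueError(f"unknown permutation scheme {scheme!r}")
        if stat_fn(perm) >= observed:
            count += 1
    p = (1.0 + count) / (n_perm + 1.0)
    return SyncResult(statistic=stat_name, value=float(observed), p_value=p,
                      n_permutations=n_perm, transform=transform)
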