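"""PERMDISP: permutation test of homogeneity of multivariate dispersions.

Group dispersion is the average distance of group members to their group
centroid in the principal-coordinate embedding of the (Euclidean) distance
matrix. Axes with negative eigenvalues — absent for Euclidean input, present
for semi-metric distances — are tracked separately and subtract from squared
distances, following the standard correction:

    d_i = sqrt(max(d2_real - d2_imaginary, 0))

Heterogeneity between groups is tested with the one-way ANOVA F statistic on
the centroid distances, with a permutation p-value obtained by reshuffling
the distances across groups.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

__all__ = ["PermdispResult", "permdisp", "standardize_jointly"]


@dataclass
class PermdispResult:
    group_labels: list
    centroid_distances: pd.Series  # per-site distance to own-group centroid
    group_means: pd.Series  # per-group average distance
    f_stat: float
    p_perm: float
    n_perm: int
    seed: int


def standardize_jointly(X: pd.DataFrame) -> pd.DataFrame:
    """Z-score variables across all groups together (the PERMDISP input
    contract: transformed, jointly standardized variables)."""
    sd = X.std(axis=0, ddof=1)
    keep = sd[sd > 0].index
    return (X[keep] - X[keep].mean(axis=0)) / sd[keep]


def _anova_f(dists: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    n = dists.size
    grand = dists.mean()
    ss_between = 0.0
    ss_within = 0.0
    for g in range(n_groups):
        vals = dists[codes == g]
        ss_between += vals.size * (vals.mean() - grand) ** 2
        ss_within += ((vals - vals.mean()) ** 2).sum()
    df1 = n_groups - 1
    df2 = n - n_groups
    if ss_within <= 0.0:
        return np.inf if ss_between > 0 else 0.0
    return (ss_between / df1) / (ss_within / df2)


def permdisp(
    X: pd.DataFrame | np.ndarray,
    groups,
    n_perm: int = 999,
    seed: int = 0,
    distances: np.ndarray | None = None,
) -> PermdispResult:
    """Test equality of multivariate dispersion between groups.

    Parameters
    ----------
    X : site-by-variable table (Euclidean geometry) — ignored if a
        precomputed square distance matrix is passed via ``distances``.
    groups : per-site group labels; at least two groups of at least two sites.
    n_perm : label permutations for the p-value (resolution 1/(n_perm+1)).
    """
    if isinstance(X, pd.DataFrame):
        index = X.index
        values = X.to_numpy(dtype=float)
    else:
        values = np.asarray(X, dtype=float)
        index = pd.RangeIndex(values.shape[0])
    groups = pd.Series(np.asarray(groups), index=index)
    labels, codes = np.unique(groups.to_numpy(), return_inverse=True)
    if labels.size < 2:
        raise ValueError("need at least two groups")
    counts = np.bincount(codes)
    if counts.min() < 2:
        small = labels[counts < 2].tolist()
        raise ValueError(f"groups with a single site: {small}")

    dmat = squareform(pdist(values)) if distances is None else np.asarray(distances, float)
    n = dmat.shape[0]
    if not np.any(dmat > 0):
        raise ValueError("zero total variance: all sites identical")

    # principal-coordinate embedding (Gower-centered) with signed axes
    a = -0.5 * dmat**2
    centering = np.eye(n) - np.ones((n, n)) / n
    g = centering @ a @ centering
    eigval, eigvec = np.linalg.eigh((g + g.T) / 2.0)
    tol = 1e-9 * np.abs(eigval).max()
    pos, neg = eigval > tol, eigval < -tol
    coords_real = eigvec[:, pos] * np.sqrt(eigval[pos])
    coords_imag = eigvec[:, neg] * np.sqrt(-eigval[neg])

    dists = np.empty(n)
    for gcode in range(labels.size):
        members = codes == gcode
        c_real = coords_real[members].mean(axis=0)
        c_imag = coords_imag[members].mean(axis=0)
        d2_real = ((coords_real[members] - c_real) ** 2).sum(axis=1)
        d2_imag = ((coords_imag[members] - c_imag) ** 2).sum(axis=1)
        dists[members] = np.sqrt(np.maximum(d2_real - d2_imag, 0.0))

    f_obs = _anova_f(dists, codes, labels.size)
    rng = np.random.default_rng(seed)
    count_ge = 0
    for _ in range(n_perm):
        f_perm = _anova_f(rng.permutation(dists), codes, labels.size)
        if f_perm >= f_obs:
            count_ge += 1
    p = (1.0 + count_ge) / (1.0 + n_perm)

    series = pd.Series(dists, index=index, name="distance_to_centroid")
    means = series.groupby(groups).mean()
    return PermdispResult(
        group_labels=labels.tolist(),
        centroid_distances=series,
        group_means=means,
        f_stat=float(f_obs),
        p_perm=float(p),
        n_perm=n_perm,
        seed=seed,
    )
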