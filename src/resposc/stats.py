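"""Group-level inference machinery.

* :func:`cluster_test` - dependent-sample cluster-based permutation test:
  a paired t test at every cell of a (time / time x frequency / ... x
  channel) grid, thresholded at a sample-level p, suprathreshold cells
  clustered under lattice adjacency (plus an optional channel neighbour
  graph), cluster statistic = sum of t values, null distribution from
  sign-flipping participants' difference grids, two-tailed.
* :func:`fdr_bh` - Benjamini-Hochberg step-up mask.
* :func:`robust_regress` - iteratively reweighted least squares with
  bisquare weights (tuning constant 4.685), reporting slope, intercept,
  weighted R^2, and an F test for the slope with (1, n-2) df.
* :func:`coupling_reactivation` - the coupling-strength -> memory
  reactivation analysis: robust regression per channel, FDR across
  channels.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats as sp_stats

logger = logging.getLogger(__name__)

__all__ = [
    "ClusterTestResult",
    "RegressionResult",
    "cluster_test",
    "fdr_bh",
    "robust_regress",
    "coupling_reactivation",
]


@dataclass
class ClusterTestResult:
    t_map: np.ndarray
    threshold: float
    cluster_labels: np.ndarray          # integer labels, 0 = background
    cluster_stats: np.ndarray           # summed t per cluster (signed)
    cluster_p: np.ndarray               # Monte-Carlo p per cluster
    n_permutations: int
    alpha: float

    @property
    def significant_mask(self) -> np.ndarray:
        mask = np.zeros_like(self.cluster_labels, dtype=bool)
        for lab, p in zip(range(1, len(self.cluster_stats) + 1), self.cluster_p):
            if p <= self.alpha:
                mask |= self.cluster_labels == lab
        return mask


def _label_clusters(
    suprathreshold: np.ndarray,
    channel_adjacency: np.ndarray | None,
    channel_axis: int | None,
) -> tuple[np.ndarray, int]:
    """Connected components of a boolean grid.

    Lattice adjacency along every axis; if ``channel_axis`` is given, that
    axis is connected through ``channel_adjacency`` (boolean neighbour
    matrix) instead of linear order.
    """
    if channel_axis is None:
        structure = ndimage.generate_binary_structure(suprathreshold.ndim, 1)
        return ndimage.label(suprathreshold, structure=structure)
    # label each channel's sub-grid separately, then merge labels of
    # co-active cells on neighbouring channels via union-find
    mask = np.moveaxis(suprathreshold, channel_axis, 0)
    n_ch = mask.shape[0]
    labels = np.zeros(mask.shape, dtype=int)
    offset = 0
    for c in range(n_ch):
        if mask.ndim > 1:
            structure = ndimage.generate_binary_structure(mask.ndim - 1, 1)
            lab, k = ndimage.label(mask[c], structure=structure)
            labels[c] = np.where(lab > 0, lab + offset, 0)
        else:
            k = int(mask[c])
            labels[c] = offset + 1 if mask[c] else 0
        offset += k

    parent = list(range(offset + 1))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    adj = np.asarray(channel_adjacency, dtype=bool)
    for a in range(n_ch):
        for b in range(a + 1, n_ch):
            if not adj[a, b]:
                continue
            both = (labels[a] > 0) & (labels[b] > 0)
            if not np.any(both):
                continue
            pairs = set(zip(np.atleast_1d(labels[a])[np.atleast_1d(both)].tolist(),
                            np.atleast_1d(labels[b])[np.atleast_1d(both)].tolist()))
            for la, lb in pairs:
                ra, rb = find(la), find(lb)
                if ra != rb:
                    parent[rb] = ra

    roots = np.array([find(x) for x in range(offset + 1)])
    uniq = np.unique(roots[1:]) if offset else np.array([], dtype=int)
    remap = np.zeros(offset + 1, dtype=int)
    remap[uniq] = np.arange(1, uniq.size + 1)
    out = remap[roots[labels]]
    return np.moveaxis(out, 0, channel_axis), int(uniq.size)


def _max_cluster_stat(
    t_map: np.ndarray,
    threshold: float,
    channel_adjacency: np.ndarray | None,
    channel_axis: int | None,
) -> float:
    best = 0.0
    for sign in (1.0, -1.0):
        mask = sign * t_map > threshold
        if not mask.any():
            continue
        labels, n = _label_clusters(mask, channel_adjacency, channel_axis)
        if n:
            sums = ndimage.sum_labels(np.abs(t_map), labels, index=np.arange(1, n + 1))
            best = max(best, float(np.max(sums)))
    return best


def cluster_test(
    condition_a: np.ndarray,
    condition_b: np.ndarray,
    n_permutations: int = 1000,
    threshold_p: float = 0.05,
    alpha: float = 0.05,
    channel_adjacency: np.ndarray | None = None,
    channel_axis: int | None = None,
    seed: int | np.random.Generator | None = 0,
) -> ClusterTestResult:
    """Dependent-sample cluster permutation test on paired grids.

    ``condition_a`` and ``condition_b`` are (n_participants, *grid) arrays.
    Cluster p-values are ``(1 + #{permutation max >= |observed sum|}) /
    (n_permutations + 1)``, where the permutation maximum is taken over
    both polarities (two-tailed).
    """
    a = np.asarray(condition_a, dtype=float)
    b = np.asarray(condition_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("condition grids must have identical shapes")
    n = a.shape[0]
    if n < 2:
        raise ValueError("need at least 2 participants")
    if n_permutations < 100:
        warnings.warn(f"only {n_permutations} permutations: p-value resolution is coarse",
                      stacklevel=2)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    diff = a - b
    grid_shape = diff.shape[1:]
    flat = diff.reshape(n, -1)

    def t_of(signed: np.ndarray) -> np.ndarray:
        mean = signed.mean(axis=0)
        sd = signed.std(axis=0, ddof=1)
        sd = np.where(sd == 0, np.inf, sd)
        return mean / (sd / np.sqrt(n))

    threshold = float(sp_stats.t.ppf(1 - threshold_p / 2, df=n - 1))
    t_obs = t_of(flat).reshape(grid_shape)

    # observed clusters, both polarities, jointly numbered
    labels = np.zeros(grid_shape, dtype=int)
    cluster_sums: list[float] = []
    for sign in (1.0, -1.0):
        mask = sign * t_obs > threshold
        lab, k = _label_clusters(mask, channel_adjacency, channel_axis)
        for j in range(1, k + 1):
            cells = lab == j
            labels[cells] = len(cluster_sums) + 1
            cluster_sums.append(float(t_obs[cells].sum()))

    null_max = np.empty(n_permutations)
    flips = rng.integers(0, 2, size=(n_permutations, n)) * 2 - 1
    for p in range(n_permutations):
        t_perm = t_of(flips[p][:, None] * flat).reshape(grid_shape)
        null_max[p] = _max_cluster_stat(t_perm, threshold, channel_adjacency, channel_axis)

    cluster_p = np.array([
        (1 + np.sum(null_max >= abs(s))) / (n_permutations + 1) for s in cluster_sums
    ])
    logger.info("cluster test: %d clusters, min p = %s",
                len(cluster_sums), cluster_p.min() if cluster_sums else None)
    return ClusterTestResult(
        t_map=t_obs, threshold=threshold, cluster_labels=labels,
        cluster_stats=np.asarray(cluster_sums), cluster_p=cluster_p,
        n_permutations=n_permutations, alpha=alpha,
    )


def fdr_bh(p_values: np.ndarray, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up significance mask."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    mask, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return mask


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    f_stat: float
    df: tuple[int, int]
    p_value: float
    weights: np.ndarray


def robust_regress(x: np.ndarray, y: np.ndarray, max_iter: int = 50, tol: float = 1e-8) -> RegressionResult:
    """Robust simple regression (IRLS, bisquare weights, c = 4.685).

    R^2 is computed on the weighted fit (weighted residual vs total sum of
    squares about the weighted mean); the F statistic tests slope != 0
    with (1, n-2) degrees of freedom.
    """
    import statsmodels.api as sm

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    n = x.size
    if n < 4:
        raise ValueError("robust regression needs at least 4 points")
    if np.ptp(x) == 0:
        raise ValueError("x has zero variance")
    model = sm.RLM(y, sm.add_constant(x), M=sm.robust.norms.TukeyBiweight(c=4.685))
    fit = model.fit(maxiter=max_iter, tol=tol, conv="coefs")
    intercept, slope = fit.params
    w = np.asarray(fit.weights, dtype=float)
    resid = y - (intercept + slope * x)
    if np.max(np.abs(resid)) <= 1e-10 * max(1.0, float(np.max(np.abs(y)))):
        w = np.ones_like(w)  # exact fit: the weight function is 0/0, all points are inliers
    ybar_w = np.average(y, weights=w) if w.sum() > 0 else y.mean()
    ss_res = float(np.sum(w * resid**2))
    ss_tot = float(np.sum(w * (y - ybar_w) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
    df = (1, n - 2)
    if np.isfinite(r2) and r2 < 1:
        f = r2 / (1 - r2) * df[1]
        p = float(sp_stats.f.sf(f, *df))
    else:
        f, p = np.inf, 0.0
    return RegressionResult(float(slope), float(intercept), float(r2), float(f), df, p, w)


def coupling_reactivation(
    vector_lengths: pd.DataFrame,
    scores: pd.DataFrame,
    q: float = 0.05,
) -> pd.DataFrame:
    """Robust regression of reactivation score on coupling strength per channel.

    ``vector_lengths``: columns participant, channel, vector_length.
    ``scores``: columns participant, score. Participants missing a score
    are dropped with a warning. Returns one row per channel with slope,
    intercept, R^2, F, p, and the FDR mask across channels.
    """
    merged = vector_lengths.merge(scores[["participant", "score"]], on="participant", how="left")
    missing = merged.loc[merged["score"].isna(), "participant"].unique()
    if missing.size:
        warnings.warn(f"dropping participants without scores: {sorted(missing)}", stacklevel=2)
        merged = merged.dropna(subset=["score"])
    rows = []
    for channel, group in merged.groupby("channel", sort=True):
        res = robust_regress(group["vector_length"].to_numpy(), group["score"].to_numpy())
        rows.append(dict(channel=channel, slope=res.slope, intercept=res.intercept,
                         r_squared=res.r_squared, f_stat=res.f_stat, p_value=res.p_value,
                         n=len(group)))
    table = pd.DataFrame(rows)
    table["significant"] = fdr_bh(table["p_value"].to_numpy(), q=q)
    return table
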