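"""Group statistics: cluster-based permutation tests and scalar comparisons.

Electrode-space group comparisons use a nonparametric cluster-based
permutation test: per-electrode unpaired t statistics (optionally
covariate-adjusted) are thresholded at an uncorrected 5% level,
suprathreshold electrodes with at least two adjacent members form
clusters, the maximum |t| within each cluster is carried forward, and
cluster significance comes from a permutation null of the largest
cluster statistic (Monte Carlo, 1000 draws by default).

Comodulogram speech-vs-baseline comparisons use the dependent-samples
variant: per-cell paired t, 4-neighbor grid adjacency, sign-flip
permutations; grid-cell clusters may have size 1 (the two-member rule is
an electrode-space constraint).

Covariate adjustment follows the Freedman-Lane scheme: the covariate is
regressed out of both the data and the group indicator, and permutations
shuffle the covariate-residualized data.  The literal alternative of
shuffling the covariate labels themselves is available via
``covariate_scheme="shuffle-covariate"`` for sensitivity analysis.
"""
from __future__ import annotations

import numpy as np
from scipy import ndimage, stats
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .containers import ClusterResult, GroupComparison


# ---------------------------------------------------------------------------
# scalar comparisons
# ---------------------------------------------------------------------------

def group_t_pooled(x: np.ndarray, y: np.ndarray, variable: str = "") -> GroupComparison:
    """Student's pooled two-sample t with pairwise-complete deletion.

    Missing values are dropped per variable, so df = n1 + n2 - 2 after
    exclusion.  Effect size eta^2 = t^2 / (t^2 + df).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x, y = x[np.isfinite(x)], y[np.isfinite(y)]
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need >= 2 non-missing values per group")
    res = stats.ttest_ind(x, y, equal_var=True)
    df = len(x) + len(y) - 2
    t = float(res.statistic)
    if not np.isfinite(t):
        raise ValueError("zero pooled variance")
    return GroupComparison(
        variable=variable,
        mean_x=float(x.mean()), sd_x=float(x.std(ddof=1)), n_x=len(x),
        mean_y=float(y.mean()), sd_y=float(y.std(ddof=1)), n_y=len(y),
        statistic=t, df=df, p=float(res.pvalue),
        eta_sq=t**2 / (t**2 + df), kind="t",
    )


def ks_two_sample(x: np.ndarray, y: np.ndarray, variable: str = "") -> GroupComparison:
    """Two-sample Kolmogorov-Smirnov D with asymptotic p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x, y = x[np.isfinite(x)], y[np.isfinite(y)]
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need >= 2 non-missing values per group")
    res = stats.ks_2samp(x, y, method="asymp")
    return GroupComparison(
        variable=variable,
        mean_x=float(x.mean()), sd_x=float(x.std(ddof=1)), n_x=len(x),
        mean_y=float(y.mean()), sd_y=float(y.std(ddof=1)), n_y=len(y),
        statistic=float(res.statistic), df=None, p=float(res.pvalue), kind="KS",
    )


# ---------------------------------------------------------------------------
# electrode-space cluster permutation test
# ---------------------------------------------------------------------------

def _vector_t_against(g: np.ndarray, Y: np.ndarray, df: int) -> np.ndarray:
    """t statistic of the regression slope of each column of Y on g."""
    gg = float(g @ g)
    b = (g @ Y) / gg
    rss = np.einsum("ij,ij->j", Y, Y) - b**2 * gg
    se = np.sqrt(np.maximum(rss, 1e-300) / df / gg)
    return b / se


def _clusters_from_mask(
    mask: np.ndarray, adjacency: csr_matrix, min_size: int
) -> list[np.ndarray]:
    idx = np.flatnonzero(mask)
    if len(idx) == 0:
        return []
    sub = adjacency[np.ix_(idx, idx)]
    n_comp, labels = connected_components(sub, directed=False)
    return [
        idx[labels == c]
        for c in range(n_comp)
        if np.sum(labels == c) >= min_size
    ]


def electrode_cluster_test(
    values: np.ndarray,
    groups: np.ndarray,
    adjacency: csr_matrix,
    covariate: np.ndarray | None = None,
    n_perm: int = 1000,
    alpha: float = 0.05,
    cluster_alpha: float = 0.05,
    min_cluster_size: int = 2,
    rng: np.random.Generator | None = None,
    covariate_scheme: str = "freedman-lane",
) -> ClusterResult:
    """Cluster-based permutation comparison of two groups over electrodes.

    ``values`` is (participants, electrodes); ``groups`` a label array
    with exactly two levels; ``adjacency`` the electrode neighbor graph.
    With a covariate, per-electrode statistics are covariate-adjusted
    regression t values (df = n - 3).
    """
    rng = np.random.default_rng() if rng is None else rng
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    uniq = np.unique(groups)
    if len(uniq) != 2 or min(np.sum(groups == u) for u in uniq) < 2:
        raise ValueError("need two groups with >= 2 participants each")
    n, n_elec = values.shape
    g = (groups == uniq[0]).astype(float)
    g -= g.mean()

    if covariate is not None:
        cov = np.asarray(covariate, dtype=float)
        if len(cov) != n:
            raise ValueError("covariate not aligned to participants")
        Z = np.column_stack([np.ones(n), cov])
        H = Z @ np.linalg.solve(Z.T @ Z, Z.T)
        R = values - H @ values  # covariate-residualized data
        g_t = g - H @ g  # covariate-residualized group indicator
        df = n - 3
    else:
        R = values - values.mean(axis=0)
        g_t = g
        df = n - 2

    t_crit = stats.t.ppf(1 - alpha / 2, df)
    t_obs = _vector_t_against(g_t, R, df)
    clusters = _clusters_from_mask(np.abs(t_obs) > t_crit, adjacency, min_cluster_size)
    cluster_stats = [float(np.max(np.abs(t_obs[c]))) for c in clusters]

    null = np.zeros(n_perm)
    for s in range(n_perm):
        if covariate is not None and covariate_scheme == "shuffle-covariate":
            cov_p = rng.permutation(cov)
            Zp = np.column_stack([np.ones(n), cov_p])
            Hp = Zp @ np.linalg.solve(Zp.T @ Zp, Zp.T)
            Rp = values - Hp @ values
            gp = g - Hp @ g
            t_p = _vector_t_against(gp, Rp, df)
        else:
            perm = rng.permutation(n)
            Rp = R[perm]
            if covariate is not None:
                # Freedman-Lane: refit the reduced model on the permuted
                # residuals so the permuted statistic matches the observed
                # one's degrees of freedom
                Rp = Rp - H @ Rp
            t_p = _vector_t_against(g_t, Rp, df)
        cl_p = _clusters_from_mask(np.abs(t_p) > t_crit, adjacency, min_cluster_size)
        null[s] = max((np.max(np.abs(t_p[c])) for c in cl_p), default=0.0)

    out = [
        {
            "members": c.tolist(),
            "stat": cs,
            "p": float((1 + np.sum(null >= cs)) / (n_perm + 1)),
        }
        for c, cs in zip(clusters, cluster_stats)
    ]
    return ClusterResult(
        clusters=out,
        n_permutations=n_perm,
        alpha=cluster_alpha,
        test="independent",
        covariate_used=covariate is not None,
        t_obs=t_obs,
    )


# ---------------------------------------------------------------------------
# comodulogram-cell cluster permutation test (paired)
# ---------------------------------------------------------------------------

def pac_cluster_test(
    speech_mi: np.ndarray,
    baseline_mi: np.ndarray,
    n_perm: int = 1000,
    alpha: float = 0.05,
    cluster_alpha: float = 0.05,
    rng: np.random.Generator | None = None,
) -> ClusterResult:
    """Paired cluster permutation test of speech vs baseline comodulograms.

    Inputs are (participants, n_phase, n_amp) MI grids.  Per-cell paired
    t values are thresholded, suprathreshold cells form clusters under
    4-neighbor grid adjacency (minimum size 1), and the null randomly
    flips each participant's condition sign.
    """
    rng = np.random.default_rng() if rng is None else rng
    speech_mi = np.asarray(speech_mi, dtype=float)
    baseline_mi = np.asarray(baseline_mi, dtype=float)
    if speech_mi.shape != baseline_mi.shape:
        raise ValueError("speech and baseline grids must be paired (same shape)")
    diff = speech_mi - baseline_mi
    n = diff.shape[0]
    if n < 2:
        raise ValueError("paired test needs >= 2 participants")
    df = n - 1
    t_crit = stats.t.ppf(1 - alpha / 2, df)

    def grid_t(d: np.ndarray) -> np.ndarray:
        m = np.nanmean(d, axis=0)
        se = np.nanstd(d, axis=0, ddof=1) / np.sqrt(n)
        with np.errstate(invalid="ignore", divide="ignore"):
            return m / se

    def grid_clusters(t: np.ndarray) -> list[np.ndarray]:
        mask = np.abs(t) > t_crit
        labels, n_lab = ndimage.label(mask)  # 4-neighbor connectivity
        return [np.argwhere(labels == k) for k in range(1, n_lab + 1)]

    t_obs = grid_t(diff)
    clusters = grid_clusters(t_obs)
    cluster_stats = [
        float(np.max(np.abs(t_obs[c[:, 0], c[:, 1]]))) for c in clusters
    ]

    null = np.zeros(n_perm)
    for s in range(n_perm):
        signs = rng.choice([-1.0, 1.0], size=n)[:, None, None]
        t_p = grid_t(diff * signs)
        cl = grid_clusters(t_p)
        null[s] = max(
            (np.max(np.abs(t_p[c[:, 0], c[:, 1]])) for c in cl), default=0.0
        )

    out = [
        {
            "members": [tuple(map(int, cell)) for cell in c],
            "stat": cs,
            "p": float((1 + np.sum(null >= cs)) / (n_perm + 1)),
        }
        for c, cs in zip(clusters, cluster_stats)
    ]
    return ClusterResult(
        clusters=out,
        n_permutations=n_perm,
        alpha=cluster_alpha,
        test="dependent",
        t_obs=t_obs,
    )
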