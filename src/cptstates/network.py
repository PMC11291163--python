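"""State-conditioned pairwise correlation structure.

For each decoded behavioral state, all frames assigned to that state are
collapsed and pairwise Pearson correlations computed between neurons
(diagonal zeroed).  Pairs are classed positive / negative / non-significant
against a per-frame sign-flip permutation null; correlation strength versus
inter-neuronal distance is fit with an exponential decay y = A·exp(k·x)
(bootstrap CIs, z-tests between states); and K-means on the correlation
profiles characterizes cluster sizes, spatial compactness and intra-/inter-
cluster coupling changes across states.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .core import CalciumTraceSet


def state_correlation_matrix(ts: CalciumTraceSet, state_mask: np.ndarray) -> np.ndarray:
    """Pearson correlation over the frames of one state, diagonal zeroed.

    Neurons with zero variance within the state get NaN rows/columns (their
    pairs are undefined) and a warning.
    """
    state_mask = np.asarray(state_mask, dtype=bool)
    if state_mask.sum() < 2:
        raise ValueError("need at least 2 frames in the state")
    x = ts.traces[:, state_mask]
    if x.shape[0] < 2:
        raise ValueError("need at least 2 neurons")
    sd = x.std(axis=1)
    dead = sd == 0
    if dead.any():
        warnings.warn(f"{int(dead.sum())} zero-variance neuron(s) in state; pairs set NaN")
    with np.errstate(invalid="ignore", divide="ignore"):
        mat = np.corrcoef(x)
    mat[dead, :] = np.nan
    mat[:, dead] = np.nan
    np.fill_diagonal(mat, 0.0)
    return mat


def cell_max_correlations(matrix: np.ndarray) -> pd.DataFrame:
    """Per cell, the strongest positive and strongest negative partner value.

    Cells lacking any positive (or negative) partner get NaN in that column.
    """
    n = matrix.shape[0]
    if n < 2:
        raise ValueError("need at least 2 cells")
    m = matrix.copy().astype(float)
    np.fill_diagonal(m, np.nan)
    pos = np.where(m > 0, m, np.nan)
    neg = np.where(m < 0, m, np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        return pd.DataFrame(
            {
                "max_positive": np.nanmax(pos, axis=1),
                "max_negative": np.nanmin(neg, axis=1),
            }
        )


def compare_state_distributions(values_a, values_b):
    """Two-sample KS comparison of correlation-value distributions.

    Returns (D, p, ecdf_table); the table carries both empirical CDFs on the
    pooled support for plotting cumulative probability curves.
    """
    a = np.sort(np.asarray(values_a, dtype=float))
    b = np.sort(np.asarray(values_b, dtype=float))
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be nonempty")
    d, p = stats.ks_2samp(a, b)
    support = np.union1d(a, b)
    ecdf = pd.DataFrame(
        {
            "value": support,
            "cdf_a": np.searchsorted(a, support, side="right") / len(a),
            "cdf_b": np.searchsorted(b, support, side="right") / len(b),
        }
    )
    return float(d), float(p), ecdf


def classify_pair_correlations(
    ts: CalciumTraceSet,
    state_mask: np.ndarray,
    n_perm: int = 10000,
    seed: int = 0,
    alpha: float = 0.05,
):
    """Classify pairs by a per-frame sign-flip permutation null.

    Each iteration multiplies one member of every pair by a fresh per-frame
    random ±1 vector and recomputes the pair correlation; a pair is
    significant-positive when its observed r exceeds its 1−α/2 null
    percentile, significant-negative below the α/2 percentile.  For
    within-state z-scored traces the flipped correlation has the closed form
    (Σ_t s_t x_it x_jt / T) / sqrt(1 − m_i²) with m_i = Σ_t s_t x_it / T,
    which lets the null be accumulated as exceedance counts without storing
    n_perm full matrices.

    Returns
    -------
    classes : (n, n) array of {"positive", "negative", "nonsignificant"}
    observed : the state correlation matrix
    """
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives unstable null percentiles")
    state_mask = np.asarray(state_mask, dtype=bool)
    observed = state_correlation_matrix(ts, state_mask)
    x = ts.traces[:, state_mask]
    sd = x.std(axis=1)
    ok = sd > 0
    xz = np.zeros_like(x)
    xz[ok] = (x[ok] - x[ok].mean(axis=1, keepdims=True)) / sd[ok][:, None]
    n, T = xz.shape
    rng = np.random.default_rng(seed)
    ge = np.zeros((n, n), dtype=np.int64)  # null >= observed
    le = np.zeros((n, n), dtype=np.int64)
    obs = np.nan_to_num(observed)
    for _ in range(n_perm):
        s = rng.integers(0, 2, size=T) * 2.0 - 1.0
        m = (xz @ s) / T
        cross = ((xz * s) @ xz.T) / T
        null = cross / np.sqrt(np.maximum(1.0 - m[:, None] ** 2, 1e-12))
        ge += null >= obs
        le += null <= obs
    classes = np.full((n, n), "nonsignificant", dtype=object)
    half = alpha / 2.0
    classes[(ge / n_perm) < half] = "positive"
    classes[(le / n_perm) < half] = "negative"
    classes[np.isnan(observed)] = "undefined"
    np.fill_diagonal(classes, "self")
    return classes, observed


@dataclass
class DecayFit:
    """Exponential decay fit y = A·exp(k·x) of correlation vs distance."""

    A: float
    k: float
    A_ci: tuple
    k_ci: tuple
    A_se: float
    k_se: float
    n_pairs: int
    category: str
    sign: int  # +1 fitted on r, -1 fitted on |r| of negative pairs
    converged: bool

    def to_dict(self) -> dict:
        d = {f: getattr(self, f) for f in self.__dataclass_fields__}
        d["A_ci"], d["k_ci"] = list(self.A_ci), list(self.k_ci)
        return d


def _fit_exp(x: np.ndarray, y: np.ndarray):
    """Nonlinear least squares for A·exp(kx); log-linear start and fallback."""
    pos = y > 1e-12
    if pos.sum() >= 2:
        slope, intercept = np.polyfit(x[pos], np.log(y[pos]), 1)
        p0 = (float(np.exp(intercept)), float(slope))
    else:
        p0 = (max(float(np.mean(y)), 1e-6), -1e-3)
    try:
        popt, _ = optimize.curve_fit(
            lambda d, A, k: A * np.exp(k * d), x, y, p0=p0, maxfev=5000
        )
        return float(popt[0]), float(popt[1]), True
    except (RuntimeError, optimize.OptimizeWarning):
        return p0[0], p0[1], False


def fit_correlation_decay(
    pair_r: np.ndarray,
    pair_d_um: np.ndarray,
    category: str = "positive",
    n_boot: int = 1000,
    seed: int = 0,
) -> DecayFit:
    """Fit correlation strength vs distance with bootstrap pair resampling.

    Negative-category values are fitted on |r| (A·exp(kx) with A>0 is
    ill-posed for negative y) and the sign recorded for reporting.  95% CIs
    and SEs come from percentile bootstrap over pairs.
    """
    r = np.asarray(pair_r, dtype=float)
    d = np.asarray(pair_d_um, dtype=float)
    if len(r) < 10:
        raise ValueError("need at least 10 pairs for a decay fit")
    sign = -1 if category == "negative" else 1
    y = np.abs(r) if sign < 0 else r
    A, k, conv = _fit_exp(d, y)
    rng = np.random.default_rng(seed)
    boots = np.empty((n_boot, 2))
    for b in range(n_boot):
        idx = rng.integers(0, len(y), size=len(y))
        boots[b] = _fit_exp(d[idx], y[idx])[:2]
    lo, hi = np.percentile(boots, [2.5, 97.5], axis=0)
    se = boots.std(axis=0, ddof=1)
    return DecayFit(
        A=A,
        k=k,
        A_ci=(float(lo[0]), float(hi[0])),
        k_ci=(float(lo[1]), float(hi[1])),
        A_se=float(se[0]),
        k_se=float(se[1]),
        n_pairs=len(y),
        category=category,
        sign=sign,
        converged=conv,
    )


def compare_decay_rates(fit1: DecayFit, fit2: DecayFit):
    """z-test for independent decay constants: z = (k1−k2)/√(se1²+se2²)."""
    denom = np.hypot(fit1.k_se, fit2.k_se)
    if denom == 0:
        raise ValueError("zero combined standard error")
    z = (fit1.k - fit2.k) / denom
    return float(z), float(2.0 * stats.norm.sf(abs(z)))


def cluster_states(
    matrix: np.ndarray, k_grid=range(2, 7), seed: int = 0
):
    """K-means on correlation-profile rows; K chosen by mean silhouette.

    Returns (chosen K, assignments, silhouette table).  Identical rows
    (degenerate geometry) collapse to a single-cluster flag.
    """
    k_grid = list(k_grid)
    n = matrix.shape[0]
    if n < max(k_grid) + 1:
        raise ValueError("need more cells than the largest K in the grid")
    feats = np.nan_to_num(np.asarray(matrix, dtype=float))
    if np.allclose(feats, feats[0]):
        return 1, np.zeros(n, dtype=int), pd.DataFrame({"k": [1], "silhouette": [np.nan]})
    rows, best = [], None
    for k in k_grid:
        km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(feats)
        sil = float(silhouette_score(feats, km.labels_))
        rows.append({"k": k, "silhouette": sil})
        if best is None or sil > best[0]:
            best = (sil, k, km.labels_)
    return best[1], best[2], pd.DataFrame(rows)


def cluster_metrics(assignments: np.ndarray, centroids_um: np.ndarray) -> pd.DataFrame:
    """Per-cluster member count and spatial compactness.

    Compactness is the mean Euclidean distance (µm) of member cells to the
    cluster's spatial centroid; singleton clusters report 0 and are flagged.
    """
    assignments = np.asarray(assignments)
    centroids_um = np.asarray(centroids_um, dtype=float)
    if len(assignments) != len(centroids_um):
        raise ValueError("assignments and centroids must align")
    rows = []
    for c in np.unique(assignments):
        pts = centroids_um[assignments == c]
        center = pts.mean(axis=0)
        compact = float(np.linalg.norm(pts - center, axis=1).mean())
        rows.append(
            {
                "cluster": int(c),
                "size": len(pts),
                "compactness_um": compact,
                "singleton": len(pts) == 1,
            }
        )
    return pd.DataFrame(rows)


def pair_table(
    matrix: np.ndarray,
    distances_um: np.ndarray,
    classes: np.ndarray | None = None,
    assignments: np.ndarray | None = None,
) -> pd.DataFrame:
    """Tidy upper-triangle pair table (cell_i, cell_j, r, distance, class)."""
    n = matrix.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    df = pd.DataFrame(
        {
            "cell_i": iu,
            "cell_j": ju,
            "r": matrix[iu, ju],
            "distance_um": distances_um[iu, ju],
        }
    )
    if classes is not None:
        df["class"] = classes[iu, ju]
    if assignments is not None:
        assignments = np.asarray(assignments)
        df["intra_cluster"] = assignments[iu] == assignments[ju]
    return df


def compare_cluster_coupling(
    matrix_engaged: np.ndarray,
    matrix_disengaged: np.ndarray,
    assignments: np.ndarray,
    distances_um: np.ndarray,
) -> pd.DataFrame:
    """Paired comparison of coupling across states by cluster topology × sign.

    Pairs are partitioned into intra-/inter-cluster and by the sign of their
    correlation in the disengaged (reference) state, then compared engaged
    vs disengaged with paired t-tests over matched pairs.  Spearman ρ of
    correlation vs distance for the positive pairs of each state is appended.
    """
    n = matrix_engaged.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    eng, dis = matrix_engaged[iu, ju], matrix_disengaged[iu, ju]
    d = distances_um[iu, ju]
    assignments = np.asarray(assignments)
    intra = assignments[iu] == assignments[ju]
    rows = []
    for topo, topo_mask in (("intra", intra), ("inter", ~intra)):
        for sgn, sgn_mask in (("positive", dis > 0), ("negative", dis < 0)):
            m = topo_mask & sgn_mask & np.isfinite(eng) & np.isfinite(dis)
            if m.sum() < 2:
                rows.append(
                    {"partition": f"{topo}_{sgn}", "n": int(m.sum()), "skipped": True}
                )
                continue
            t, p = stats.ttest_rel(eng[m], dis[m])
            rows.append(
                {
                    "partition": f"{topo}_{sgn}",
                    "n": int(m.sum()),
                    "mean_engaged": float(eng[m].mean()),
                    "mean_disengaged": float(dis[m].mean()),
                    "t": float(t),
                    "p": float(p),
                    "skipped": False,
                }
            )
    for name, vals in (("engaged", eng), ("disengaged", dis)):
        m = (vals > 0) & np.isfinite(vals)
        if m.sum() >= 3:
            rho, p = stats.spearmanr(d[m], vals[m])
            rows.append(
                {
                    "partition": f"spearman_positive_{name}",
                    "n": int(m.sum()),
                    "rho": float(rho),
                    "p": float(p),
                    "skipped": False,
                }
            )
    return pd.DataFrame(rows)
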