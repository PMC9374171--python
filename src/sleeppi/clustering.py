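"""k-means clustering, internal validity indices and model selection.

Lloyd's algorithm (the expectation-maximisation-style assign/update loop)
minimises the within-cluster sum of squares (WCSS); the best of several
seeded restarts is kept.  Internal validity is measured by the
Calinski-Harabasz index — between/within dispersion scaled by degrees of
freedom — and the mean silhouette coefficient; the cluster count is chosen
where the WCSS-vs-k curve has maximum discrete curvature (the elbow), and
the feature-extraction method is chosen by averaging min-max-normalised CH
and silhouette over the small-k range where medically meaningful pattern
counts live.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import calinski_harabasz_score, silhouette_score

from .errors import ConfigurationError

#: Sentinel standing in for an infinite CH index when W = 0.
CH_PERFECT = 1e12


@dataclass
class ClusterSolution:
    k: int
    centroids: np.ndarray  # (k, J)
    labels: np.ndarray     # (n,), values in [0, k)
    wcss: float
    ch_index: float | None = None
    silhouette: float | None = None


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------


def fit_kmeans(
    Z: np.ndarray,
    k: int,
    max_iter: int = 300,
    restarts: int = 10,
    seed: int = 0,
    extra_init: np.ndarray | None = None,
    compute_metrics: bool = True,
) -> ClusterSolution:
    """Best-of-restarts Lloyd k-means on the extracted features.

    ``extra_init`` adds one run started from an explicit centroid array
    (used to warm-start k from the k-1 solution so the WCSS curve is
    non-increasing by construction).  Empty clusters are repaired by
    reseeding to far points (the library's strategy).
    """
    Z = np.asarray(Z, dtype=float)
    if Z.ndim != 2:
        raise ConfigurationError("Z must be 2-D")
    if not np.isfinite(Z).all():
        raise ConfigurationError("Z contains non-finite values")
    if k > Z.shape[0]:
        raise ConfigurationError(f"k={k} exceeds n={Z.shape[0]}")
    if k < 1:
        raise ConfigurationError("k must be >= 1")

    best = KMeans(
        n_clusters=k, n_init=restarts, max_iter=max_iter,
        algorithm="lloyd", random_state=seed,
    ).fit(Z)
    inertia, centroids, labels = best.inertia_, best.cluster_centers_, best.labels_
    if extra_init is not None:
        extra_init = np.asarray(extra_init, dtype=float)
        if extra_init.shape != (k, Z.shape[1]):
            raise ConfigurationError("extra_init must have shape (k, d)")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            warm = KMeans(
                n_clusters=k, init=extra_init, n_init=1, max_iter=max_iter,
                algorithm="lloyd", random_state=seed,
            ).fit(Z)
        if warm.inertia_ < inertia:
            inertia, centroids, labels = warm.inertia_, warm.cluster_centers_, warm.labels_

    sol = ClusterSolution(k=k, centroids=centroids, labels=labels, wcss=float(inertia))
    if compute_metrics and 2 <= k <= Z.shape[0] - 1:
        sol.ch_index = calinski_harabasz(Z, labels)
        sol.silhouette = silhouette(Z, labels)
    return sol


def assign(solution: ClusterSolution, Z_new: np.ndarray) -> np.ndarray:
    """Nearest-centroid labels (squared Euclidean; ties to lowest index)."""
    Z_new = np.asarray(Z_new, dtype=float)
    if Z_new.ndim != 2 or Z_new.shape[1] != solution.centroids.shape[1]:
        raise ConfigurationError(
            f"Z_new must be (n, {solution.centroids.shape[1]})"
        )
    d2 = ((Z_new[:, None, :] - solution.centroids[None, :, :]) ** 2).sum(axis=2)
    return np.argmin(d2, axis=1)  # argmin takes the first (lowest) index on ties


# ---------------------------------------------------------------------------
# Internal validity indices
# ---------------------------------------------------------------------------


def _check_labels(Z, labels):
    Z = np.asarray(Z, dtype=float)
    labels = np.asarray(labels)
    if Z.shape[0] != labels.shape[0]:
        raise ConfigurationError("labels must align with rows of Z")
    uniq, counts = np.unique(labels, return_counts=True)
    if uniq.size < 2:
        raise ConfigurationError("need at least 2 clusters")
    if (counts < 1).any():
        raise ConfigurationError("every cluster must be non-empty")
    return Z, labels, uniq


def calinski_harabasz(Z, labels) -> float:
    """(B/(k-1)) / (W/(n-k)); a large sentinel replaces +inf when W = 0."""
    Z, labels, uniq = _check_labels(Z, labels)
    W = 0.0
    for u in uniq:
        sub = Z[labels == u]
        W += float(((sub - sub.mean(axis=0)) ** 2).sum())
    if W == 0.0:
        return CH_PERFECT
    return float(calinski_harabasz_score(Z, labels))


def silhouette(Z, labels) -> float:
    """Mean per-point (b - a) / max(a, b); singleton clusters score 0."""
    Z, labels, uniq = _check_labels(Z, labels)
    if Z.shape[0] < 2:
        raise ConfigurationError("need at least 2 points")
    if uniq.size == Z.shape[0]:  # every cluster is a singleton
        return 0.0
    return float(silhouette_score(Z, labels))


# ---------------------------------------------------------------------------
# Elbow selection on the WCSS curve
# ---------------------------------------------------------------------------


@dataclass
class ElbowResult:
    k: int
    curvature: dict = field(default_factory=dict)
    no_elbow: bool = False


def elbow_select(wcss_by_k: dict, linear_tolerance: float = 1e-3) -> ElbowResult:
    """k at the maximum second difference of the WCSS curve.

    Requires consecutive k values.  Ties break toward the smallest k.  A
    near-linear curve — maximum curvature below ``linear_tolerance`` times
    the curve's range — is flagged ``no_elbow`` and the smallest candidate
    is returned with a warning.
    """
    ks = sorted(wcss_by_k)
    if len(ks) < 3:
        raise ConfigurationError("elbow selection needs at least 3 consecutive k values")
    if any(b - a != 1 for a, b in zip(ks, ks[1:])):
        raise ConfigurationError("k values must be consecutive")
    w = np.asarray([wcss_by_k[k] for k in ks], dtype=float)
    d2 = w[:-2] - 2.0 * w[1:-1] + w[2:]
    curvature = {ks[i + 1]: float(d2[i]) for i in range(len(d2))}
    span = float(w.max() - w.min())
    if span == 0.0 or float(d2.max()) < linear_tolerance * span:
        warnings.warn("WCSS curve is near-linear: no clear elbow", stacklevel=2)
        return ElbowResult(k=ks[1], curvature=curvature, no_elbow=True)
    best = int(np.argmax(d2))  # ties: argmax takes the first, i.e. smallest k
    return ElbowResult(k=ks[best + 1], curvature=curvature)


def wcss_curve(
    Z: np.ndarray, k_values=range(1, 11), restarts: int = 10, seed: int = 0
) -> dict:
    """WCSS for each k, warm-starting k from the k-1 solution.

    Each k also tries the previous solution's centroids plus a far-point
    split as one initialisation, guaranteeing a non-increasing curve.
    """
    out, prev = {}, None
    for k in k_values:
        extra = None
        if prev is not None and prev.k + 1 == k:
            d2 = ((np.asarray(Z)[:, None, :] - prev.centroids[None, :, :]) ** 2).sum(axis=2)
            far = np.asarray(Z)[int(np.argmax(d2.min(axis=1)))]
            extra = np.vstack([prev.centroids, far])
        sol = fit_kmeans(Z, k, restarts=restarts, seed=seed, extra_init=extra,
                         compute_metrics=False)
        out[k] = sol.wcss
        prev = sol
    return out


# ---------------------------------------------------------------------------
# Feature-method selection grid
# ---------------------------------------------------------------------------


def build_selection_grid(
    feature_sets: dict, k_values=range(2, 11), restarts: int = 10, seed: int = 0
) -> pd.DataFrame:
    """CH, silhouette and WCSS per (feature set, k).

    ``feature_sets`` maps a name (e.g. ``raw``, ``pca``, ``dae_J=2``) to its
    (n, J) feature array.
    """
    rows = []
    for name, Z in feature_sets.items():
        for k in k_values:
            sol = fit_kmeans(Z, k, restarts=restarts, seed=seed)
            rows.append(
                {
                    "feature_set": name,
                    "k": int(k),
                    "ch_index": sol.ch_index,
                    "silhouette": sol.silhouette,
                    "wcss": sol.wcss,
                }
            )
    return pd.DataFrame(rows)


def select_architecture(grid: pd.DataFrame, k_focus=(2, 3, 4)):
    """Feature set maximising normalised CH + silhouette over small k.

    For each k in ``k_focus`` and each metric, scores are min-max
    normalised across feature sets; each feature set's score is the mean of
    its normalised values.  Returns ``(winner, ranking_table)``.
    """
    need = {"feature_set", "k", "ch_index", "silhouette"}
    if not need <= set(grid.columns):
        raise ConfigurationError(f"grid must have columns {sorted(need)}")
    sub = grid[grid["k"].isin(list(k_focus))]
    feature_sets = list(dict.fromkeys(grid["feature_set"]))
    expected = len(feature_sets) * len(list(k_focus))
    if len(sub) != expected or sub[["ch_index", "silhouette"]].isna().any().any():
        raise ConfigurationError("selection grid has missing cells for k_focus")
    if len(feature_sets) == 1:
        return feature_sets[0], pd.DataFrame(
            {"feature_set": feature_sets, "score": [1.0]}
        )

    scores = {fs: [] for fs in feature_sets}
    for k in k_focus:
        at_k = sub[sub["k"] == k].set_index("feature_set")
        for metric in ("ch_index", "silhouette"):
            vals = at_k[metric].astype(float)
            lo, hi = vals.min(), vals.max()
            norm = (vals - lo) / (hi - lo) if hi > lo else vals * 0.0 + 0.5
            for fs in feature_sets:
                scores[fs].append(float(norm[fs]))
    ranking = pd.DataFrame(
        {
            "feature_set": feature_sets,
            "score": [float(np.mean(scores[fs])) for fs in feature_sets],
        }
    ).sort_values("score", ascending=False, kind="stable").reset_index(drop=True)
    return ranking.loc[0, "feature_set"], ranking
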