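"""PCA + repeated k-means + silhouette classification engine.

The same procedure serves three feature spaces: z-scored evoked patterns,
autocorrelogram shapes, and mean spike waveforms.  Features are reduced to
their first three principal components; k-means (random-point
initialization, Euclidean metric) is run many times for each candidate
cluster count k = 3..8; every run is scored by its mean silhouette; the k
whose runs reach the highest silhouette scores (upper quartile across runs)
is selected and the labels of the best-scoring single run are kept.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import chi2_contingency
from sklearn.decomposition import PCA

from . import stats as _stats

DEFAULT_K_RANGE = range(3, 9)
DEFAULT_N_ITER = 1000
# upper-quartile silhouette below this level means the scan found no real
# shape structure (pure-noise embeddings score ~0.25-0.30 at any k)
LOW_SEPARATION_SILHOUETTE = 0.4


def pca_embed(features: np.ndarray, n_components: int = 3):
    """Centered PCA embedding of a units x features matrix.

    Returns ``(scores, loadings, variance_fractions)`` with scores of shape
    (n_units, n_components), orthonormal loadings (n_features, n_components)
    and nonincreasing variance fractions. A matrix of identical rows maps to
    all-zero scores and zero variance fractions.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim != 2 or X.shape[0] < 4:
        raise ValueError("need a 2-D matrix with at least 4 units (rows)")
    if not np.all(np.isfinite(X)):
        raise ValueError("features must be finite")
    centered = X - X.mean(axis=0)
    if not centered.any():
        return (
            np.zeros((X.shape[0], n_components)),
            np.eye(X.shape[1], n_components),
            np.zeros(n_components),
        )
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    return scores, pca.components_.T, pca.explained_variance_ratio_.copy()


def _kmeans(X: np.ndarray, k: int, rng, max_iter: int = 100) -> np.ndarray:
    """Lloyd's algorithm with random-point initialization."""
    n = X.shape[0]
    centers = X[rng.choice(n, size=k, replace=False)].copy()
    labels = np.full(n, -1)
    for _ in range(max_iter):
        d = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        new = d.argmin(axis=1)
        if np.array_equal(new, labels):
            break
        labels = new
        for j in range(k):
            mask = labels == j
            if mask.any():
                centers[j] = X[mask].mean(axis=0)
    return labels


def mean_silhouette(D: np.ndarray, labels: np.ndarray, k: int) -> float:
    """Mean silhouette over all points, from a precomputed distance matrix.

    Singleton clusters score 0 (the usual convention); a run that left any
    of its k clusters empty scores -1, the worst possible value.
    """
    sizes = np.bincount(labels, minlength=k)
    if np.any(sizes == 0):
        return -1.0
    onehot = np.zeros((labels.size, k))
    onehot[np.arange(labels.size), labels] = 1.0
    sums = D @ onehot                              # point x cluster distance sums
    own = sums[np.arange(labels.size), labels]
    a = np.where(sizes[labels] > 1, own / np.maximum(sizes[labels] - 1, 1), 0.0)
    other = sums / np.maximum(sizes, 1)
    other[np.arange(labels.size), labels] = np.inf
    b = other.min(axis=1)
    denom = np.maximum(a, b)
    s = np.where(denom > 0, (b - a) / np.where(denom > 0, denom, 1.0), 0.0)
    s[sizes[labels] == 1] = 0.0
    return float(s.mean())


@dataclass
class ClusterScanResult:
    """Outcome of a silhouette scan over candidate cluster counts."""

    feature_tag: str
    k_range: list
    silhouettes: np.ndarray        # (n_k, n_iter) per-run mean silhouettes
    selected_k: int
    labels: np.ndarray             # 1..selected_k, from the best single run
    scores: np.ndarray             # (n_units, 3) PC scores
    loadings: np.ndarray
    variance_fractions: np.ndarray
    cluster_means: np.ndarray | None = None   # per-cluster mean feature pattern
    distribution_test: object = None          # rank test across per-k runs
    low_separation: bool = False
    best_labels_per_k: dict = field(default_factory=dict)

    def median_silhouettes(self) -> np.ndarray:
        return np.median(self.silhouettes, axis=1)

    def selection_scores(self, quantile: float = 75.0) -> np.ndarray:
        """Upper-quantile per-run silhouette for each scanned k."""
        return np.percentile(self.silhouettes, quantile, axis=1)


def silhouette_scan(
    scores: np.ndarray,
    k_range=DEFAULT_K_RANGE,
    n_iter: int = DEFAULT_N_ITER,
    seed: int = 0,
    max_iter: int = 100,
    selection_quantile: float = 75.0,
    features: np.ndarray | None = None,
    feature_tag: str = "",
    loadings: np.ndarray | None = None,
    variance_fractions: np.ndarray | None = None,
) -> ClusterScanResult:
    """Repeated k-means over ``k_range`` scored by the silhouette method.

    For each k, ``n_iter`` independent k-means runs (per-run RNG derived
    from (seed, k, iteration)); the selected k maximizes the
    ``selection_quantile`` (default: upper quartile) of the per-run mean
    silhouettes, ties going to the smaller k, and the labels come from the
    best-scoring single run of the selected k, relabeled 1..k in order of
    first appearance.

    The upper quartile scores each k by its well-converged runs: with
    random-point initialization many runs at the true k fail to seed every
    cluster (especially when cluster sizes are unequal), which drags the
    median down exactly at the correct k and biases a median-based
    selection toward k + 1.
    """
    X = np.asarray(scores, dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("scores must be finite")
    k_list = list(k_range)
    n = X.shape[0]
    if max(k_list) >= n:
        raise ValueError(f"largest k ({max(k_list)}) must be < n_units ({n})")
    D = squareform(pdist(X))
    if not D.any():
        raise ValueError("all points identical: silhouette undefined")

    sil = np.empty((len(k_list), n_iter))
    best_labels: dict[int, np.ndarray] = {}
    best_score = {k: -np.inf for k in k_list}
    for ki, k in enumerate(k_list):
        for it in range(n_iter):
            rng = np.random.default_rng([seed, k, it])
            labels = _kmeans(X, k, rng, max_iter=max_iter)
            s = mean_silhouette(D, labels, k)
            sil[ki, it] = s
            if s > best_score[k]:
                best_score[k] = s
                best_labels[k] = labels
    agg = np.percentile(sil, selection_quantile, axis=1)
    selected_k = k_list[int(np.argmax(agg))]       # argmax ties -> smaller k

    raw = best_labels[selected_k]
    labels = _relabel_first_appearance(raw)
    test = _stats.rank_tests({k: sil[i] for i, k in enumerate(k_list)}, posthoc=False)
    means = None
    if features is not None:
        feats = np.asarray(features, dtype=float)
        means = np.vstack([feats[labels == c].mean(axis=0) for c in range(1, selected_k + 1)])
    return ClusterScanResult(
        feature_tag=feature_tag,
        k_range=k_list,
        silhouettes=sil,
        selected_k=selected_k,
        labels=labels,
        scores=X,
        loadings=loadings if loadings is not None else np.empty((0, 0)),
        variance_fractions=(
            variance_fractions if variance_fractions is not None else np.empty(0)
        ),
        cluster_means=means,
        distribution_test=test,
        low_separation=bool(agg.max() < LOW_SEPARATION_SILHOUETTE),
        best_labels_per_k={k: _relabel_first_appearance(v) for k, v in best_labels.items()},
    )


def _relabel_first_appearance(labels: np.ndarray) -> np.ndarray:
    mapping: dict[int, int] = {}
    out = np.empty_like(labels)
    for i, lab in enumerate(labels):
        if lab not in mapping:
            mapping[lab] = len(mapping) + 1
        out[i] = mapping[lab]
    return out


def classify_patterns(
    features: np.ndarray,
    k_range=DEFAULT_K_RANGE,
    n_iter: int = DEFAULT_N_ITER,
    seed: int = 0,
    feature_tag: str = "",
) -> ClusterScanResult:
    """PCA embedding followed by the silhouette scan, in one call."""
    scores, loadings, var_frac = pca_embed(features)
    return silhouette_scan(
        scores, k_range=k_range, n_iter=n_iter, seed=seed,
        features=features, feature_tag=feature_tag,
        loadings=loadings, variance_fractions=var_frac,
    )


def prevalence_by_group(labels, groups, animals=None, alpha: float = 0.05) -> dict:
    """Cluster prevalence per group with a composition test.

    Returns ``{"table": counts, "percent": per-group percentages, "test":
    ...}``. With per-unit ``animals`` the test is Kruskal-Wallis across the
    group x cluster cells of per-animal percentages (the study's pooled
    factor coding); without animal ids it falls back to a chi-square test of
    independence on the contingency table.
    """
    labels = np.asarray(labels)
    groups = np.asarray(groups)
    if labels.shape != groups.shape:
        raise ValueError("labels and groups must be aligned (same length)")
    counts = pd.crosstab(pd.Series(groups, name="group"), pd.Series(labels, name="cluster"))
    if (counts.sum(axis=1) == 0).any():
        raise ValueError("a group is absent from the labels")
    percent = counts.div(counts.sum(axis=1), axis=0) * 100.0

    if animals is not None:
        animals = np.asarray(animals)
        df = pd.DataFrame({"group": groups, "cluster": labels, "animal": animals})
        per_animal = (
            df.groupby(["group", "animal", "cluster"], observed=True).size()
            .unstack(fill_value=0)
        )
        per_animal = per_animal.div(per_animal.sum(axis=1), axis=0) * 100.0
        samples = {
            (g, c): per_animal.xs(g, level="group")[c].to_numpy(float)
            for g in counts.index
            for c in per_animal.columns
        }
        test = _stats.rank_tests(samples, alpha=alpha, posthoc=False)
        return {"table": counts, "percent": percent, "test": test}
    chi2, p, dof, _ = chi2_contingency(counts.to_numpy())
    test = _stats.TestResult(statistic=float(chi2), df=float(dof), p=float(p), name="chi2")
    return {"table": counts, "percent": percent, "test": test}


__all__ = [
    "DEFAULT_K_RANGE", "DEFAULT_N_ITER", "LOW_SEPARATION_SILHOUETTE",
    "pca_embed", "mean_silhouette", "ClusterScanResult", "silhouette_scan",
    "classify_patterns", "prevalence_by_group",
]
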