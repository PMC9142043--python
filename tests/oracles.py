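"""Independent brute-force / closed-form oracles used by the test suite.

These deliberately avoid the package's own code paths: exhaustive partition
enumeration for k-means, an eigendecomposition of the sample covariance for
PCA, and the closed-form shared-covariance Bayes rule for LDA.
"""

import itertools

import numpy as np


def brute_force_kmeans_inertia(X: np.ndarray, k: int) -> float:
    """Minimum within-cluster SSE over all partitions into k nonempty groups."""
    n = X.shape[0]
    best = np.inf
    for labels in itertools.product(range(k), repeat=n):
        if len(set(labels)) != k:
            continue
        labels = np.asarray(labels)
        sse = 0.0
        for j in range(k):
            members = X[labels == j]
            sse += float(((members - members.mean(axis=0)) ** 2).sum())
        best = min(best, sse)
    return best


def best_lloyd_reachable_inertia(X: np.ndarray, k: int) -> float:
    """Best inertia reachable by Lloyd iteration from any distinct-point
    seeding (independent re-implementation using scipy only).

    On rare tiny instances the globally optimal partition, although a Lloyd
    fixed point, lies in a basin no point seeding reaches; this oracle
    bounds what any k-means++-seeded Lloyd run can achieve.
    """
    from scipy.spatial.distance import cdist

    best = np.inf
    for subset in itertools.combinations(range(X.shape[0]), k):
        centers = X[list(subset)].copy()
        for _ in range(200):
            labels = cdist(X, centers, "sqeuclidean").argmin(axis=1)
            new = np.array(
                [
                    X[labels == j].mean(axis=0) if (labels == j).any() else centers[j]
                    for j in range(k)
                ]
            )
            if np.allclose(new, centers, atol=1e-14):
                break
            centers = new
        d = cdist(X, centers, "sqeuclidean")
        best = min(best, float(d[np.arange(X.shape[0]), d.argmin(axis=1)].sum()))
    return best


def covariance_pca(X: np.ndarray, p: int):
    """PCA via eigendecomposition of the sample covariance (n-1 denominator).

    Returns (loadings (C, p), explained_variance (p,)) with the same sign
    convention as the implementation: largest-magnitude loading entry positive.
    """
    Xc = X - X.mean(axis=0)
    cov = Xc.T @ Xc / (X.shape[0] - 1)
    vals, vecs = np.linalg.eigh(cov)
    order = np.argsort(vals)[::-1][:p]
    loadings = vecs[:, order]
    flip = np.sign(loadings[np.argmax(np.abs(loadings), axis=0), np.arange(p)])
    flip[flip == 0] = 1.0
    return loadings * flip, vals[order]


def bayes_rule_predict(X, mu_wt, mu_ko, cov):
    """Equal-prior Bayes classifier for two Gaussians with shared covariance."""
    w = np.linalg.solve(cov, mu_ko - mu_wt)
    threshold = 0.5 * (mu_wt + mu_ko) @ w
    return np.where(X @ w >= threshold, "KO", "WT")
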