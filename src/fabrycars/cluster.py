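"""Pooled k-means clustering of preprocessed pixel spectra.

The cohort's pixel spectra (both genotypes, all images) are pooled and
clustered with Lloyd's algorithm under k-means++ seeding with restarts.
Clusters are then reported in a canonical order by the lipid:protein
intensity ratio of their centroids — the intensity at the channel nearest
2850 cm^-1 (CH2 symmetric, lipids) over that nearest 2940 cm^-1 (CH3
asymmetric, proteins) — so that canonical cluster 0 is always the most
lipid-dominant.  Per-genotype cluster percentages and cluster mean spectra
summarize the cohort composition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .axis import SpectralAxis
from .preprocess import PixelSpectraMatrix
from .simulate import LIPID_CM1, PROTEIN_CM1

__all__ = [
    "ClusterModel",
    "ClusterMap",
    "ClusterSummary",
    "kmeans_fit",
    "canonical_order",
    "assign",
    "fit_cohort",
    "SENTINEL",
]

#: label assigned to dropped (masked/degenerate) pixels in cluster maps
SENTINEL = 255

#: denominator floor for the lipid:protein centroid ratio; far below any
#: real protein-band intensity of a unit-norm spectrum (~0.1)
RATIO_EPS = 1e-6


@dataclass
class ClusterModel:
    """Fitted k-means model.

    ``centroids`` are stored in raw (fit) order; ``order[i]`` gives the raw
    index occupying canonical position ``i`` once :func:`canonical_order`
    has run (identity until then).  ``sizes`` are training-point counts per
    raw cluster.
    """

    k: int
    centroids: np.ndarray
    inertia: float
    seed: int
    sizes: np.ndarray
    order: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.order is None:
            self.order = np.arange(self.k)
        if not np.all(np.isfinite(self.centroids)):
            raise ValueError("centroids must be finite")
        if self.inertia < 0:
            raise ValueError("inertia must be nonnegative")
        if sorted(self.order.tolist()) != list(range(self.k)):
            raise ValueError("order must be a permutation of 0..k-1")

    @property
    def canonical_centroids(self) -> np.ndarray:
        return self.centroids[self.order]


@dataclass
class ClusterMap:
    """Canonical cluster index per downsampled pixel (SENTINEL = dropped)."""

    labels: np.ndarray
    meta: dict


@dataclass
class ClusterSummary:
    """Per-genotype cluster percentages and cluster mean spectra.

    ``percentages[genotype]`` is a length-k vector summing to 100 (indexed
    by canonical cluster); ``mean_spectra`` is (k, C), the mean of all
    assigned pixel spectra per canonical cluster across the whole cohort.
    """

    k: int
    percentages: dict[str, np.ndarray]
    mean_spectra: np.ndarray

    def __post_init__(self):
        for g, p in self.percentages.items():
            if abs(p.sum() - 100.0) > 1e-6:
                raise ValueError(f"percentages for {g} sum to {p.sum()}, not 100")


def _kmeanspp_init(X: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """k-means++ D^2 seeding."""
    n = X.shape[0]
    centers = np.empty((k, X.shape[1]))
    centers[0] = X[rng.integers(n)]
    d2 = np.sum((X - centers[0]) ** 2, axis=1)
    for j in range(1, k):
        total = d2.sum()
        if total <= 0:  # all points coincide with chosen centers
            centers[j:] = X[rng.integers(n, size=k - j)]
            break
        probs = d2 / total
        centers[j] = X[rng.choice(n, p=probs)]
        d2 = np.minimum(d2, np.sum((X - centers[j]) ** 2, axis=1))
    return centers


def _lloyd(X: np.ndarray, centers: np.ndarray, max_iter: int):
    """Lloyd iterations until assignments stabilize; empty clusters are
    re-seeded with the point farthest from its centroid."""
    k = centers.shape[0]
    labels = None
    prev_inertia = np.inf
    for _ in range(max_iter):
        d2 = cdist(X, centers, metric="sqeuclidean")
        new_labels = np.argmin(d2, axis=1)
        inertia = float(d2[np.arange(X.shape[0]), new_labels].sum())
        # within-cluster SSE never increases across Lloyd iterations
        assert inertia <= prev_inertia + 1e-8 * max(1.0, prev_inertia)
        prev_inertia = inertia
        if labels is not None and np.array_equal(new_labels, labels):
            break
        labels = new_labels
        for j in range(k):
            members = X[labels == j]
            if len(members):
                centers[j] = members.mean(axis=0)
            else:
                worst = np.argmax(d2[np.arange(X.shape[0]), labels])
                centers[j] = X[worst]
    d2 = cdist(X, centers, metric="sqeuclidean")
    labels = np.argmin(d2, axis=1)
    inertia = float(d2[np.arange(X.shape[0]), labels].sum())
    return centers, labels, inertia


def kmeans_fit(
    X: np.ndarray,
    k: int,
    seed: int = 0,
    restarts: int = 10,
    max_iter: int = 300,
) -> ClusterModel:
    """Fit k-means with ``restarts`` k-means++ starts; keep the lowest inertia."""
    X = np.asarray(X, dtype=np.float64)
    n = X.shape[0]
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if n < k:
        raise ValueError(f"need at least k={k} points, got n={n}")
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(restarts):
        centers = _kmeanspp_init(X, k, rng)
        centers, labels, inertia = _lloyd(X, centers, max_iter)
        if best is None or inertia < best[2]:
            best = (centers, labels, inertia)
    centers, labels, inertia = best
    sizes = np.bincount(labels, minlength=k)
    return ClusterModel(k=k, centroids=centers, inertia=inertia, seed=seed, sizes=sizes)


def canonical_order(model: ClusterModel, axis: SpectralAxis) -> ClusterModel:
    """Reorder clusters by descending centroid lipid:protein ratio.

    Ratio = centroid intensity at the channel nearest 2850 cm^-1 over that
    nearest 2940 cm^-1; canonical index 0 is the most lipid-dominant.
    Intensities are clipped at zero and the denominator floored at a small
    epsilon, so a centroid with no protein signal but positive lipid signal
    is maximally lipid-dominant, while a centroid with neither ranks last.
    Ties break by descending cluster size, then raw index.
    """
    ch_lipid = axis.nearest_channel(LIPID_CM1)
    ch_protein = axis.nearest_channel(PROTEIN_CM1)
    num = np.clip(model.centroids[:, ch_lipid], 0.0, None)
    den = np.clip(model.centroids[:, ch_protein], RATIO_EPS, None)
    ratio = num / den
    order = sorted(
        range(model.k), key=lambda j: (-ratio[j], -int(model.sizes[j]), j)
    )
    return ClusterModel(
        k=model.k,
        centroids=model.centroids,
        inertia=model.inertia,
        seed=model.seed,
        sizes=model.sizes,
        order=np.asarray(order),
    )


def assign(model: ClusterModel, X: np.ndarray) -> np.ndarray:
    """Canonical label of the nearest centroid for each row of X.

    Ties go to the lowest canonical index.
    """
    X = np.asarray(X, dtype=np.float64)
    if X.shape[1] != model.centroids.shape[1]:
        raise ValueError(
            f"X has {X.shape[1]} columns, centroids have {model.centroids.shape[1]}"
        )
    d2 = cdist(X, model.canonical_centroids, metric="sqeuclidean")
    return np.argmin(d2, axis=1)


def fit_cohort(
    matrices: list[PixelSpectraMatrix],
    k: int,
    seed: int = 0,
    pixels_per_image_cap: int = 20000,
    restarts: int = 10,
) -> tuple[ClusterModel, list[ClusterMap], ClusterSummary]:
    """Cluster a cohort: fit on a capped subsample pooled over all images of
    both genotypes, then assign every pixel of every image.

    Returns the canonically ordered model, per-image label maps, and a
    cohort summary (per-genotype percentages, cluster mean spectra).
    """
    if not matrices:
        raise ValueError("no pixel-spectra matrices given")
    rng = np.random.default_rng(seed)
    sample = []
    for mat in matrices:
        n = len(mat)
        if n > pixels_per_image_cap:
            idx = rng.choice(n, size=pixels_per_image_cap, replace=False)
            sample.append(mat.spectra[np.sort(idx)])
        else:
            sample.append(mat.spectra)
    pooled = np.vstack(sample)
    model = kmeans_fit(pooled, k, seed=seed, restarts=restarts)
    model = canonical_order(model, matrices[0].axis)

    maps: list[ClusterMap] = []
    counts: dict[str, np.ndarray] = {}
    spec_sum = np.zeros((k, matrices[0].spectra.shape[1]))
    spec_n = np.zeros(k)
    for mat in matrices:
        labels = assign(model, mat.spectra)
        lab_img = np.full(mat.shape, SENTINEL, dtype=np.uint8)
        lab_img[mat.pixel_index[:, 0], mat.pixel_index[:, 1]] = labels
        maps.append(ClusterMap(labels=lab_img, meta=dict(mat.meta)))
        g = mat.meta.get("genotype", "NA")
        counts.setdefault(g, np.zeros(k))
        counts[g] += np.bincount(labels, minlength=k)
        for j in range(k):
            rows = mat.spectra[labels == j]
            if len(rows):
                spec_sum[j] += rows.sum(axis=0)
                spec_n[j] += len(rows)

    percentages = {
        g: 100.0 * c / c.sum() for g, c in counts.items() if c.sum() > 0
    }
    mean_spectra = spec_sum / np.where(spec_n == 0, 1.0, spec_n)[:, None]
    summary = ClusterSummary(k=k, percentages=percentages, mean_spectra=mean_spectra)
    return model, maps, summary
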