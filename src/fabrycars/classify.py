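"""Per-image mean-spectrum PCA-LDA genotype classification with
leave-one-mouse-out cross-validation (LOMO-CV).

The classification unit is the mean preprocessed spectrum of one
hyperspectral image.  Dimensionality is reduced by PCA (column centering
only, no variance scaling), then a two-class Fisher discriminant with
equal priors separates WT from KO scores.  Performance is the mean
sensitivity — the unweighted average of the two per-genotype recalls
(balanced accuracy) — evaluated under grouped cross-validation in which
all images of the held-out mouse are excluded from training, preventing
subject-level leakage.  PCA and LDA are refit inside every fold on the
training images only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import PixelSpectraMatrix

__all__ = [
    "ImageFeature",
    "PCAModel",
    "LDAModel",
    "CVResult",
    "image_mean_spectrum",
    "pca_fit",
    "lda_fit",
    "lda_predict",
    "lomo_cv",
    "pc_sweep",
    "biplot_data",
]

WT, KO = "WT", "KO"


@dataclass(frozen=True)
class ImageFeature:
    """Mean preprocessed spectrum of one image plus its cohort identity."""

    mean_spectrum: np.ndarray
    image_id: str
    mouse_id: str
    genotype: str


@dataclass
class PCAModel:
    """PCA of mean spectra: column centering, no variance scaling."""

    mean_vector: np.ndarray
    loadings: np.ndarray  # (C, p), orthonormal columns
    explained_variance: np.ndarray  # length p, non-increasing

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=np.float64) - self.mean_vector) @ self.loadings


@dataclass
class LDAModel:
    """Two-class Fisher discriminant on PCA scores, equal priors.

    ``weight = (S_w + ridge*I)^-1 (mu_KO - mu_WT)`` with S_w the pooled
    within-class covariance; a point is classified to the class whose
    projected mean is nearer (midpoint threshold).  When the class means
    coincide the model degenerates and predicts the larger training class
    (ties -> WT).
    """

    weight: np.ndarray
    mean_wt: float
    mean_ko: float
    threshold: float
    ridge: float
    degenerate_class: str | None = None


@dataclass
class CVResult:
    """Cross-validated sensitivities at one PC count.

    ``sd`` is the standard deviation of the mean sensitivity over seeded
    bootstrap resamples of mice (stratified by genotype, recomputed from
    the stored per-image predictions).
    """

    n_pc: int
    predictions: pd.DataFrame  # image_id, mouse_id, genotype, predicted
    sensitivity_wt: float
    sensitivity_ko: float
    mean_sensitivity: float
    sd: float


def image_mean_spectrum(matrix: PixelSpectraMatrix) -> ImageFeature:
    """Channel-wise mean over all preprocessed pixel spectra of one image."""
    if len(matrix) == 0:
        raise ValueError("empty pixel-spectra matrix")
    return ImageFeature(
        mean_spectrum=matrix.spectra.mean(axis=0),
        image_id=str(matrix.meta.get("image_id", "")),
        mouse_id=str(matrix.meta.get("mouse_id", "")),
        genotype=str(matrix.meta.get("genotype", "")),
    )


def pca_fit(X: np.ndarray, p: int) -> PCAModel:
    """PCA via SVD of the column-centered matrix.

    Sign convention: the largest-magnitude entry of each loading is
    positive.  ``explained_variance`` uses the n-1 denominator.
    """
    X = np.asarray(X, dtype=np.float64)
    n, c = X.shape
    if not 1 <= p <= min(n - 1, c):
        raise ValueError(f"p={p} out of range [1, {min(n - 1, c)}] for shape {X.shape}")
    mean = X.mean(axis=0)
    _, s, vt = np.linalg.svd(X - mean, full_matrices=False)
    loadings = vt[:p].T
    flip = np.sign(loadings[np.argmax(np.abs(loadings), axis=0), np.arange(p)])
    flip[flip == 0] = 1.0
    loadings = loadings * flip
    var = (s[:p] ** 2) / (n - 1)
    return PCAModel(mean_vector=mean, loadings=loadings, explained_variance=var)


RIDGE_FACTOR = 1e-8


def lda_fit(scores: np.ndarray, labels) -> LDAModel:
    """Fit the two-class discriminant on PCA scores.

    ``labels`` are genotype strings ("WT"/"KO"); both classes must be
    present and n >= 3.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    n, p = scores.shape
    if n < 3:
        raise ValueError(f"need at least 3 samples, got {n}")
    wt = scores[labels == WT]
    ko = scores[labels == KO]
    if len(wt) < 1 or len(ko) < 1:
        raise ValueError("both genotype classes must be present in training data")
    mu_wt, mu_ko = wt.mean(axis=0), ko.mean(axis=0)
    dev_wt = wt - mu_wt
    dev_ko = ko - mu_ko
    sw = (dev_wt.T @ dev_wt + dev_ko.T @ dev_ko) / max(n - 2, 1)
    ridge = RIDGE_FACTOR * np.trace(sw) / p
    diff = mu_ko - mu_wt
    if not np.any(diff):  # coincident class means: no direction to separate
        larger = KO if len(ko) > len(wt) else WT
        return LDAModel(
            weight=np.zeros(p), mean_wt=0.0, mean_ko=0.0, threshold=0.0,
            ridge=ridge, degenerate_class=larger,
        )
    if ridge <= 0:  # zero within-class scatter: fall back to the mean gap
        ridge = RIDGE_FACTOR
    w = np.linalg.solve(sw + ridge * np.eye(p), diff)
    m_wt = float((wt @ w).mean())
    m_ko = float((ko @ w).mean())
    return LDAModel(
        weight=w,
        mean_wt=m_wt,
        mean_ko=m_ko,
        threshold=(m_wt + m_ko) / 2.0,
        ridge=ridge,
    )


def lda_predict(model: LDAModel, scores: np.ndarray) -> np.ndarray:
    """Classify each row to the class whose projected mean is nearer."""
    scores = np.atleast_2d(np.asarray(scores, dtype=np.float64))
    if model.degenerate_class is not None:
        return np.full(scores.shape[0], model.degenerate_class, dtype=object)
    proj = scores @ model.weight
    if model.mean_ko >= model.mean_wt:
        return np.where(proj >= model.threshold, KO, WT)
    return np.where(proj >= model.threshold, WT, KO)


def _sensitivities(pred: pd.DataFrame) -> tuple[float, float, float]:
    sens = {}
    for g in (WT, KO):
        sub = pred[pred.genotype == g]
        sens[g] = 100.0 * (sub.predicted == g).mean() if len(sub) else np.nan
    mean = (sens[WT] + sens[KO]) / 2.0
    return sens[WT], sens[KO], mean


def _bootstrap_sd(pred: pd.DataFrame, B: int, rng: np.random.Generator) -> float:
    """SD of the mean sensitivity over bootstrap resamples of mice,
    stratified by genotype so both classes stay represented."""
    by_mouse = {m: sub for m, sub in pred.groupby("mouse_id")}
    mice_wt = sorted(m for m, s in by_mouse.items() if s.genotype.iloc[0] == WT)
    mice_ko = sorted(m for m, s in by_mouse.items() if s.genotype.iloc[0] == KO)
    stats = []
    for _ in range(B):
        pick = list(rng.choice(mice_wt, size=len(mice_wt), replace=True)) + list(
            rng.choice(mice_ko, size=len(mice_ko), replace=True)
        )
        sample = pd.concat([by_mouse[m] for m in pick], ignore_index=True)
        stats.append(_sensitivities(sample)[2])
    return float(np.std(stats))


def lomo_cv(
    features: list[ImageFeature],
    n_pc: int,
    bootstrap_B: int = 200,
    seed: int = 0,
    group_by_mouse: bool = True,
) -> CVResult:
    """Cross-validated PCA-LDA genotype prediction.

    With ``group_by_mouse=True`` (LOMO-CV, the default) the training set
    for an image excludes every image of that image's mouse; PCA and LDA
    are refit per fold on training images only.  ``group_by_mouse=False``
    gives naive leave-one-image-out CV — provided only to demonstrate the
    subject-leakage inflation it causes when mice contribute several
    images.
    """
    if len({f.mouse_id for f in features if f.genotype == WT}) < 2 or len(
        {f.mouse_id for f in features if f.genotype == KO}
    ) < 2:
        raise ValueError("need at least 2 mice per genotype")
    X = np.array([f.mean_spectrum for f in features])
    mouse = np.array([f.mouse_id for f in features])
    geno = np.array([f.genotype for f in features])

    predicted = np.empty(len(features), dtype=object)
    if group_by_mouse:
        folds = [(m, mouse == m) for m in sorted(set(mouse))]
    else:
        folds = [(features[i].image_id, np.arange(len(features)) == i)
                 for i in range(len(features))]
    for fold_name, held in folds:
        train = ~held
        n_train = int(train.sum())
        cap = min(n_train - 1, X.shape[1])
        if n_pc > cap:
            raise ValueError(
                f"n_pc={n_pc} infeasible in fold {fold_name!r} "
                f"(max {cap} with {n_train} training images)"
            )
        pca = pca_fit(X[train], n_pc)
        lda = lda_fit(pca.transform(X[train]), geno[train])
        predicted[held] = lda_predict(lda, pca.transform(X[held]))

    pred = pd.DataFrame(
        {
            "image_id": [f.image_id for f in features],
            "mouse_id": mouse,
            "genotype": geno,
            "predicted": predicted,
        }
    )
    s_wt, s_ko, mean = _sensitivities(pred)
    sd = _bootstrap_sd(pred, bootstrap_B, np.random.default_rng(seed))
    return CVResult(
        n_pc=n_pc,
        predictions=pred,
        sensitivity_wt=s_wt,
        sensitivity_ko=s_ko,
        mean_sensitivity=mean,
        sd=sd,
    )


def pc_sweep(
    features: list[ImageFeature],
    max_pc: int = 15,
    bootstrap_B: int = 200,
    seed: int = 0,
) -> tuple[list[CVResult], int]:
    """LOMO-CV over n_pc = 1..max_pc (capped by per-fold feasibility).

    Returns the sensitivity curve and the optimal PC count: the smallest
    n_pc attaining the maximum mean sensitivity.
    """
    mice = {}
    for f in features:
        mice.setdefault(f.mouse_id, 0)
        mice[f.mouse_id] += 1
    n = len(features)
    c = len(features[0].mean_spectrum)
    feasible = min(n - count - 1 for count in mice.values())
    feasible = min(feasible, c, max_pc)
    if feasible < 1:
        raise ValueError("no feasible PC count for this cohort")
    results = [
        lomo_cv(features, n_pc, bootstrap_B=bootstrap_B, seed=seed)
        for n_pc in range(1, feasible + 1)
    ]
    best = max(r.mean_sensitivity for r in results)
    optimal = next(r.n_pc for r in results if r.mean_sensitivity == best)
    return results, optimal


def biplot_data(features: list[ImageFeature]) -> pd.DataFrame:
    """PC1/PC2 scores of all image mean spectra, for the genotype biplot."""
    if len(features) < 3:
        raise ValueError("need at least 3 images for a biplot")
    X = np.array([f.mean_spectrum for f in features])
    pca = pca_fit(X, 2)
    scores = pca.transform(X)
    return pd.DataFrame(
        {
            "image_id": [f.image_id for f in features],
            "PC1": scores[:, 0],
            "PC2": scores[:, 1],
            "genotype": [f.genotype for f in features],
        }
    )
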