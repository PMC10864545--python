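"""Composite expression marker and the two-feature linear-margin classifier.

The composite marker is the first principal component (PC1) of the marker
panel -- PSMC6 plus the seven alpha-ring genes (PSMA1-PSMA7) -- with samples as
observations.  PC1 is regressed against clinical severity indicators (MMSE,
NFT) by ordinary least squares.  The classifier takes two features per sample,
(PSMC6 expression, mean alpha-ring expression), fits a soft-margin linear SVM,
and evaluates it with stratified k-fold cross-validated ROC/AUC.  A rotated
coordinate frame aligned with the disease-group trendline defines a deviation
band: AD samples concentrate inside a narrow band around the trendline, and
the report gives the fraction of AD samples outside it and of controls inside
it, plus a feature-space threshold point O.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .data_io import ExpressionMatrix
from .panel import GenePanel

AD_LABEL = "AD"
CON_LABEL = "CON"


@dataclass
class MarkerScores:
    """PC1 composite-marker scores with loadings and orientation rule."""

    sample_ids: list[str]
    pc1: np.ndarray
    explained_ratio: float
    loadings: np.ndarray
    gene_ids: list[str]
    sign_convention: str = "positive-loading-sum"


@dataclass
class FitResult:
    """Ordinary least-squares fit with Pearson r and its two-sided p."""

    slope: float
    intercept: float
    r: float
    p: float
    n: int


@dataclass
class RotatedFrame:
    """Orthonormal frame with x' along the AD trendline, y' orthogonal."""

    origin: np.ndarray          # a point on the trendline
    x_axis: np.ndarray          # unit vector along the trendline
    y_axis: np.ndarray          # unit normal
    slope: float
    intercept: float

    def transform(self, points: np.ndarray) -> np.ndarray:
        """Map feature-space points into (x', y') coordinates (an isometry)."""
        rel = np.atleast_2d(points) - self.origin
        return np.column_stack([rel @ self.x_axis, rel @ self.y_axis])


@dataclass
class ClassifierReport:
    """Linear-margin classifier evaluation plus the rotated band rule."""

    weights: np.ndarray
    bias: float
    fold_aucs: list[float]
    mean_auc: float
    roc_points: list[tuple[float, float]]   # pooled (fpr, tpr) over folds
    threshold_point: tuple[float, float] | None = None
    frame: RotatedFrame | None = None
    band_half_width: float | None = None
    coverage_quantile: float | None = None
    ad_outside_band: float | None = None
    con_inside_band: float | None = None

    def to_dict(self) -> dict:
        d = {
            "weights": [float(w) for w in self.weights],
            "bias": float(self.bias),
            "fold_aucs": [float(a) for a in self.fold_aucs],
            "mean_auc": float(self.mean_auc),
            "threshold_point": list(self.threshold_point) if self.threshold_point else None,
            "band_half_width": self.band_half_width,
            "coverage_quantile": self.coverage_quantile,
            "ad_outside_band": self.ad_outside_band,
            "con_inside_band": self.con_inside_band,
        }
        if self.frame is not None:
            d["frame"] = {
                "origin": [float(v) for v in self.frame.origin],
                "x_axis": [float(v) for v in self.frame.x_axis],
                "y_axis": [float(v) for v in self.frame.y_axis],
                "slope": float(self.frame.slope),
                "intercept": float(self.frame.intercept),
            }
        return d


# -- operations -----------------------------------------------------------------

def pc1_scores(m: ExpressionMatrix) -> MarkerScores:
    """First principal component of the marker panel (samples = observations).

    Eigendecomposition of the gene-gene covariance of the centered data;
    scores are the centered projections on the top eigenvector.  Orientation:
    the loading sum is made positive (tie broken by the first nonzero loading).
    """
    if m.n_samples < 2 or m.n_genes < 2:
        raise ValueError("PC1 needs at least 2 samples and 2 genes")
    x = m.values.T  # samples x genes
    centered = x - x.mean(axis=0)
    cov = centered.T @ centered / (x.shape[0] - 1)
    total = float(np.trace(cov))
    if total <= 0:
        raise ValueError("zero total variance: PC1 undefined")
    eigval, eigvec = np.linalg.eigh(cov)
    top = eigvec[:, -1]
    ssum = top.sum()
    if ssum < 0 or (ssum == 0 and top[np.flatnonzero(top)[0]] < 0):
        top = -top
    scores = centered @ top
    return MarkerScores(
        sample_ids=list(m.sample_ids),
        pc1=scores,
        explained_ratio=float(eigval[-1] / total),
        loadings=top,
        gene_ids=list(m.gene_ids),
    )


def linear_fit(x: Sequence[float], y: Sequence[float]) -> FitResult:
    """OLS slope/intercept with Pearson r and two-sided p from the t statistic
    t = r * sqrt((n-2)/(1-r^2)), df = n-2.  A constant y gives r = 0, slope 0."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 3:
        raise ValueError("linear fit needs at least 3 points")
    if x.std() == 0:
        raise ValueError("x has zero variance: fit undefined")
    if y.std() == 0:
        return FitResult(slope=0.0, intercept=float(y.mean()), r=0.0, p=1.0, n=n)
    res = stats.linregress(x, y)
    r = float(res.rvalue)
    if abs(r) >= 1.0 - 1e-15:
        p = 0.0
    else:
        t = r * np.sqrt((n - 2) / (1 - r * r))
        p = float(2 * stats.t.sf(abs(t), n - 2))
    return FitResult(slope=float(res.slope), intercept=float(res.intercept),
                     r=r, p=p, n=n)


def make_features(m: ExpressionMatrix, panel: GenePanel) -> tuple[np.ndarray, list[str]]:
    """Per-sample (PSMC6, mean alpha-ring) feature pairs.

    Returns an (n_samples, 2) array and the sample ids.  Requires PSMC6 and
    all seven alpha-ring genes.
    """
    alpha = panel.alpha_ring
    needed = ("PSMC6",) + alpha
    missing = [g for g in needed if g not in m.gene_ids]
    if missing:
        raise ValueError(f"marker genes absent from matrix: {missing}")
    psmc6 = m.row("PSMC6")
    alpha_mean = np.vstack([m.row(g) for g in alpha]).mean(axis=0)
    return np.column_stack([psmc6, alpha_mean]), list(m.sample_ids)


def _check_labels(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels)
    classes = set(labels.tolist())
    if classes != {AD_LABEL, CON_LABEL}:
        raise ValueError(f"labels must contain both {AD_LABEL!r} and {CON_LABEL!r}, got {sorted(classes)}")
    return labels


def default_threshold_point(
    features: np.ndarray, weights: np.ndarray, bias: float
) -> tuple[float, float]:
    """Threshold point O: the decision boundary evaluated at the marginal medians.

    O_x solves w.x + b = 0 at y = median(feature 2); O_y solves it at
    x = median(feature 1).  Falls back to the plain marginal medians when the
    boundary is parallel to an axis.
    """
    med = np.median(features, axis=0)
    w1, w2 = float(weights[0]), float(weights[1])
    ox = (-bias - w2 * med[1]) / w1 if abs(w1) > 1e-12 else float(med[0])
    oy = (-bias - w1 * med[0]) / w2 if abs(w2) > 1e-12 else float(med[1])
    return (float(ox), float(oy))


def fit_evaluate_classifier(
    features: np.ndarray,
    labels: Sequence[str],
    folds: int = 10,
    seed: int = 0,
    C: float = 1.0,
) -> ClassifierReport:
    """Soft-margin linear SVM with stratified k-fold cross-validated ROC/AUC.

    Per-fold AUC from decision scores on the held-out fold; the reported
    boundary is refit on all data.  AD is the positive class.
    """
    features = np.asarray(features, dtype=float)
    labels = _check_labels(np.asarray(labels))
    y = (labels == AD_LABEL).astype(int)
    min_class = min(int(y.sum()), int((1 - y).sum()))
    if folds > min_class:
        raise ValueError(
            f"folds={folds} exceeds the smaller class size {min_class}; "
            f"reduce folds to at most {min_class}"
        )
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    fold_aucs: list[float] = []
    roc_points: list[tuple[float, float]] = []
    for train, test in skf.split(features, y):
        clf = SVC(kernel="linear", C=C)
        clf.fit(features[train], y[train])
        scores = clf.decision_function(features[test])
        fold_aucs.append(float(roc_auc_score(y[test], scores)))
        fpr, tpr, _ = roc_curve(y[test], scores)
        roc_points.extend(zip(map(float, fpr), map(float, tpr)))
    final = SVC(kernel="linear", C=C)
    final.fit(features, y)
    weights = final.coef_[0]
    bias = float(final.intercept_[0])
    return ClassifierReport(
        weights=weights,
        bias=bias,
        fold_aucs=fold_aucs,
        mean_auc=float(np.mean(fold_aucs)),
        roc_points=roc_points,
        threshold_point=default_threshold_point(features, weights, bias),
    )


def rotated_band_rule(
    features: np.ndarray,
    labels: Sequence[str],
    coverage_quantile: float = 0.95,
    threshold_point: tuple[float, float] | None = None,
) -> ClassifierReport:
    """Deviation-band rule in the frame of the AD trendline.

    The x'-axis is the least-squares trendline fitted on AD samples only; y' is
    the signed orthogonal deviation from it.  The band half-width is the
    ``coverage_quantile`` of AD |y'|.  Reports the fraction of AD samples
    outside the band and of controls inside it, and the threshold point O in
    both frames.
    """
    features = np.asarray(features, dtype=float)
    labels = _check_labels(np.asarray(labels))
    ad = features[labels == AD_LABEL]
    con = features[labels == CON_LABEL]
    if ad.shape[0] < 3:
        raise ValueError("need at least 3 AD samples for the trendline")
    if not 0 < coverage_quantile <= 1:
        raise ValueError("coverage_quantile must lie in (0, 1]")
    fit = linear_fit(ad[:, 0], ad[:, 1])
    direction = np.array([1.0, fit.slope]) / np.sqrt(1 + fit.slope ** 2)
    normal = np.array([-fit.slope, 1.0]) / np.sqrt(1 + fit.slope ** 2)
    x0 = float(ad[:, 0].mean())
    origin = np.array([x0, fit.intercept + fit.slope * x0])
    frame = RotatedFrame(origin=origin, x_axis=direction, y_axis=normal,
                         slope=fit.slope, intercept=fit.intercept)
    ad_y = frame.transform(ad)[:, 1]
    band = float(np.quantile(np.abs(ad_y), coverage_quantile))
    con_y = frame.transform(con)[:, 1]
    report = ClassifierReport(
        weights=np.array([np.nan, np.nan]),
        bias=float("nan"),
        fold_aucs=[],
        mean_auc=float("nan"),
        roc_points=[],
        threshold_point=tuple(map(float, threshold_point)) if threshold_point else None,
        frame=frame,
        band_half_width=band,
        coverage_quantile=coverage_quantile,
        ad_outside_band=float((np.abs(ad_y) > band).mean()),
        con_inside_band=float((np.abs(con_y) <= band).mean()),
    )
    return report
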