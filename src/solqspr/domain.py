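"""Domain-of-applicability (DOA) assessment for the solubility model.

Two complementary views of how well a test compound is represented by the
training chemical space, both computed on the (0,1)-scaled selected
descriptors:

* **PCA ellipse** - principal components of the centred (not
  re-standardised) scaled training table; a test compound is "inside the
  domain" when the Mahalanobis distance of its (PC1, PC2) score under the
  training score covariance is within the chi-square(2 df) 95% quantile.

* **Normalized Euclidean similarity** - for vectors in the m-dimensional
  unit hypercube the largest possible Euclidean distance is sqrt(m)
  (corner to corner), so  sim(a, b) = 1 - ||a - b|| / sqrt(m)  lies in
  [0, 1], equals 1 only for identical vectors, and ranks neighbours
  exactly as raw Euclidean distance does.  The 10 nearest training
  neighbours of a query and the spread of their logS0 values flag
  compounds whose neighbourhood disagrees with them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from .evaluation import OutlierReport

__all__ = [
    "DoaModel",
    "fit_doa",
    "project",
    "inside_ellipse",
    "similarity_index",
    "similarity_matrix",
    "nearest_neighbors",
    "doa_report",
]


@dataclass
class DoaModel:
    """Training PCA basis plus the 95% ellipse on PC1-PC2."""

    feature_names: list[str]
    mean: np.ndarray                 # training mean of scaled descriptors
    components: np.ndarray           # (n_components, n_features), orthonormal rows
    explained_variance_ratio: np.ndarray
    score_cov: np.ndarray            # 2x2 covariance of training PC1-2 scores
    chi2_quantile: float             # chi-square(2) quantile for the 95% region
    training_scores: np.ndarray      # (n, 2) training scores, for reporting


def fit_doa(scaled_training: pd.DataFrame, coverage: float = 0.95) -> DoaModel:
    """PCA on the centred scaled training descriptors; keep the ellipse data."""
    X = scaled_training.to_numpy(dtype=float)
    if X.shape[0] < 3:
        raise ValueError("need at least 3 training compounds for the DOA model")
    pca = PCA()
    scores = pca.fit_transform(X)
    s2 = scores[:, :2]
    cov = np.cov(s2.T, ddof=1)
    return DoaModel(feature_names=list(scaled_training.columns),
                    mean=pca.mean_,
                    components=pca.components_,
                    explained_variance_ratio=pca.explained_variance_ratio_,
                    score_cov=cov,
                    chi2_quantile=float(stats.chi2.ppf(coverage, df=2)),
                    training_scores=s2)


def project(model: DoaModel, scaled: pd.DataFrame) -> np.ndarray:
    """(PC1, PC2) scores of compounds in the training basis."""
    missing = [c for c in model.feature_names if c not in scaled.columns]
    if missing:
        raise ValueError(f"missing descriptor column(s): {missing}")
    X = scaled[model.feature_names].to_numpy(dtype=float)
    return (X - model.mean) @ model.components[:2].T


def inside_ellipse(model: DoaModel, scores: np.ndarray) -> np.ndarray:
    """Boolean per compound: Mahalanobis^2 of the PC1-2 score <= chi2_0.95(2)."""
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    if np.linalg.matrix_rank(model.score_cov) < 2:
        raise ValueError("singular PC1-PC2 score covariance; ellipse undefined")
    inv = np.linalg.inv(model.score_cov)
    d2 = np.einsum("ij,jk,ik->i", scores, inv, scores)
    return d2 <= model.chi2_quantile


def similarity_index(a, b, literal: bool = False) -> float:
    """Similarity of two scaled descriptor vectors; 1 identical, 0 opposite corners.

    Default form: 1 - ||a - b|| / sqrt(m).  ``literal=True`` evaluates the
    difference-of-squares variant 1 - sqrt(sum(a_i^2 - b_i^2)) / sqrt(m)
    for comparison; its radicand can be negative, in which case NaN is
    returned.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    m = a.size
    if literal:
        radicand = float(np.sum(a ** 2 - b ** 2))
        if radicand < 0:
            return float("nan")
        return 1.0 - np.sqrt(radicand) / np.sqrt(m)
    return float(1.0 - np.linalg.norm(a - b) / np.sqrt(m))


def similarity_matrix(queries: pd.DataFrame | np.ndarray,
                      training: pd.DataFrame | np.ndarray) -> np.ndarray:
    """(n_query, n_train) similarity indices, vectorised."""
    A = np.asarray(queries, dtype=float)
    B = np.asarray(training, dtype=float)
    if A.shape[1] != B.shape[1]:
        raise ValueError("query/training descriptor dimensions differ")
    m = A.shape[1]
    d = np.sqrt(((A[:, None, :] - B[None, :, :]) ** 2).sum(axis=2))
    return 1.0 - d / np.sqrt(m)


@dataclass
class NeighborStats:
    """logS0 statistics over a query's k nearest training neighbours."""

    neighbors: pd.DataFrame   # compound_id, similarity, logS0 (descending similarity)
    mean: float
    min: float
    max: float


def nearest_neighbors(query, training_scaled: pd.DataFrame, training_logS0,
                      training_ids, k: int = 10) -> NeighborStats:
    """The k most similar training compounds and their logS0 spread.

    Ranking by descending similarity (equivalently ascending Euclidean
    distance); ties broken by compound id for determinism.
    """
    n = len(training_scaled)
    if k > n:
        raise ValueError(f"k={k} exceeds the {n} training compounds")
    sims = similarity_matrix(np.atleast_2d(np.asarray(query, dtype=float)),
                             training_scaled)[0]
    ids = [str(i) for i in training_ids]
    y = np.asarray(training_logS0, dtype=float)
    order = sorted(range(n), key=lambda i: (-sims[i], ids[i]))[:k]
    nb = pd.DataFrame({"compound_id": [ids[i] for i in order],
                       "similarity": [float(sims[i]) for i in order],
                       "logS0": [float(y[i]) for i in order]})
    return NeighborStats(neighbors=nb, mean=float(nb["logS0"].mean()),
                         min=float(nb["logS0"].min()), max=float(nb["logS0"].max()))


def doa_report(model: DoaModel, test_scaled: pd.DataFrame, test_ids,
               y_exp, y_pred, training_scaled: pd.DataFrame, training_logS0,
               training_ids, outliers: OutlierReport | None = None,
               k: int = 10) -> pd.DataFrame:
    """Per-compound reliability table for one test set.

    Columns: compound_id, pc1, pc2, inside_95, exp_logS0, pred_logS0,
    nn_mean, nn_min, nn_max, max_similarity, flag (outlier / best / "").
    """
    scores = project(model, test_scaled)
    inside = inside_ellipse(model, scores) if len(test_scaled) else np.array([], bool)
    sims = (similarity_matrix(test_scaled[model.feature_names], training_scaled)
            if len(test_scaled) else np.zeros((0, len(training_scaled))))
    y_exp = np.asarray(y_exp, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    flag_of: dict[str, str] = {}
    if outliers is not None:
        for cid, _ in outliers.outliers:
            flag_of[cid] = "outlier"
        for cid, _ in outliers.best:
            flag_of[cid] = "best"
    rows = []
    for i, cid in enumerate([str(c) for c in test_ids]):
        nb = nearest_neighbors(test_scaled[model.feature_names].iloc[i],
                               training_scaled, training_logS0, training_ids, k=k)
        rows.append({"compound_id": cid,
                     "pc1": float(scores[i, 0]), "pc2": float(scores[i, 1]),
                     "inside_95": bool(inside[i]),
                     "exp_logS0": float(y_exp[i]), "pred_logS0": float(y_pred[i]),
                     "nn_mean": nb.mean, "nn_min": nb.min, "nn_max": nb.max,
                     "max_similarity": float(sims[i].max()),
                     "flag": flag_of.get(cid, "")})
    return pd.DataFrame(rows, columns=["compound_id", "pc1", "pc2", "inside_95",
                                       "exp_logS0", "pred_logS0", "nn_mean",
                                       "nn_min", "nn_max", "max_similarity", "flag"])
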