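"""Prediction-performance metrics, cross-validation and outlier analysis.

Metrics follow the SC-2 conventions: R^2 (against the evaluated set's own
mean), RMSE, bias (mean of experimental minus predicted, so a negative
bias means over-prediction) and the percentage of predictions within 0.5
log units (boundary inclusive).  Outliers are compounds whose absolute
error strictly exceeds twice the set's own RMSE; best-predicted compounds
have absolute error at most 0.2x RMSE.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold

from .curation import aggregate_replicates, drop_incomplete_descriptors
from .features import ScalingParams, fit_scaling, select_top_k
from .models import MlpConfig, TrainedModel, train_mlp

__all__ = [
    "MetricsReport",
    "OutlierReport",
    "compute_metrics",
    "null_rmse_identity",
    "kfold_cv",
    "detect_outliers",
    "leave_out_metrics",
    "compare_strategies",
    "residual_table",
]


@dataclass
class MetricsReport:
    """R^2 / RMSE / bias / %+-0.5 for one evaluated set.

    ``r2`` is ``None`` when the experimental values have zero variance.
    ``pct_within_half`` is a raw percentage in [0, 100]; tables usually
    print it rounded to whole percent.
    """

    n: int
    r2: float | None
    rmse: float
    bias: float
    pct_within_half: float

    def to_dict(self) -> dict:
        return {"n": self.n, "r2": self.r2, "rmse": self.rmse,
                "bias": self.bias, "pct_within_half": self.pct_within_half}

    def __str__(self) -> str:
        r2 = "n/a" if self.r2 is None else f"{self.r2:.2f}"
        return (f"n={self.n}  R2={r2}  RMSE={self.rmse:.2f}  "
                f"bias={self.bias:.3f}  %+-0.5={self.pct_within_half:.0f}")


def compute_metrics(y, y_pred) -> MetricsReport:
    """SC-2 measures of prediction performance for one set."""
    y = np.asarray(y, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y.shape != y_pred.shape:
        raise ValueError(f"length mismatch: {y.shape} vs {y_pred.shape}")
    if y.size == 0:
        raise ValueError("empty evaluation set")
    resid = y - y_pred
    rmse = float(np.sqrt(np.mean(resid ** 2)))
    bias = float(np.mean(resid))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = None if ss_tot == 0 else float(1.0 - np.sum(resid ** 2) / ss_tot)
    pct = float(100.0 * np.mean(np.abs(resid) <= 0.5))
    return MetricsReport(n=int(y.size), r2=r2, rmse=rmse, bias=bias,
                         pct_within_half=pct)


def null_rmse_identity(test_mean: float, test_sd: float, n: int,
                       train_mean: float) -> MetricsReport:
    """Null-model metrics from a test set's printed moments alone.

    For a constant prediction c = train_mean,
    RMSE^2 = ((n-1)/n) SD^2 + (mean - c)^2  and  bias = mean - c;
    R^2 follows from the same two quantities.  The %+-0.5 measure needs
    per-compound values and is reported as NaN here.
    """
    bias = test_mean - train_mean
    mse = (n - 1) / n * test_sd ** 2 + bias ** 2
    ss_tot = (n - 1) * test_sd ** 2
    r2 = None if ss_tot == 0 else 1.0 - n * mse / ss_tot
    return MetricsReport(n=n, r2=r2, rmse=float(np.sqrt(mse)), bias=float(bias),
                         pct_within_half=float("nan"))


def kfold_cv(X: pd.DataFrame, y, config: MlpConfig | None = None, k: int = 10,
             seed: int = 0, top_k: int = 10, prune_threshold: float = 0.8,
             select_within_folds: bool = True
             ) -> tuple[MetricsReport, pd.DataFrame]:
    """k-fold cross-validation of the full modelling chain.

    Each compound is validated exactly once.  By default feature selection
    and scaling are re-fit inside every training fold (leakage-free);
    ``select_within_folds=False`` reproduces the historical protocol of
    selecting features once on the full table before splitting.  Returns
    pooled out-of-fold metrics plus a per-compound prediction table.
    """
    config = config or MlpConfig()
    y = np.asarray(y, dtype=float)
    n = len(X)
    if k > n:
        raise ValueError(f"k={k} exceeds n={n}")
    global_selection = None
    if not select_within_folds:
        global_selection = select_top_k(X, pd.Series(y), k=top_k,
                                        threshold=prune_threshold).selected
    kf = KFold(n_splits=k, shuffle=True, random_state=seed)
    pred = np.full(n, np.nan)
    fold_of = np.full(n, -1)
    for fold, (tr, va) in enumerate(kf.split(X)):
        Xtr, ytr = X.iloc[tr], y[tr]
        feats = (global_selection if global_selection is not None
                 else select_top_k(Xtr, pd.Series(ytr), k=top_k,
                                   threshold=prune_threshold).selected)
        scaling = fit_scaling(Xtr[feats], ytr)
        model = train_mlp(scaling.transform_features(Xtr[feats]),
                          scaling.transform_target(ytr),
                          MlpConfig(**{**config.__dict__, "seed": config.seed + fold}),
                          scaling=scaling, feature_names=feats)
        pred[va] = model.predict(X.iloc[va])
        fold_of[va] = fold
    assert not np.isnan(pred).any()
    table = pd.DataFrame({"y": y, "y_pred": pred, "fold": fold_of}, index=X.index)
    return compute_metrics(y, pred), table


@dataclass
class OutlierReport:
    """Worst- and best-predicted compounds of one evaluated set.

    ``outliers``: |error| strictly greater than 2 x RMSE, worst first.
    ``best``: |error| <= 0.2 x RMSE.  Errors are signed (experimental
    minus predicted).
    """

    rmse: float
    threshold: float
    outliers: list[tuple[str, float]] = field(default_factory=list)
    best: list[tuple[str, float]] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {"rmse": self.rmse, "threshold": self.threshold,
                "outliers": [{"compound_id": c, "error": e} for c, e in self.outliers],
                "best": [{"compound_id": c, "error": e} for c, e in self.best]}


def detect_outliers(y, y_pred, ids: Sequence[str]) -> OutlierReport:
    """Flag compounds against the set's own 2xRMSE / 0.2xRMSE thresholds."""
    y = np.asarray(y, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    err = y - y_pred
    rmse = float(np.sqrt(np.mean(err ** 2)))
    thr = 2.0 * rmse
    order = np.argsort(-np.abs(err), kind="stable")
    outliers = [(str(ids[i]), float(err[i])) for i in order if abs(err[i]) > thr]
    best = [(str(ids[i]), float(err[i])) for i in order[::-1]
            if abs(err[i]) <= 0.2 * rmse]
    return OutlierReport(rmse=rmse, threshold=thr, outliers=outliers, best=best)


def leave_out_metrics(y, y_pred, ids: Sequence[str],
                      removals: Sequence[str]) -> list[MetricsReport]:
    """Metrics after cumulatively removing the named compounds one at a time.

    Element 0 is the full set; element i the set with the first i removal
    ids excluded (mirrors the outlier-removal table of the analysis).
    """
    ids = [str(i) for i in ids]
    unknown = set(removals) - set(ids)
    if unknown:
        raise ValueError(f"unknown removal id(s): {sorted(unknown)}")
    y = np.asarray(y, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    reports = [compute_metrics(y, y_pred)]
    gone: set[str] = set()
    for rid in removals:
        gone.add(rid)
        mask = np.array([i not in gone for i in ids])
        reports.append(compute_metrics(y[mask], y_pred[mask]))
    return reports


def compare_strategies(log_records: pd.DataFrame, descriptors: pd.DataFrame,
                       test_sets: Mapping[str, pd.DataFrame],
                       config: MlpConfig | None = None, top_k: int = 10,
                       prune_threshold: float = 0.8,
                       strategies: Sequence[str] = ("mean", "median", "all")
                       ) -> dict[str, dict[str, MetricsReport]]:
    """Train one model per replicate-handling strategy, score shared test sets.

    ``log_records`` must already be in log molar (column ``log_s0``); test
    tables need ``logS0`` plus the descriptor columns.  The same seed
    protocol is used for every strategy so differences reflect the training
    table alone.
    """
    config = config or MlpConfig()
    out: dict[str, dict[str, MetricsReport]] = {}
    for strategy in strategies:
        agg = aggregate_replicates(log_records, strategy=strategy)
        table = agg.merge(descriptors, on="compound_id", how="left")
        desc_names = [c for c in descriptors.columns if c != "compound_id"]
        table, _ = drop_incomplete_descriptors(table, desc_names)
        X, y = table[desc_names], table["logS0"].to_numpy()
        feats = select_top_k(X, pd.Series(y), k=top_k, threshold=prune_threshold).selected
        scaling = fit_scaling(X[feats], y)
        model = train_mlp(scaling.transform_features(X[feats]),
                          scaling.transform_target(y), config,
                          scaling=scaling, feature_names=feats)
        out[strategy] = {name: compute_metrics(ts["logS0"].to_numpy(), model.predict(ts))
                         for name, ts in test_sets.items()}
    return out


def residual_table(ids: Sequence[str], y, y_pred) -> pd.DataFrame:
    """Per-compound residual CSV payload (compound_id, y, y_pred, error)."""
    y = np.asarray(y, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    return pd.DataFrame({"compound_id": list(ids), "y": y, "y_pred": y_pred,
                         "error": y - y_pred})


def write_report(path, metrics: Mapping[str, MetricsReport],
                 outliers: Mapping[str, OutlierReport] | None = None) -> None:
    payload: dict = {"metrics": {k: m.to_dict() for k, m in metrics.items()}}
    if outliers:
        payload["outliers"] = {k: o.to_dict() for k, o in outliers.items()}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
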