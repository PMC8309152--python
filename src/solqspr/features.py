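"""Descriptor filtering, correlation-based selection and min-max scaling.

Selection proceeds in three steps on the curated training table only:

1. :func:`drop_zero_variance` removes descriptors constant across all
   training compounds (exact zero variance);
2. :func:`correlation_prune` removes one member of every descriptor pair
   with absolute Pearson correlation above a threshold (default 0.8),
   keeping the member more correlated with logS0;
3. :func:`select_top_k` ranks the survivors by |Pearson r with logS0| and
   keeps the top k (default 10).

Scaling maps every retained descriptor, and the target, into (0, 1) by the
training min and max:  d' = (d - min) / (max - min).  Test tables are
scaled with the *training* statistics and may fall outside [0, 1]; they are
deliberately not clipped.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "FeatureSelection",
    "ScalingParams",
    "drop_zero_variance",
    "correlation_prune",
    "select_top_k",
    "fit_scaling",
]


def drop_zero_variance(table: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Remove columns with a single distinct value (literal zero variance)."""
    constant = [c for c in table.columns if table[c].nunique(dropna=False) <= 1]
    out = table.drop(columns=constant)
    if out.shape[1] == 0:
        raise ValueError("all descriptors have zero variance")
    return out, constant


def _target_corr(table: pd.DataFrame, target: pd.Series) -> pd.Series:
    y = np.asarray(target, dtype=float)
    corr = {}
    for c in table.columns:
        x = table[c].to_numpy(dtype=float)
        if x.std() == 0:
            raise ValueError(
                f"descriptor {c!r} is constant; remove zero-variance columns first")
        corr[c] = float(np.corrcoef(x, y)[0, 1])
    return pd.Series(corr)


@dataclass
class FeatureSelection:
    """Record of the full selection pipeline for one training table."""

    removed_zero_variance: list[str] = field(default_factory=list)
    #: (kept, dropped, pairwise r) per pruning step
    removed_correlated: list[tuple[str, str, float]] = field(default_factory=list)
    #: (name, signed r with target) in descending |r|
    ranked: list[tuple[str, float]] = field(default_factory=list)
    selected: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        """Selection report table (name, correlation with target, selected?)."""
        return pd.DataFrame(
            [{"name": n, "corr_with_target": r, "selected": n in set(self.selected)}
             for n, r in self.ranked])


def correlation_prune(table: pd.DataFrame, target: pd.Series,
                      threshold: float = 0.8) -> tuple[list[str], list[tuple[str, str, float]]]:
    """Iteratively break up descriptor pairs with |pairwise r| > threshold.

    At each step the currently most-correlated violating pair is found and
    its member with the smaller |r with target| is dropped (ties broken
    lexicographically: equal target correlations keep the alphabetically
    first name; equal pairwise correlations resolve the alphabetically
    first pair).  Returns the surviving column names (input order) and the
    (kept, dropped, r) log.
    """
    if len(table) < 2:
        raise ValueError("need at least two compounds to compute correlations")
    tcorr = _target_corr(table, target).abs()
    corr = table.corr(method="pearson")
    active = list(table.columns)
    removed: list[tuple[str, str, float]] = []
    while True:
        best_pair = None
        best_abs = threshold
        for i, a in enumerate(active):
            for b in active[i + 1:]:
                r = corr.loc[a, b]
                pair = tuple(sorted((a, b)))
                if abs(r) > best_abs or (best_pair is not None
                                         and abs(r) == best_abs
                                         and pair < best_pair):
                    best_pair, best_abs, best_r = pair, abs(r), float(r)
        if best_pair is None:
            break
        a, b = best_pair
        if tcorr[a] > tcorr[b]:
            keep, drop = a, b
        elif tcorr[b] > tcorr[a]:
            keep, drop = b, a
        else:
            keep, drop = sorted((a, b))  # tie: alphabetical keep
        removed.append((keep, drop, best_r))
        active.remove(drop)
    return active, removed


def select_top_k(table: pd.DataFrame, target: pd.Series, k: int = 10,
                 threshold: float = 0.8,
                 prune: bool = True) -> FeatureSelection:
    """Full selection: zero-variance filter, pruning, then top-k by |r|.

    ``ranked`` lists every pruning survivor with its signed Pearson r in
    descending |r| (ties alphabetical); ``selected`` is the first k.
    """
    table, constant = drop_zero_variance(table)
    if prune:
        survivors, removed_pairs = correlation_prune(table, target, threshold)
    else:
        survivors, removed_pairs = list(table.columns), []
    if k > len(survivors):
        raise ValueError(f"k={k} exceeds the {len(survivors)} available descriptors")
    signed = _target_corr(table[survivors], target)
    order = sorted(survivors, key=lambda n: (-abs(signed[n]), n))
    ranked = [(n, float(signed[n])) for n in order]
    return FeatureSelection(removed_zero_variance=constant,
                            removed_correlated=removed_pairs,
                            ranked=ranked,
                            selected=order[:k])


@dataclass
class ScalingParams:
    """Training min/max per feature and for the target (the (0,1) map).

    Fitted on the training set only; applying to other tables can produce
    values outside [0, 1], which is intentional.
    """

    feature_min: dict[str, float]
    feature_max: dict[str, float]
    target_min: float
    target_max: float

    @property
    def feature_names(self) -> list[str]:
        return list(self.feature_min)

    def _check(self, table: pd.DataFrame) -> None:
        missing = [c for c in self.feature_names if c not in table.columns]
        if missing:
            raise ValueError(f"table missing scaled feature column(s): {missing}")

    def transform_features(self, table: pd.DataFrame) -> pd.DataFrame:
        self._check(table)
        out = {}
        for c in self.feature_names:
            lo, hi = self.feature_min[c], self.feature_max[c]
            out[c] = (table[c].to_numpy(dtype=float) - lo) / (hi - lo)
        return pd.DataFrame(out, index=table.index)

    def transform_target(self, y) -> np.ndarray:
        y = np.asarray(y, dtype=float)
        return (y - self.target_min) / (self.target_max - self.target_min)

    def inverse_target(self, scaled) -> np.ndarray:
        scaled = np.asarray(scaled, dtype=float)
        return self.target_min + scaled * (self.target_max - self.target_min)

    def to_dict(self) -> dict:
        return {"feature_min": self.feature_min, "feature_max": self.feature_max,
                "target_min": self.target_min, "target_max": self.target_max}

    @classmethod
    def from_dict(cls, d: dict) -> "ScalingParams":
        return cls(feature_min=dict(d["feature_min"]), feature_max=dict(d["feature_max"]),
                   target_min=float(d["target_min"]), target_max=float(d["target_max"]))

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_json(cls, path) -> "ScalingParams":
        return cls.from_dict(json.loads(Path(path).read_text()))


def fit_scaling(table: pd.DataFrame, target) -> ScalingParams:
    """Fit per-feature and target min/max on the training table."""
    y = np.asarray(target, dtype=float)
    if y.max() == y.min():
        raise ValueError("target has zero range; cannot scale")
    fmin, fmax = {}, {}
    for c in table.columns:
        x = table[c].to_numpy(dtype=float)
        lo, hi = float(x.min()), float(x.max())
        if hi == lo:
            raise ValueError(f"feature {c!r} has zero range; drop it before scaling")
        fmin[c], fmax[c] = lo, hi
    return ScalingParams(feature_min=fmin, feature_max=fmax,
                         target_min=float(y.min()), target_max=float(y.max()))
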