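"""Curation of literature intrinsic-solubility records.

Published intrinsic solubility (S0) values arrive in heterogeneous
concentration units (molar, log molar, mass-per-volume) and many molecules
carry several inter-laboratory replicates, sometimes including distinct
polymorphic forms measured separately.  This module turns such raw records
into one training table with a single aggregated logS0 (log10 mol/L) per
molecule:

1. convert every value to log10 molar (:func:`to_log_molar`);
2. aggregate per-molecule replicates by mean, median, an explicit
   most-trusted override, or keep all rows (:func:`aggregate_replicates`);
3. remove molecules that also appear in a held-out test set
   (:func:`remove_test_overlap`);
4. drop molecules with any undefined descriptor value
   (:func:`drop_incomplete_descriptors`);
5. summarise the replicate structure and the inter-laboratory standard
   deviation (:func:`replicate_summary`).

Polymorph-labelled entries of the same compound are treated as ordinary
replicates.  Compound identity is the supplied ``compound_id`` string (a CAS
number in typical use); no name resolution is attempted.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "VALID_UNITS",
    "ConversionError",
    "ValidationError",
    "ReplicateSummary",
    "CuratedDataset",
    "to_log_molar",
    "records_to_log_molar",
    "aggregate_replicates",
    "remove_test_overlap",
    "drop_incomplete_descriptors",
    "replicate_summary",
    "curate",
    "read_records_csv",
    "write_curated_csv",
]

RECORD_COLUMNS = ["compound_id", "cas", "source_id", "value", "unit", "mw", "polymorph"]

#: factor turning one unit of the given mass concentration into g/L
_MASS_UNITS_G_PER_L = {"mg_per_mL": 1.0, "ug_per_mL": 1e-3, "g_per_L": 1.0}

VALID_UNITS = frozenset({"log_molar", "molar"} | set(_MASS_UNITS_G_PER_L))


class ValidationError(ValueError):
    """A record violates a structural invariant (bad unit, non-positive value...)."""


class ConversionError(ValueError):
    """A record cannot be converted to log molar (e.g. missing molecular weight)."""


def to_log_molar(value: float, unit: str, molecular_weight: float | None = None,
                 record_id: str | None = None) -> float:
    """Convert one solubility value to log10 molar.

    ``log_molar`` values pass through unchanged.  Mass-based units require a
    positive molecular weight (g/mol).

    Parameters
    ----------
    value
        The reported solubility; must be > 0 for all non-log units.
    unit
        One of :data:`VALID_UNITS`.
    molecular_weight
        g/mol; required for ``mg_per_mL``, ``ug_per_mL`` and ``g_per_L``.
    record_id
        Optional label used in error messages.
    """
    tag = f" (record {record_id})" if record_id is not None else ""
    if unit not in VALID_UNITS:
        raise ValidationError(f"unknown unit {unit!r}{tag}")
    value = float(value)
    if unit == "log_molar":
        if not math.isfinite(value):
            raise ValidationError(f"non-finite log_molar value{tag}")
        return value
    if not (math.isfinite(value) and value > 0):
        raise ValidationError(f"non-positive value {value!r} for unit {unit!r}{tag}")
    if unit == "molar":
        return math.log10(value)
    # mass-based unit
    if molecular_weight is None or not math.isfinite(molecular_weight) or molecular_weight <= 0:
        raise ConversionError(
            f"molecular weight required to convert {unit!r} to molarity{tag}")
    g_per_l = value * _MASS_UNITS_G_PER_L[unit]
    return math.log10(g_per_l / molecular_weight)


def _check_duplicates(records: pd.DataFrame) -> None:
    key = ["compound_id", "source_id", "polymorph", "value"]
    dup = records.duplicated(subset=key, keep=False)
    if dup.any():
        rows = records.loc[dup, key].head(10)
        raise ValidationError(
            "identical duplicate records (same compound, source, polymorph and "
            f"value) are rejected as data errors:\n{rows.to_string(index=False)}")


def records_to_log_molar(records: pd.DataFrame) -> pd.DataFrame:
    """Vectorised record table conversion.

    Expects the columns ``compound_id, cas, source_id, value, unit, mw,
    polymorph`` (missing optional columns are added empty) and returns a copy
    with a ``log_s0`` column in log10 molar.  Identical duplicate rows raise.
    """
    records = records.copy()
    for col in RECORD_COLUMNS:
        if col not in records.columns:
            if col in ("value", "unit", "compound_id"):
                raise ValidationError(f"records table missing required column {col!r}")
            records[col] = np.nan
    _check_duplicates(records)
    log_s0 = [
        to_log_molar(row.value, row.unit,
                     None if pd.isna(row.mw) else float(row.mw),
                     record_id=str(row.compound_id))
        for row in records.itertuples()
    ]
    records["log_s0"] = log_s0
    return records


@dataclass
class ReplicateSummary:
    """Replicate-count histogram and inter-laboratory variability.

    ``mean_interlab_sd`` is the unweighted mean over molecules with >= 2
    replicates of the per-molecule sample standard deviation (n-1
    denominator); ``None`` when no molecule is replicated.
    """

    histogram: dict[int, int]
    n_molecules: int
    n_values: int
    mean_interlab_sd: float | None

    def to_dict(self) -> dict:
        return {
            "histogram": {str(k): v for k, v in sorted(self.histogram.items())},
            "n_molecules": self.n_molecules,
            "n_values": self.n_values,
            "mean_interlab_sd": self.mean_interlab_sd,
        }


def replicate_summary(log_records: pd.DataFrame) -> ReplicateSummary:
    """Summarise replicate structure of a log-molar record table.

    Parameters
    ----------
    log_records
        One row per measurement with columns ``compound_id`` and ``log_s0``.
    """
    groups = log_records.groupby("compound_id")["log_s0"]
    counts = groups.size()
    histogram = counts.value_counts().sort_index()
    sds = groups.std(ddof=1)  # NaN for singletons
    replicated = sds.dropna()
    mean_sd = float(replicated.mean()) if len(replicated) else None
    return ReplicateSummary(
        histogram={int(k): int(v) for k, v in histogram.items()},
        n_molecules=int(len(counts)),
        n_values=int(counts.sum()),
        mean_interlab_sd=mean_sd,
    )


def aggregate_replicates(log_records: pd.DataFrame, strategy: str = "mean",
                         overrides: Mapping[str, float] | None = None) -> pd.DataFrame:
    """Aggregate per-molecule replicate logS0 values.

    Parameters
    ----------
    log_records
        One row per measurement, columns ``compound_id`` and ``log_s0``.
    strategy
        ``"mean"`` or ``"median"`` give one row per molecule; ``"all"`` keeps
        one row per replicate (each carrying the molecule's id, for designs
        that train on every literature value); ``"manual"`` uses an explicit
        most-trusted value per compound from *overrides*, falling back to the
        mean where no override is given.
    overrides
        compound_id -> trusted logS0, only for ``strategy="manual"``.

    Returns
    -------
    DataFrame with columns ``compound_id, logS0, n_replicates``.
    """
    if log_records.empty:
        raise ValidationError("no records to aggregate")
    if strategy not in ("mean", "median", "all", "manual"):
        raise ValidationError(f"unknown aggregation strategy {strategy!r}")
    groups = log_records.groupby("compound_id", sort=True)["log_s0"]
    n = groups.size().rename("n_replicates")
    if strategy == "all":
        out = log_records[["compound_id", "log_s0"]].rename(columns={"log_s0": "logS0"})
        out = out.merge(n, on="compound_id")
        return out.sort_values(["compound_id", "logS0"], kind="stable").reset_index(drop=True)
    if strategy == "mean":
        agg = groups.mean()
    elif strategy == "median":
        agg = groups.median()
    else:  # manual
        agg = groups.mean()
        overrides = dict(overrides or {})
        unknown = set(overrides) - set(agg.index)
        if unknown:
            raise ValidationError(f"override for unknown compound(s): {sorted(unknown)}")
        for cid, val in overrides.items():
            agg.loc[cid] = float(val)
    out = pd.DataFrame({"compound_id": agg.index, "logS0": agg.values})
    return out.merge(n, on="compound_id").reset_index(drop=True)


def remove_test_overlap(training: pd.DataFrame, test_ids: Iterable[str]
                        ) -> tuple[pd.DataFrame, list[str]]:
    """Drop training molecules whose ``compound_id`` occurs in any test set.

    Returns the filtered table and the sorted list of removed ids.
    Idempotent; an empty overlap is allowed.
    """
    test_ids = set(test_ids)
    mask = training["compound_id"].isin(test_ids)
    removed = sorted(training.loc[mask, "compound_id"].unique())
    out = training.loc[~mask].reset_index(drop=True)
    if out.empty and not training.empty:
        warnings.warn("test overlap removal left an empty training set", stacklevel=2)
    return out, removed


def drop_incomplete_descriptors(dataset: pd.DataFrame,
                                descriptor_names: Sequence[str] | None = None
                                ) -> tuple[pd.DataFrame, list[str]]:
    """Remove molecules with an undefined value for at least one descriptor.

    ``descriptor_names`` defaults to every column except
    ``compound_id, logS0, n_replicates``.  Raises if nothing survives.
    """
    if descriptor_names is None:
        descriptor_names = [c for c in dataset.columns
                            if c not in ("compound_id", "logS0", "n_replicates")]
    bad = dataset[list(descriptor_names)].isna().any(axis=1)
    removed = sorted(dataset.loc[bad, "compound_id"].unique())
    out = dataset.loc[~bad].reset_index(drop=True)
    if out.empty:
        raise ValidationError("all molecules removed: every row has an undefined descriptor")
    return out, removed


@dataclass
class CuratedDataset:
    """Output of the full curation pipeline.

    ``table`` has one row per molecule (or per replicate for
    ``strategy='all'``) with ``compound_id, logS0, n_replicates`` followed by
    the descriptor columns; ``summary`` describes the replicate structure of
    the post-overlap-removal record table; ``log`` carries record counts at
    each filtering step.
    """

    table: pd.DataFrame
    descriptor_names: list[str]
    summary: ReplicateSummary
    strategy: str
    log: dict = field(default_factory=dict)

    @property
    def X(self) -> pd.DataFrame:
        return self.table[self.descriptor_names]

    @property
    def y(self) -> pd.Series:
        return self.table["logS0"]


def curate(records: pd.DataFrame, descriptors: pd.DataFrame,
           test_ids: Iterable[str] = (), strategy: str = "mean",
           overrides: Mapping[str, float] | None = None) -> CuratedDataset:
    """Run the full curation chain on raw records plus a descriptor table.

    Steps: unit conversion -> test-overlap removal (on the record table, so
    the replicate summary reflects the retained molecules) -> replicate
    aggregation -> descriptor join -> incomplete-descriptor removal.
    """
    log: dict = {"n_input_records": int(len(records))}
    recs = records_to_log_molar(records)
    recs, overlap = remove_test_overlap(recs, test_ids)
    log["n_test_overlap_removed"] = len(overlap)
    log["test_overlap_ids"] = overlap
    log["n_records_after_overlap"] = int(len(recs))

    desc_names = [c for c in descriptors.columns if c != "compound_id"]
    missing = set(recs["compound_id"]) - set(descriptors["compound_id"])
    if missing:
        raise ValidationError(
            f"{len(missing)} curated compound(s) missing from the descriptor table, "
            f"e.g. {sorted(missing)[:5]}")

    agg = aggregate_replicates(recs, strategy=strategy, overrides=overrides)
    table = agg.merge(descriptors, on="compound_id", how="left")
    table, incomplete = drop_incomplete_descriptors(table, desc_names)
    log["n_incomplete_descriptor_removed"] = len(incomplete)
    log["incomplete_descriptor_ids"] = incomplete

    # summary over the records of retained molecules only
    kept = set(table["compound_id"])
    summary = replicate_summary(recs[recs["compound_id"].isin(kept)])
    log["n_molecules"] = int(table["compound_id"].nunique())
    log["n_rows"] = int(len(table))
    log["n_log_values"] = summary.n_values
    return CuratedDataset(table=table, descriptor_names=desc_names,
                          summary=summary, strategy=strategy, log=log)


def read_records_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"compound_id": str, "cas": str, "source_id": str,
                                  "unit": str, "polymorph": str})
    return df


def write_curated_csv(dataset: CuratedDataset, path) -> None:
    dataset.table.to_csv(path, index=False)


def write_curation_report(dataset: CuratedDataset, path) -> None:
    report = {"strategy": dataset.strategy,
              "summary": dataset.summary.to_dict(),
              "log": dataset.log}
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2)
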