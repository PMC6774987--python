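"""Acoustic unit measurements, naming-consistency check and substitution costs.

Each unit type carries 11 frequency/duration measurements (duration, min/max/
peak/start/end frequency, bandwidth, frequency trend and range ratios, number
of inflections, pulse repetition rate).  These serve two purposes: a
decision-tree classification check that human unit naming is acoustically
consistent, and the substitution-cost matrix that weights the phrase-level
edit distance so that swapping one unit for an acoustically similar one costs
less than swapping it for a dissimilar one.

Costs are per-pair mean absolute differences of min-max-normalized feature
centroids (per-label medians), so they always lie in [0, 1]; insertions and
deletions cost a fixed 1.  A cost matrix can also be loaded from CSV when
costs derived elsewhere should be substituted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "FEATURE_NAMES",
    "MeasurementError",
    "UnitFeatureTable",
    "CostMatrix",
    "read_measurements",
    "substitution_costs",
    "costs_from_centroids",
    "classification_consistency",
    "ConsistencyResult",
]

#: The 11 per-unit acoustic measurements, in CSV column order.
FEATURE_NAMES = (
    "duration_s",
    "min_freq_hz",
    "max_freq_hz",
    "bandwidth_hz",
    "peak_freq_hz",
    "start_freq_hz",
    "end_freq_hz",
    "freq_trend_ratio",
    "freq_range_ratio",
    "n_inflections",
    "pulse_rate_hz",
)

BANDWIDTH_TOL_HZ = 1.0


class MeasurementError(ValueError):
    """Invalid unit measurement data."""


@dataclass
class UnitFeatureTable:
    """Long-format table of unit measurements (several exemplars per label).

    ``data`` has a ``unit_label`` column plus the 11 feature columns.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        expected = ("unit_label",) + FEATURE_NAMES
        if tuple(self.data.columns) != expected:
            raise MeasurementError(
                f"expected columns {expected}, found {tuple(self.data.columns)}"
            )
        if len(self.data) == 0:
            raise MeasurementError("measurement table is empty")
        _validate_rows(self.data)

    @property
    def labels(self) -> list[str]:
        seen: dict[str, None] = {}
        for lab in self.data["unit_label"]:
            seen.setdefault(lab, None)
        return list(seen)

    def centroids(self) -> pd.DataFrame:
        """Per-label feature centroids: the median over exemplars.

        The median keeps rare unit types with few (even single) exemplars
        from being dominated by one noisy measurement.
        """
        return (
            self.data.groupby("unit_label", sort=False)[list(FEATURE_NAMES)]
            .median()
        )


def _validate_rows(df: pd.DataFrame) -> None:
    feats = df[list(FEATURE_NAMES)]
    if not np.issubdtype(np.asarray(feats).dtype, np.number):
        raise MeasurementError("non-numeric feature values")
    arr = feats.to_numpy(dtype=float)
    if not np.all(np.isfinite(arr)):
        bad = df.index[~np.isfinite(arr).all(axis=1)][0]
        raise MeasurementError(f"row {bad}: non-finite feature value")
    for i, row in df.iterrows():
        if row["duration_s"] <= 0:
            raise MeasurementError(f"row {i}: duration must be > 0")
        lo, hi, pk = row["min_freq_hz"], row["max_freq_hz"], row["peak_freq_hz"]
        if min(lo, hi, pk, row["start_freq_hz"], row["end_freq_hz"]) <= 0:
            raise MeasurementError(f"row {i}: frequencies must be > 0")
        if not (lo <= pk <= hi):
            raise MeasurementError(
                f"row {i}: requires min_freq <= peak_freq <= max_freq"
            )
        if row["n_inflections"] < 0 or row["pulse_rate_hz"] < 0:
            raise MeasurementError(f"row {i}: counts and rates must be >= 0")
        if abs(row["bandwidth_hz"] - (hi - lo)) > BANDWIDTH_TOL_HZ:
            warnings.warn(
                f"row {i}: bandwidth {row['bandwidth_hz']:.1f} Hz differs from "
                f"max-min {hi - lo:.1f} Hz by more than {BANDWIDTH_TOL_HZ} Hz",
                stacklevel=3,
            )


def read_measurements(path: str | Path) -> UnitFeatureTable:
    """Read and validate the unit-measurement CSV (label + 11 features)."""
    df = pd.read_csv(path)
    expected = ("unit_label",) + FEATURE_NAMES
    if tuple(df.columns) != expected:
        raise MeasurementError(
            f"{path}: expected columns {expected}, found {tuple(df.columns)}"
        )
    try:
        df[list(FEATURE_NAMES)] = df[list(FEATURE_NAMES)].astype(float)
    except (TypeError, ValueError) as exc:
        raise MeasurementError(f"{path}: non-numeric feature value ({exc})") from None
    df["unit_label"] = df["unit_label"].astype(str)
    return UnitFeatureTable(data=df)


@dataclass
class CostMatrix:
    """Symmetric unit-substitution costs in [0, 1]; indels cost ``indel_cost``."""

    labels: tuple[str, ...]
    costs: np.ndarray
    indel_cost: float = 1.0
    _index: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.costs = np.asarray(self.costs, dtype=float)
        n = len(self.labels)
        if self.costs.shape != (n, n):
            raise ValueError(f"cost matrix shape {self.costs.shape} != ({n}, {n})")
        if not np.allclose(self.costs, self.costs.T, atol=1e-12):
            raise ValueError("cost matrix must be symmetric")
        if np.any(np.diag(self.costs) != 0):
            raise ValueError("cost matrix diagonal must be 0")
        if self.costs.min() < 0 or self.costs.max() > 1:
            raise ValueError("substitution costs must lie in [0, 1]")
        self._index = {lab: i for i, lab in enumerate(self.labels)}
        if len(self._index) != n:
            raise ValueError("duplicate labels in cost matrix")

    def cost(self, a: str, b: str) -> float:
        try:
            return float(self.costs[self._index[a], self._index[b]])
        except KeyError as exc:
            raise KeyError(f"unit label {exc.args[0]!r} not in cost matrix") from None

    def index_of(self, label: str) -> int:
        try:
            return self._index[label]
        except KeyError:
            raise KeyError(f"unit label {label!r} not in cost matrix") from None

    def is_metric(self, atol: float = 1e-9) -> bool:
        """Whether costs satisfy the triangle inequality on the inventory.

        When true, the weighted edit distance of :mod:`levensong.seqsim` is a
        metric on unit sequences.
        """
        c = self.costs
        n = len(self.labels)
        for k in range(n):
            if np.any(c > c[:, [k]] + c[[k], :] + atol):
                return False
        return True

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.costs, index=list(self.labels), columns=list(self.labels)).to_csv(
            path, float_format="%.6f"
        )

    @classmethod
    def from_csv(cls, path: str | Path, indel_cost: float = 1.0) -> "CostMatrix":
        df = pd.read_csv(path, index_col=0)
        if list(df.index) != list(df.columns):
            raise ValueError(f"{path}: row and column labels differ")
        vals = df.to_numpy(dtype=float)
        # round-trip through fixed-point CSV can break symmetry in the last ulp
        vals = (vals + vals.T) / 2.0
        np.fill_diagonal(vals, 0.0)
        return cls(labels=tuple(str(c) for c in df.columns), costs=vals,
                   indel_cost=indel_cost)


def costs_from_centroids(centroids: pd.DataFrame) -> CostMatrix:
    """Substitution costs from per-label feature centroids.

    Each feature is min-max normalized to [0, 1] across centroids; the cost
    of substituting label *x* for *y* is the mean absolute normalized
    difference over the features.  Features constant across all labels carry
    no information and are dropped from the mean with a warning.  The
    construction is invariant to affine rescaling of any input feature.
    """
    if len(centroids) < 2:
        raise MeasurementError("need at least 2 unit labels to derive costs")
    vals = centroids.to_numpy(dtype=float)
    lo = vals.min(axis=0)
    rng = vals.max(axis=0) - lo
    keep = rng > 0
    if not keep.all():
        dropped = [c for c, k in zip(centroids.columns, keep) if not k]
        warnings.warn(
            f"features constant across labels dropped from costs: {dropped}",
            stacklevel=2,
        )
    if not keep.any():
        raise MeasurementError("all features constant across labels")
    norm = (vals[:, keep] - lo[keep]) / rng[keep]
    diff = np.abs(norm[:, None, :] - norm[None, :, :]).mean(axis=2)
    np.fill_diagonal(diff, 0.0)
    return CostMatrix(labels=tuple(centroids.index), costs=diff)


def substitution_costs(table: UnitFeatureTable) -> CostMatrix:
    """Cost matrix from a measurement table (centroids = per-label medians)."""
    return costs_from_centroids(table.centroids())


@dataclass
class ConsistencyResult:
    """Outcome of the unit-naming consistency check."""

    agreement: float
    confusion: pd.DataFrame
    excluded_labels: list[str]


def classification_consistency(
    table: UnitFeatureTable, seed: int = 0, n_splits: int = 5
) -> ConsistencyResult:
    """Cross-validated decision-tree check that unit naming is consistent.

    Fits a CART-style decision tree predicting the human-assigned unit label
    from the 11 acoustic features and returns the fraction of exemplars whose
    cross-validated prediction agrees with the human label, plus a confusion
    table.  Labels with a single exemplar cannot be cross-validated and are
    excluded with a warning.  Deterministic for a fixed ``seed``.
    """
    from sklearn.model_selection import StratifiedKFold, cross_val_predict
    from sklearn.tree import DecisionTreeClassifier

    df = table.data
    counts = df["unit_label"].value_counts()
    excluded = sorted(counts.index[counts < 2])
    if excluded:
        warnings.warn(
            f"labels with a single exemplar excluded from consistency check: "
            f"{excluded}",
            stacklevel=2,
        )
        df = df[~df["unit_label"].isin(excluded)]
    if df["unit_label"].nunique() < 2:
        raise MeasurementError(
            "need >= 2 unit labels with >= 2 exemplars each"
        )
    X = df[list(FEATURE_NAMES)].to_numpy(dtype=float)
    y = df["unit_label"].to_numpy()
    n_splits = int(min(n_splits, df["unit_label"].value_counts().min()))
    cv = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    clf = DecisionTreeClassifier(random_state=seed)
    pred = cross_val_predict(clf, X, y, cv=cv)
    agreement = float(np.mean(pred == y))
    confusion = pd.crosstab(
        pd.Series(y, name="human"), pd.Series(pred, name="predicted")
    )
    return ConsistencyResult(
        agreement=agreement, confusion=confusion, excluded_labels=list(excluded)
    )
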