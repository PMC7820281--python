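"""Correlation-based feature ordering and per-partition feature selection.

Convolutional kernels act on adjacent inputs, so before a tabular feature
vector is fed to a 1D convolution the columns are permuted to place highly
correlated predictors next to each other. The permutation is the leaf order
of average-linkage agglomerative clustering on the distance 1 - |rho|, where
rho is the Pearson correlation between (filled) feature columns.

Determinism: features are pre-sorted lexically by name before clustering, so
the fitted order depends only on the set of names and the correlation values,
never on incidental input column order. The fitted order is frozen into the
model artifact so scoring reorders exactly as training did.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import squareform

from .variants import FeatureMatrix


@dataclass(frozen=True)
class FeatureOrder:
    """A fitted permutation of feature names plus how it was obtained."""

    names: tuple[str, ...]
    method: Mapping[str, str] = field(
        default_factory=lambda: {"correlation": "pearson", "linkage": "average"}
    )

    def __post_init__(self) -> None:
        if len(set(self.names)) != len(self.names):
            raise ValueError("feature order contains duplicate names")

    def apply(self, fm: FeatureMatrix) -> FeatureMatrix:
        return fm.reorder(list(self.names))

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump({"names": list(self.names), "method": dict(self.method)}, fh, indent=1)

    @classmethod
    def from_json(cls, path: str | Path) -> "FeatureOrder":
        with open(path) as fh:
            d = json.load(fh)
        return cls(names=tuple(d["names"]), method=d.get("method", {}))


def feature_correlation(fm: FeatureMatrix | pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation between feature columns.

    A zero-variance feature is assigned correlation 0 with every other
    feature (and 1 with itself) instead of propagating NaN.
    """
    data = fm.data if isinstance(fm, FeatureMatrix) else fm
    if data.shape[1] < 2:
        raise ValueError("feature correlation requires at least 2 features")
    corr = data.corr(method="pearson")
    corr = corr.fillna(0.0)
    np.fill_diagonal(corr.values, 1.0)
    return corr


def order_features(corr: pd.DataFrame) -> FeatureOrder:
    """Leaf order of average-linkage clustering on distance 1 - |rho|.

    Any two features with |rho| = 1 merge at distance 0 and end up adjacent.
    Ties are broken by lexical feature-name order (columns are pre-sorted by
    name), making the result invariant to input column shuffling.
    """
    values = corr.to_numpy(dtype=float)
    if values.shape[0] != values.shape[1]:
        raise ValueError("correlation matrix must be square")
    if not np.allclose(values, values.T, atol=1e-12):
        raise ValueError("correlation matrix must be symmetric")
    if np.any(np.abs(values) > 1.0 + 1e-12):
        raise ValueError("correlation entries must lie in [-1, 1]")

    names = sorted(map(str, corr.columns))
    c = corr.loc[names, names].to_numpy(dtype=float)
    if len(names) == 2:
        return FeatureOrder(names=tuple(names))

    dist = 1.0 - np.abs(c)
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    condensed = squareform(dist, checks=False)
    if np.all(condensed == condensed[0]):
        # fully degenerate (e.g. identity correlation): every order is
        # equally good; keep the lexical order rather than an incidental
        # merge order
        return FeatureOrder(names=tuple(names))
    z = linkage(condensed, method="average")
    order = leaves_list(z)
    return FeatureOrder(names=tuple(names[i] for i in order))


def fit_feature_order(fm: FeatureMatrix) -> FeatureOrder:
    """Convenience: correlation + clustering in one step."""
    return order_features(feature_correlation(fm))


def select_features(
    fm: FeatureMatrix,
    partition_tag: str,
    config: Mapping[str, Sequence[str]],
) -> FeatureMatrix:
    """Restrict a feature matrix to the configured feature set of a partition.

    Two gene classes use different feature sets (the constrained-gene model
    uses more conservation and published-predictor features than the
    non-constrained one); ``config`` maps partition tag -> feature names.
    """
    if partition_tag not in config:
        raise KeyError(f"no feature config for partition {partition_tag!r}")
    names = list(config[partition_tag])
    if not names:
        raise ValueError(f"feature config for {partition_tag!r} is empty")
    try:
        return fm.select(names)
    except KeyError as exc:
        raise KeyError(f"partition {partition_tag!r}: {exc}") from None


def adjacent_correlation_sum(corr: pd.DataFrame, order: Sequence[str]) -> float:
    """Sum of |rho| over adjacent pairs under ``order`` (ordering quality)."""
    a = corr.loc[list(order), list(order)].to_numpy(dtype=float)
    return float(np.sum(np.abs(np.diag(a, k=1))))
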