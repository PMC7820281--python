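"""Rank-percentile normalization of raw network outputs and threshold calls.

A raw sigmoid output is only meaningful relative to other variants, so the
reported score is the rank percentile of the raw value within a declared
*universe* — a large collection of raw scores standing in for all possible
missense variants. Higher percentile = more damaging; e.g. a score of 0.75
means the variant outranks 75% of the universe. Ties take midrank weight
(half credit), which keeps the self-percentiles of any universe centred at
exactly 0.5.

Pathogenic/benign calls use partition-specific percentile thresholds
(0.70 in constrained genes, 0.75 in non-constrained genes by default,
the optimal ROC operating points on cancer-hotspot data).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._defaults import (
    CONSTRAINED,
    NONCONSTRAINED,
    THRESHOLD_CONSTRAINED,
    THRESHOLD_NONCONSTRAINED,
)


@dataclass(frozen=True)
class ThresholdPolicy:
    """Percentile thresholds above which a variant is called pathogenic."""

    constrained: float = THRESHOLD_CONSTRAINED
    nonconstrained: float = THRESHOLD_NONCONSTRAINED

    def __post_init__(self) -> None:
        for name, t in (("constrained", self.constrained),
                        ("nonconstrained", self.nonconstrained)):
            if not (0.0 <= t <= 1.0):
                raise ValueError(f"{name} threshold must be in [0, 1], got {t}")

    def threshold_for(self, partition: str) -> float:
        if partition == CONSTRAINED:
            return self.constrained
        if partition == NONCONSTRAINED:
            return self.nonconstrained
        raise KeyError(f"unknown partition {partition!r}")


@dataclass
class ScoreSet:
    """Raw scores plus their rank percentiles relative to one universe."""

    keys: pd.DataFrame
    raw: np.ndarray
    percentile: np.ndarray
    universe_id: str = "universe"

    def __post_init__(self) -> None:
        if len(self.raw) != len(self.percentile) or len(self.raw) != len(self.keys):
            raise ValueError("keys, raw and percentile must have equal length")
        if np.any((self.percentile < 0) | (self.percentile > 1)):
            raise ValueError("percentiles must lie in [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        out = self.keys.reset_index(drop=True).copy()
        out["raw_score"] = self.raw
        out["mvp_rank_percentile"] = self.percentile
        return out


def rank_percentile(universe: np.ndarray, queries: np.ndarray) -> np.ndarray:
    """Midrank percentile of each query within the universe.

    percentile(q) = (#{u < q} + 0.5 * #{u == q}) / |universe|.
    """
    universe = np.asarray(universe, dtype=float)
    if universe.size == 0:
        raise ValueError("score universe is empty")
    queries = np.asarray(queries, dtype=float)
    srt = np.sort(universe)
    below = np.searchsorted(srt, queries, side="left")
    at_or_below = np.searchsorted(srt, queries, side="right")
    return (below + at_or_below) / (2.0 * universe.size)


def score_variants(
    keys: pd.DataFrame,
    raw: np.ndarray,
    universe: np.ndarray,
    universe_id: str = "universe",
) -> ScoreSet:
    """Bundle raw outputs with their percentiles in one universe."""
    return ScoreSet(
        keys=keys,
        raw=np.asarray(raw, dtype=float),
        percentile=rank_percentile(universe, raw),
        universe_id=universe_id,
    )


def classify(
    scores: ScoreSet | np.ndarray,
    partitions: Sequence[str],
    policy: ThresholdPolicy | None = None,
) -> np.ndarray:
    """Call each variant pathogenic/benign at its partition's threshold.

    Pathogenic iff percentile >= threshold (the printed operating points are
    themselves calls). Every variant must carry a partition tag.
    """
    policy = policy or ThresholdPolicy()
    pct = scores.percentile if isinstance(scores, ScoreSet) else np.asarray(scores, float)
    partitions = list(partitions)
    if len(partitions) != len(pct):
        raise ValueError("one partition tag required per variant")
    thresholds = np.array([policy.threshold_for(p) for p in partitions])
    return np.where(pct >= thresholds, "pathogenic", "benign")


def read_universe(path: str | Path, column: str = "raw_score") -> np.ndarray:
    """Read a score-universe file: a TSV with a raw-score column (or a
    single headerless column of floats)."""
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    if column in df.columns:
        return df[column].to_numpy(dtype=float)
    if df.shape[1] == 1:
        return pd.read_csv(path, sep="\t", header=None,
                           float_precision="round_trip").iloc[:, 0].to_numpy(float)
    raise ValueError(f"universe file lacks a {column!r} column")


def write_universe(path: str | Path, raw: np.ndarray) -> None:
    pd.DataFrame({"raw_score": np.asarray(raw, float)}).to_csv(
        path, sep="\t", index=False, float_format="%.17g"
    )


def write_scores(
    path: str | Path,
    scores: ScoreSet,
    calls: np.ndarray | None = None,
) -> None:
    """Write the score TSV: chrom,pos,ref,alt,raw_score,mvp_rank_percentile[,call]."""
    out = scores.to_frame()
    if calls is not None:
        out["call"] = calls
    out.to_csv(path, sep="\t", index=False, float_format="%.17g")
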