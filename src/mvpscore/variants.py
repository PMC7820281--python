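"""Variant tables: data model, TSV I/O, rarity filtering and gene partitioning.

A variant table is a delimited text file with one row per missense variant.
Identity columns (``chrom, pos, ref, alt, gene``, optionally ``transcript``)
plus optional annotations (``pli, maf, label``) come first; every remaining
column is a numeric feature. A YAML sidecar maps each feature name to one of
the six feature categories (local context, amino-acid constraint,
conservation, protein structure/interaction/modification, gene intolerance,
published predictor scores); the category determines the missing-value fill.

Coordinates are 1-based and alleles are VCF-style. A variant is keyed by
(chrom, pos, ref, alt, transcript).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from ._defaults import (
    COMPLEX_FILL_GROUPS,
    CONSTRAINED,
    FILL_COMPLEX,
    FILL_DEFAULT,
    MAF_THRESHOLD,
    NONCONSTRAINED,
    PLI_CONSTRAINED_CUT,
)

IDENTITY_COLUMNS = ("chrom", "pos", "ref", "alt", "gene")
OPTIONAL_COLUMNS = ("transcript", "pli", "maf", "label")
KEY_COLUMNS = ("chrom", "pos", "ref", "alt", "transcript")

VALID_LABELS = {"pathogenic", "benign", "unknown"}


class SchemaError(ValueError):
    """A table does not conform to the expected column schema."""


@dataclass(frozen=True)
class VariantRecord:
    """One missense variant with identity, annotations and optional label."""

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    transcript: str | None = None
    maf: float | None = None
    label: str = "unknown"

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")
        if self.maf is not None and not (0.0 <= self.maf <= 1.0):
            raise ValueError(f"maf must be in [0, 1], got {self.maf}")
        if self.label not in VALID_LABELS:
            raise ValueError(f"label must be one of {sorted(VALID_LABELS)}")

    @property
    def key(self) -> tuple:
        return (self.chrom, self.pos, self.ref, self.alt, self.transcript)


@dataclass(frozen=True)
class GeneInfo:
    """Gene-level annotation: symbol plus LoF-intolerance probability (pLI)."""

    gene: str
    pli: float | None = None
    shet: float | None = None

    def __post_init__(self) -> None:
        if self.pli is not None and not (0.0 <= self.pli <= 1.0):
            raise ValueError(f"pli must be in [0, 1], got {self.pli}")


@dataclass
class FeatureMatrix:
    """Variants x named numeric features, with per-feature group and fill tags.

    ``data`` holds one row per variant (index = positional row id aligned with
    the variant table) and one column per feature; NaN marks a missing cell
    prior to :func:`fill_missing`. ``groups`` maps feature name -> category
    tag; ``fills`` records the sentinel used per feature once filling has run.
    """

    data: pd.DataFrame
    groups: dict[str, str] = field(default_factory=dict)
    fills: dict[str, float] | None = None

    def __post_init__(self) -> None:
        if self.data.columns.duplicated().any():
            dupes = self.data.columns[self.data.columns.duplicated()].tolist()
            raise SchemaError(f"duplicate feature names: {dupes}")

    @property
    def feature_names(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def has_missing(self) -> bool:
        return bool(self.data.isna().any().any())

    def select(self, names: Sequence[str]) -> "FeatureMatrix":
        """Restrict to ``names`` in the given order; unknown names raise."""
        missing = [n for n in names if n not in self.data.columns]
        if missing:
            raise KeyError(f"features not present in table: {missing}")
        if len(names) == 0:
            raise ValueError("feature selection is empty")
        return FeatureMatrix(
            data=self.data.loc[:, list(names)].copy(),
            groups={n: self.groups[n] for n in names if n in self.groups},
            fills={n: self.fills[n] for n in names} if self.fills else None,
        )

    def reorder(self, names: Sequence[str]) -> "FeatureMatrix":
        if sorted(names) != sorted(self.data.columns):
            raise ValueError("reorder requires a permutation of the feature names")
        return self.select(names)


def read_variant_table(
    path: str | Path,
    *,
    sep: str = "\t",
    groups: Mapping[str, str] | str | Path | None = None,
) -> tuple[pd.DataFrame, FeatureMatrix]:
    """Read a variant feature table.

    Returns the variant identity/annotation frame and the feature matrix.
    Unparseable numeric feature cells become NaN (missing) rather than
    dropping the row. ``groups`` is either a mapping feature -> group tag or
    the path of a YAML sidecar holding that mapping.
    """
    df = pd.read_csv(path, sep=sep, dtype={"chrom": str}, float_precision="round_trip")
    missing = [c for c in IDENTITY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"required column(s) missing: {missing}")

    ident_cols = [c for c in IDENTITY_COLUMNS + OPTIONAL_COLUMNS if c in df.columns]
    variants = df[ident_cols].copy()
    variants["pos"] = pd.to_numeric(variants["pos"], errors="raise").astype(int)
    if "label" not in variants.columns:
        variants["label"] = "unknown"
    if "transcript" not in variants.columns:
        variants["transcript"] = pd.NA

    key_cols = [c for c in KEY_COLUMNS if c in variants.columns]
    if variants.duplicated(subset=key_cols).any():
        dup = variants[variants.duplicated(subset=key_cols)].iloc[0]
        raise SchemaError(
            f"duplicate variant key {tuple(dup[c] for c in key_cols)}"
        )

    feat_cols = [c for c in df.columns if c not in ident_cols]
    feats = df[feat_cols].apply(pd.to_numeric, errors="coerce")

    group_map: dict[str, str] = {}
    if groups is not None:
        if isinstance(groups, (str, Path)):
            with open(groups) as fh:
                group_map = dict(yaml.safe_load(fh) or {})
        else:
            group_map = dict(groups)

    return variants, FeatureMatrix(data=feats, groups=group_map)


def write_variant_table(
    path: str | Path,
    variants: pd.DataFrame,
    fm: FeatureMatrix | None = None,
    *,
    sep: str = "\t",
) -> None:
    """Write variants (and features, if given) back to delimited text.

    Floats are printed with 17 significant digits so a read-write-read cycle
    round-trips finite values bit-identically.
    """
    out = variants.reset_index(drop=True)
    if fm is not None:
        out = pd.concat([out, fm.data.reset_index(drop=True)], axis=1)
    out.to_csv(path, sep=sep, index=False, float_format="%.17g")


def write_group_sidecar(path: str | Path, groups: Mapping[str, str]) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dict(groups), fh, sort_keys=True)


def records_from_frame(variants: pd.DataFrame) -> list[VariantRecord]:
    """Materialize :class:`VariantRecord` objects (validates invariants)."""
    recs = []
    for row in variants.itertuples(index=False):
        maf = getattr(row, "maf", None)
        if maf is not None and pd.isna(maf):
            maf = None
        transcript = getattr(row, "transcript", None)
        if transcript is not None and pd.isna(transcript):
            transcript = None
        recs.append(
            VariantRecord(
                chrom=str(row.chrom),
                pos=int(row.pos),
                ref=str(row.ref),
                alt=str(row.alt),
                gene=str(row.gene),
                transcript=transcript,
                maf=maf,
                label=getattr(row, "label", "unknown") or "unknown",
            )
        )
    return recs


def fill_missing(fm: FeatureMatrix) -> FeatureMatrix:
    """Fill missing feature cells by category.

    Protein-complex style features are filled with 0; every other feature is
    filled with -1. Non-missing cells are untouched. Every feature must carry
    a group tag.
    """
    untagged = [c for c in fm.data.columns if c not in fm.groups]
    if untagged:
        raise ValueError(f"feature(s) without a group tag: {untagged}")
    fills = {
        name: (FILL_COMPLEX if fm.groups[name] in COMPLEX_FILL_GROUPS else FILL_DEFAULT)
        for name in fm.data.columns
    }
    data = fm.data.copy()
    for name, sentinel in fills.items():
        data[name] = data[name].fillna(sentinel)
    return FeatureMatrix(data=data, groups=dict(fm.groups), fills=fills)


def partition_genes(
    genes: Iterable[GeneInfo] | pd.DataFrame,
    pli_cut: float = PLI_CONSTRAINED_CUT,
) -> dict[str, str]:
    """Assign every gene to ``constrained`` (pLI >= cut) or ``nonconstrained``.

    A gene with no pLI annotation is assigned nonconstrained with a warning:
    the constrained set is defined by pLI >= cut, so anything outside it falls
    in the complement.
    """
    if isinstance(genes, pd.DataFrame):
        genes = [
            GeneInfo(gene=str(r.gene), pli=None if pd.isna(r.pli) else float(r.pli))
            for r in genes.itertuples(index=False)
        ]
    out: dict[str, str] = {}
    n_missing = 0
    for g in genes:
        if g.pli is None:
            n_missing += 1
            out[g.gene] = NONCONSTRAINED
        else:
            out[g.gene] = CONSTRAINED if g.pli >= pli_cut else NONCONSTRAINED
    if n_missing:
        warnings.warn(
            f"{n_missing} gene(s) missing pLI assigned nonconstrained",
            stacklevel=2,
        )
    return out


def read_gene_table(path: str | Path, *, sep: str = "\t") -> pd.DataFrame:
    """Read a two-column gene annotation table (gene, pli)."""
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    missing = [c for c in ("gene", "pli") if c not in df.columns]
    if missing:
        raise SchemaError(f"gene table missing column(s): {missing}")
    return df


def maf_filter(
    variants: pd.DataFrame,
    threshold: float = MAF_THRESHOLD,
    strict_threshold: float | None = None,
    partition: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Rarity filter on minor allele frequency.

    Keeps variants with ``maf < threshold`` (strict inequality, as printed).
    When ``strict_threshold`` is given, variants in constrained genes must
    additionally satisfy ``maf < strict_threshold`` — the extra filter applied
    to constrained genes in case/control de novo comparisons. Missing MAF is
    treated as 0 (absent from the population database passes any rarity cut).
    """
    if not (0.0 < threshold < 1.0):
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    if strict_threshold is not None:
        if not (0.0 < strict_threshold < 1.0):
            raise ValueError(f"strict_threshold must be in (0, 1), got {strict_threshold}")
        if strict_threshold > threshold:
            raise ValueError("strict_threshold must be <= threshold")
        if partition is None:
            raise ValueError("strict_threshold requires a gene partition")

    maf = (
        pd.to_numeric(variants["maf"], errors="coerce").fillna(0.0)
        if "maf" in variants.columns
        else pd.Series(0.0, index=variants.index)
    )
    keep = maf < threshold
    if strict_threshold is not None:
        constrained = variants["gene"].map(
            lambda g: partition.get(g, NONCONSTRAINED) == CONSTRAINED
        )
        keep &= ~constrained | (maf < strict_threshold)
    return variants.loc[keep].copy()
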