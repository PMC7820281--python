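"""Synthetic data generators with known ground truth.

Real training data for a missense pathogenicity model comes from curated
variant databases and population sequencing; none of that is redistributable
or needed for testing the machinery. These generators emulate the *shapes*
that matter:

* a variant feature table with block-correlated Gaussian features (correlated
  blocks mimic groups like conservation scores or published predictors),
  class-conditional mean shifts for pathogenic rows, per-group missingness,
  gene assignments with a bimodal pLI distribution, and a long-tailed MAF;
* a raw-score universe standing in for the genome-wide collection of all
  possible missense variants that rank percentiles are taken against;
* case/control de novo mutation (DNM) cohorts with Poisson counts, a planted
  enrichment of high-scoring risk variants in cases, and a technical
  inflation factor applied equally to control missense and synonymous rates
  (so the synonymous-rate adjustment is testable against truth).

Everything is deterministic under the spec seed. Default sizes are desk
scale: 5,000 variants and 40 features for the feature table (down from the
~119k-variant training corpus), and a 100,000-score universe standing in for
the 76 million possible missense variants.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .variants import FeatureMatrix

_BASES = np.array(list("ACGT"))

#: Default feature blocks: (group tag, n features, within-block rho,
#: pathogenic-class mean shift in SD units). Effect sizes concentrate signal
#: in conservation and published-predictor features, mirroring where real
#: models find it; the protein_complex block exercises the fill-with-0 rule.
DEFAULT_BLOCKS: tuple[tuple[str, int, float, float], ...] = (
    ("local_context", 1, 0.0, 0.0),
    ("aa_constraint", 2, 0.3, 0.5),
    ("conservation", 7, 0.7, 1.5),
    ("protein_structure", 9, 0.4, 0.8),
    ("protein_complex", 3, 0.4, 0.5),
    ("gene_intolerance", 8, 0.5, 0.5),
    ("published_scores", 10, 0.6, 1.0),
)


#: A strongly separable condition: 1.5 SD shifts on four feature blocks, under
#: which a linear classifier already attains near-perfect AUC. Used to check
#: that the network learns what is plainly learnable.
SEPARABLE_BLOCKS: tuple[tuple[str, int, float, float], ...] = (
    ("local_context", 1, 0.0, 0.0),
    ("aa_constraint", 2, 0.3, 1.5),
    ("conservation", 7, 0.7, 1.5),
    ("protein_structure", 9, 0.4, 1.5),
    ("protein_complex", 3, 0.4, 0.5),
    ("gene_intolerance", 8, 0.5, 0.5),
    ("published_scores", 10, 0.6, 1.5),
)


@dataclass(frozen=True)
class GeneratorSpec:
    """Parameters of the synthetic study.

    ``blocks`` entries are (group, size, within-block correlation, pathogenic
    mean shift in SD units). ``class_balance`` matches the roughly 1:2.7
    positive:negative training mix. DNM cohort sizes default to the CHD
    case / unaffected-sibling control shape (2645 / 1911), with per-person
    Poisson rates around 0.5 missense and 0.3 synonymous DNMs.
    """

    n_variants: int = 5000
    blocks: tuple[tuple[str, int, float, float], ...] = DEFAULT_BLOCKS
    class_balance: float = 0.27
    missing_rate: float = 0.05
    n_genes: int = 200
    seed: int = 0

    # DNM cohort parameters
    n1: int = 2645
    n0: int = 1911
    benign_missense_rate: float = 0.5
    risk_missense_rate: float = 0.15
    synonymous_rate: float = 0.3
    inflation: float = 1.0
    risk_score_low: float = 0.5

    def __post_init__(self) -> None:
        if self.n_variants < 1:
            raise ValueError("n_variants must be >= 1")
        if not (0.0 < self.class_balance < 1.0):
            raise ValueError("class_balance must be in (0, 1)")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must be in [0, 1)")
        for g, size, rho, _ in self.blocks:
            if size < 1:
                raise ValueError(f"block {g!r} has size {size}")
            if not (-1.0 <= rho <= 1.0):
                raise ValueError(f"block {g!r} rho {rho} outside [-1, 1]")
        for name in ("benign_missense_rate", "risk_missense_rate", "synonymous_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.inflation <= 0:
            raise ValueError("inflation must be > 0")

    @property
    def n_features(self) -> int:
        return sum(size for _, size, _, _ in self.blocks)

    def with_(self, **kw) -> "GeneratorSpec":
        return replace(self, **kw)


def _gene_table(spec: GeneratorSpec, rng: np.random.Generator) -> pd.DataFrame:
    """Genes with a bimodal pLI (most genes near 0 or 1, as in ExAC)."""
    low = rng.beta(0.5, 5.0, size=spec.n_genes)
    high = rng.beta(5.0, 0.5, size=spec.n_genes)
    pli = np.where(rng.random(spec.n_genes) < 0.7, low, high)
    return pd.DataFrame(
        {"gene": [f"GENE{i:04d}" for i in range(spec.n_genes)], "pli": pli}
    )


def gen_feature_table(
    spec: GeneratorSpec,
) -> tuple[pd.DataFrame, FeatureMatrix, np.ndarray, pd.DataFrame]:
    """Variant table + feature matrix + binary labels + gene table.

    Features are equicorrelated within blocks (common-factor construction,
    unit marginal variance); pathogenic rows get the block's mean shift.
    Missing cells are injected at ``missing_rate`` per feature and left as
    NaN for the fill step.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_variants
    y = (rng.random(n) < spec.class_balance).astype(int)

    cols: dict[str, np.ndarray] = {}
    groups: dict[str, str] = {}
    for group, size, rho, effect in spec.blocks:
        shared = rng.standard_normal(n)
        for j in range(size):
            noise = rng.standard_normal(n)
            x = np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * noise
            x = x + effect * y
            name = f"{group}_{j:02d}"
            cols[name] = x
            groups[name] = group
    feats = pd.DataFrame(cols)

    if spec.missing_rate > 0:
        mask = rng.random(feats.shape) < spec.missing_rate
        feats = feats.mask(mask)

    genes = _gene_table(spec, rng)
    gene_idx = rng.integers(0, spec.n_genes, size=n)
    pos = rng.choice(10**8, size=n, replace=False) + 1
    ref = _BASES[rng.integers(0, 4, size=n)]
    alt_shift = rng.integers(1, 4, size=n)
    alt = _BASES[(np.searchsorted(_BASES, ref) + alt_shift) % 4]
    maf = 10.0 ** rng.uniform(-8, -2, size=n)
    maf[rng.random(n) < 0.5] = 0.0  # absent from the population database

    variants = pd.DataFrame(
        {
            "chrom": rng.integers(1, 23, size=n).astype(str),
            "pos": pos,
            "ref": ref,
            "alt": alt,
            "gene": genes["gene"].to_numpy()[gene_idx],
            "transcript": [f"ENST{p:011d}" for p in pos],
            "pli": genes["pli"].to_numpy()[gene_idx],
            "maf": maf,
            "label": np.where(y == 1, "pathogenic", "benign"),
        }
    )
    return variants, FeatureMatrix(data=feats, groups=groups), y, genes


def gen_universe(n: int = 100_000, seed: int = 0) -> np.ndarray:
    """Raw-score universe: a broad unimodal spread over (0, 1)."""
    rng = np.random.default_rng(seed)
    return rng.beta(2.0, 2.0, size=n)


@dataclass
class DnmCohort:
    """A simulated case/control DNM study with per-variant truth."""

    case_percentiles: np.ndarray
    case_is_risk: np.ndarray
    control_percentiles: np.ndarray
    n1: int
    n0: int
    s1: float  # observed per-person synonymous rate, cases
    s0: float  # observed per-person synonymous rate, controls
    true_alpha: float
    true_attributable_fraction: float
    spec: GeneratorSpec = field(repr=False, default=None)

    def to_frame(self, which: str) -> pd.DataFrame:
        pct = self.case_percentiles if which == "cases" else self.control_percentiles
        df = pd.DataFrame({"mvp_rank_percentile": pct})
        if which == "cases":
            df["is_risk"] = self.case_is_risk.astype(int)
        return df


def planted_enrichment(spec: GeneratorSpec, threshold: float) -> float:
    """Expected enrichment ratio R at a percentile threshold, from the rates.

    Benign DNM percentiles are U(0,1); risk-variant percentiles are
    U(risk_score_low, 1). Technical inflation cancels through alpha, so R
    depends only on the biological rates.
    """
    benign_above = spec.benign_missense_rate * (1.0 - threshold)
    span = 1.0 - spec.risk_score_low
    p_risk = (
        1.0 if threshold <= spec.risk_score_low
        else max(0.0, (1.0 - threshold) / span) if span > 0
        else 0.0
    )
    risk_above = spec.risk_missense_rate * p_risk
    if benign_above <= 0:
        return np.inf
    return 1.0 + risk_above / benign_above


def planted_precision(spec: GeneratorSpec, threshold: float) -> float:
    r = planted_enrichment(spec, threshold)
    return (r - 1.0) / r if np.isfinite(r) else 1.0


def gen_dnm_cohort(spec: GeneratorSpec) -> DnmCohort:
    """Simulate the DNM study.

    Counts are Poisson at the spec's per-person rates; control missense and
    synonymous rates are both multiplied by the technical inflation factor,
    so the synonymous ratio alpha = S1/S0 has expectation 1/inflation and
    cancels the inflation out of the enrichment ratio.
    """
    rng = np.random.default_rng(spec.seed + 1)
    c = spec.inflation

    n_case_benign = rng.poisson(spec.n1 * spec.benign_missense_rate)
    n_case_risk = rng.poisson(spec.n1 * spec.risk_missense_rate)
    n_ctrl_benign = rng.poisson(spec.n0 * spec.benign_missense_rate * c)
    syn1 = rng.poisson(spec.n1 * spec.synonymous_rate)
    syn0 = rng.poisson(spec.n0 * spec.synonymous_rate * c)

    case_pct = np.concatenate(
        [
            rng.uniform(0.0, 1.0, size=n_case_benign),
            rng.uniform(spec.risk_score_low, 1.0, size=n_case_risk),
        ]
    )
    case_is_risk = np.concatenate(
        [np.zeros(n_case_benign, bool), np.ones(n_case_risk, bool)]
    )
    shuffle = rng.permutation(len(case_pct))
    ctrl_pct = rng.uniform(0.0, 1.0, size=n_ctrl_benign)

    return DnmCohort(
        case_percentiles=case_pct[shuffle],
        case_is_risk=case_is_risk[shuffle],
        control_percentiles=ctrl_pct,
        n1=spec.n1,
        n0=spec.n0,
        s1=syn1 / spec.n1,
        s0=syn0 / spec.n0,
        true_alpha=1.0 / c,
        true_attributable_fraction=spec.risk_missense_rate,
        spec=spec,
    )
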