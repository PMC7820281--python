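"""De novo mutation (DNM) enrichment statistics.

Trio studies yield DNM counts in cases and controls but no per-variant ground
truth, so a classifier is evaluated indirectly: if a score enriches true risk
variants, the rate of predicted-pathogenic missense DNMs per case should
exceed the rate per control. Writing N1/N0 for the number of cases/controls,
M1/M0 for predicted-pathogenic missense DNM counts, and S1/S0 for the
per-person synonymous DNM rates:

    alpha = S1 / S0                       (technical adjustment)
    R     = (M1/N1) / ((M0/N0) * alpha)   (case/control enrichment)
    M1'   = M1 * (R - 1) / R              (estimated true risk variants)
    precision = M1' / M1 = (R - 1) / R

Synonymous DNMs are assumed biologically neutral and identical in rate
between cohorts, so any observed synonymous rate ratio alpha reflects
sequencing/processing batch effects; dividing it out of the control missense
rate cancels that technical inflation exactly. M1' serves as a recall proxy:
the total number of true risk variants across all cases is a fixed (unknown)
constant independent of the method being scored.

Significance per threshold is a two-sided binomial test on the split of the
M1 + M0_adj predicted-pathogenic DNMs between cohorts against the expected
case share N1/(N1+N0).
"""

from __future__ import annotations

from dataclasses import dataclass
from math import sqrt as math_sqrt
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class DnmCounts:
    """Cohort-level DNM counts and synonymous rates.

    ``s1``/``s0`` are per-person synonymous DNM rates; use
    :meth:`from_totals` when synonymous counts are given as cohort totals.
    """

    n1: int
    n0: int
    m1: int
    m0: int
    s1: float
    s0: float

    def __post_init__(self) -> None:
        if self.n1 < 1 or self.n0 < 1:
            raise ValueError("cohort sizes must be >= 1")
        if self.m1 < 0 or self.m0 < 0:
            raise ValueError("DNM counts must be >= 0")
        if self.s1 <= 0 or self.s0 <= 0:
            raise ValueError("synonymous rates must be > 0")

    @classmethod
    def from_totals(
        cls, n1: int, n0: int, m1: int, m0: int, syn1: float, syn0: float
    ) -> "DnmCounts":
        """Build from total synonymous counts instead of per-person rates."""
        return cls(n1=n1, n0=n0, m1=m1, m0=m0, s1=syn1 / n1, s0=syn0 / n0)


@dataclass(frozen=True)
class EnrichmentResult:
    """Derived quantities at one threshold."""

    threshold: float
    alpha: float
    enrichment: float
    m1: int
    m1_prime: float
    precision: float
    p_value: float

    @property
    def significant(self) -> bool:
        return self.p_value < 0.05


def compute_alpha(s1: float, s0: float) -> float:
    """Technical adjustment rate: ratio of synonymous DNM rates, S1/S0."""
    if s0 <= 0:
        raise ValueError("control synonymous rate must be > 0")
    return s1 / s0


def compute_enrichment(
    counts: DnmCounts,
    alpha: float,
    *,
    continuity_correction: bool = False,
) -> float:
    """Enrichment ratio R = (M1/N1) / ((M0/N0) * alpha).

    With ``continuity_correction`` a Haldane-style +0.5 is added to both M1
    and M0 so a zero control count remains usable; by default M0 = 0 raises.
    """
    m1, m0 = counts.m1, counts.m0
    if continuity_correction:
        m1 += 0.5
        m0 += 0.5
    if m0 <= 0:
        raise ValueError(
            "control count M0 is zero; enable continuity_correction to proceed"
        )
    return (m1 / counts.n1) / ((m0 / counts.n0) * alpha)


def true_risk_count(m1: int | float, enrichment: float) -> float:
    """Estimated number of true risk variants M1' = M1 (R - 1) / R.

    Clamped at 0 under depletion (R < 1): a deficit has no "excess" variants.
    """
    if enrichment <= 0:
        raise ValueError("enrichment must be > 0")
    return max(0.0, m1 * (enrichment - 1.0) / enrichment)


def precision_from_enrichment(enrichment: float) -> float:
    """Estimated precision (R - 1) / R, clamped to [0, 1]."""
    if enrichment <= 0:
        raise ValueError("enrichment must be > 0")
    return min(1.0, max(0.0, (enrichment - 1.0) / enrichment))


def binomial_significance(
    m1: int, m0_adj: float, n1: int, n0: int
) -> float:
    """Two-sided binomial test of the case/control split of pathogenic DNMs.

    M1 successes out of M1 + round(M0_adj) trials against expected success
    probability N1/(N1+N0), where M0_adj is the alpha-adjusted control count.
    """
    trials = m1 + int(round(m0_adj))
    if trials < 1:
        raise ValueError("no predicted-pathogenic DNMs in either cohort")
    p_expected = n1 / (n1 + n0)
    return float(stats.binomtest(m1, trials, p_expected, alternative="two-sided").pvalue)


def enrichment_at_threshold(
    case_percentiles: np.ndarray,
    control_percentiles: np.ndarray,
    threshold: float,
    *,
    n1: int,
    n0: int,
    s1: float,
    s0: float,
    continuity_correction: bool = False,
) -> EnrichmentResult:
    """Apply the full count -> alpha -> R -> M1' -> precision chain at one cut."""
    m1 = int(np.sum(np.asarray(case_percentiles, float) >= threshold))
    m0 = int(np.sum(np.asarray(control_percentiles, float) >= threshold))
    counts = DnmCounts(n1=n1, n0=n0, m1=m1, m0=m0, s1=s1, s0=s0)
    alpha = compute_alpha(s1, s0)
    r = compute_enrichment(counts, alpha, continuity_correction=continuity_correction)
    m1p = true_risk_count(m1, r)
    prec = precision_from_enrichment(r)
    m0_adj = m0 / alpha  # technical adjustment only; cohort size enters the test
    p = binomial_significance(m1, m0_adj, n1, n0)
    return EnrichmentResult(
        threshold=threshold,
        alpha=alpha,
        enrichment=r,
        m1=m1,
        m1_prime=m1p,
        precision=prec,
        p_value=p,
    )


def pr_proxy_curve(
    case_percentiles: np.ndarray,
    control_percentiles: np.ndarray,
    thresholds: Sequence[float],
    *,
    n1: int,
    n0: int,
    s1: float,
    s0: float,
    continuity_correction: bool = True,
    drop_nonsignificant: bool = False,
) -> pd.DataFrame:
    """Precision / recall-proxy curve over a grid of percentile thresholds.

    For each threshold the predicted-pathogenic DNMs (percentile >= t) are
    counted in cases and controls and the enrichment chain is applied. The
    threshold 0 row keeps every missense DNM — the "all missense" reference
    point estimated without any prediction method. Points failing the
    binomial test at 0.05 are flagged (``significant`` column) and optionally
    dropped; thresholds above the maximum observed percentile yield an empty
    flagged row rather than an error.
    """
    thresholds = list(thresholds)
    if not thresholds:
        raise ValueError("threshold grid is empty")
    case_percentiles = np.asarray(case_percentiles, float)
    control_percentiles = np.asarray(control_percentiles, float)

    rows = []
    for t in thresholds:
        m1 = int(np.sum(case_percentiles >= t))
        m0 = int(np.sum(control_percentiles >= t))
        if m1 == 0 and m0 == 0:
            rows.append(
                dict(threshold=t, m1=0, m0=0, alpha=np.nan, enrichment=np.nan,
                     m1_prime=np.nan, precision=np.nan, p_value=np.nan,
                     significant=False, empty=True)
            )
            continue
        res = enrichment_at_threshold(
            case_percentiles, control_percentiles, t,
            n1=n1, n0=n0, s1=s1, s0=s0,
            continuity_correction=continuity_correction,
        )
        rows.append(
            dict(threshold=t, m1=res.m1,
                 m0=m0, alpha=res.alpha, enrichment=res.enrichment,
                 m1_prime=res.m1_prime, precision=res.precision,
                 p_value=res.p_value, significant=res.significant, empty=False)
        )
    out = pd.DataFrame(rows)
    if drop_nonsignificant:
        out = out[out["significant"]].reset_index(drop=True)
    return out


def contribution_estimate(
    m1_primes: Sequence[float],
    n1: int,
    *,
    m1s: Sequence[int] | None = None,
    m0s: Sequence[int] | None = None,
    syn_counts: tuple[float, float] | None = None,
    confidence: float = 0.95,
) -> tuple[float, tuple[float, float]]:
    """Fraction of cases attributable to excess DNMs across disjoint categories.

    fraction = sum(M1') / N1. The excess count M1' = M1 - N1 (M0/N0) alpha is
    a difference of noisy counts, so when the underlying counts are supplied
    (``m1s``, ``m0s`` per category plus total synonymous counts
    ``syn_counts = (Y1, Y0)``) the interval is a delta-method normal CI whose
    variance sums the Poisson contributions of M1, M0 and both synonymous
    counts. Without them it degrades to an exact (Garwood) Poisson interval
    on the summed excess alone, which understates the uncertainty from the
    control side.
    """
    if n1 <= 0:
        raise ValueError("N1 must be > 0")
    m1_primes = np.asarray(m1_primes, dtype=float)
    excess = float(np.sum(m1_primes))
    if excess < 0:
        raise ValueError("excess counts must be >= 0")
    frac = excess / n1
    a = 1.0 - confidence

    if m1s is not None and m0s is not None:
        m1s = np.asarray(m1s, dtype=float)
        m0s = np.maximum(np.asarray(m0s, dtype=float), 1.0)
        adj = m1s - m1_primes  # the subtracted adjusted-control expectation
        syn_var = 0.0
        if syn_counts is not None:
            y1, y0 = syn_counts
            syn_var = 1.0 / y1 + 1.0 / y0
        var = float(np.sum(m1s + adj**2 * (1.0 / m0s + syn_var)))
        z = stats.norm.ppf(1.0 - a / 2.0)
        half = z * math_sqrt(var)
        lo, hi = max(0.0, excess - half), excess + half
    else:
        lo = stats.chi2.ppf(a / 2.0, 2.0 * excess) / 2.0 if excess > 0 else 0.0
        hi = stats.chi2.ppf(1.0 - a / 2.0, 2.0 * (excess + 1.0)) / 2.0
    return frac, (lo / n1, hi / n1)


def read_counts_table(path) -> pd.DataFrame:
    """Read the cohort counts TSV: columns cohort, N, category, count."""
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    required = {"cohort", "N", "category", "count"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"counts table missing column(s): {sorted(missing)}")
    return df
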