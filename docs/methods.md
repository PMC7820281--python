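# Methods

## Problem setting

A missense variant substitutes one amino acid and may or may not disrupt
protein function. The package scores variants for pathogenicity from a table
of precomputed numeric features (conservation, amino-acid substitution
scores, protein structure/interaction/modification features, gene-level
mutation intolerance, published predictor scores, local sequence context)
and evaluates such scores where labeled truth is unavailable, using de novo
mutation (DNM) burden in case/control cohorts.

Two decisions shape the whole design:

1. **Gene stratification.** Genes are split at ExAC pLI 0.5. In constrained
   (LoF-intolerant, typically dosage-sensitive) genes, a heterozygous
   hypomorphic variant can be pathogenic, so conservation-type evidence is
   informative. In non-constrained genes pathogenic variants act mainly
   through gain of function or dominant negative mechanisms; conservation
   and most published predictors carry little signal there, so the
   non-constrained model uses a reduced feature set. Separate models are
   trained per class and never share weights.
2. **Rarity.** Only rare variants with large effects are in scope: variants
   with population MAF ≥ 10⁻⁴ are filtered out of training and testing, and
   case/control DNM comparisons in constrained genes apply an additional
   MAF < 10⁻⁶ filter. A variant absent from the population database passes
   any rarity cut (missing MAF is treated as 0). Whether the 10⁻⁶ filter
   also applies to training is not settled usage; it is exposed as an
   argument and by default applied only in the DNM analysis.

## Feature preparation

Missing cells are filled by feature category: protein-complex-membership
features with 0 (absence of evidence of complex formation), all others with
−1 (a sentinel outside the useful range of normalized scores). Filling
happens before correlation and training; every feature must carry a category
tag (a YAML sidecar next to the table).

A 1D convolution only sees adjacent columns, so columns are permuted to put
correlated predictors next to each other: Pearson correlation ρ on the
filled values, average-linkage agglomerative clustering on distance 1 − |ρ|,
leaf order as the fitted permutation. Details that matter for
reproducibility:

- features are pre-sorted lexically by name before clustering, so the fitted
  order depends only on the name set and the correlation values, never on
  incidental column order;
- a zero-variance feature gets correlation 0 with everything (no NaN
  propagation);
- a fully degenerate matrix (all pairwise distances equal, e.g. identity
  correlation) keeps the lexical order outright rather than an incidental
  merge order;
- the fitted order is serialized with the model artifact and scoring always
  reorders through it, so training and scoring can never disagree.

Any ordering that brings correlated features together preserves the model's
rationale; the clustering algorithm itself was an open choice and is
recorded in the `FeatureOrder.method` metadata.

## Network

Architecture (lengths for the 38-feature constrained model):
input conv(1→32, kernel 3, stride 1, same padding), then two residual units
(conv(32→32,k3) → ReLU → conv(32→32,k3), summed with the unit input, ReLU,
max-pool size 2 in ceil mode), then FC(320→512) → ReLU → FC(512→1) →
sigmoid. The convolutional stack has exactly
32·(3+1) + 2·2·(32·3·32 + 32) = 12,544 parameters. The published FC input
width of 320 pins down two choices that are otherwise free: convolutions
must preserve length (same padding) and each of the two poolings must halve
with ceiling (38 → 19 → 10; ×32 channels = 320). Pooling is placed after
the residual sum; only total downsampling, not placement, is constrained by
that figure. For other feature counts the FC width adapts (21 features →
11 → 6 → 192).

Training: Adam (lr 1e-4, β₁ 0.9, β₂ 0.99, ε 1e-8) on binary cross-entropy,
batch 64, 80/20 random train/validation split. After each full cycle the
validation loss is recorded; training stops when it has not decreased for 5
further cycles (or at the 100-cycle cap) and the weights from the
best-validation cycle are restored — the restored weights' validation loss
is by construction the minimum of the recorded history. Weights are
He-uniform initialized from the config seed; no class reweighting is applied
even though training data are imbalanced (~1:2.7), matching the training
protocol this mirrors. Loss is computed from logits
(softplus(z) − y·z) for numerical stability; reported scores are sigmoids,
clipped away from exactly 0/1 by one ulp to keep the open-interval contract
under float rounding.

The forward and backward passes are written directly on NumPy arrays
(im2col convolutions, explicit gradients, hand-rolled Adam). At this
architecture size that is fast enough (seconds per cycle at n = 5000 on one
CPU) and buys exact, platform-independent reproducibility: the same seed
yields the same weights bit for bit, which the end-to-end determinism test
relies on. The backward pass is verified against central finite differences
in the unit tests at relative error < 1e-7.

## Scoring

Raw sigmoid outputs are not comparable across models or calibrations, so the
reported score is the rank percentile within a declared universe of raw
scores (standing in for all possible missense variants; the production-scale
universe has ~76 million entries, the desk-scale synthetic default 100,000).
Ties take midrank weight: percentile(q) = (#{u<q} + ½#{u=q})/|U|, which
makes the self-percentiles of any universe average exactly ½ and makes
percentiles invariant under any strictly increasing transform of the raw
scores. Whether the two partition models share one universe or use separate
ones is configurable; the default is a single pooled universe. Calls use
percentile ≥ 0.70 (constrained) / ≥ 0.75 (non-constrained); the thresholds
are inclusive so the printed operating points are themselves pathogenic
calls.

## Evaluation

AUC is computed as the Mann–Whitney concordance P(s⁺>s⁻) + ½P(s⁺=s⁻) via
average ranks — exact under ties — and is cross-checked in tests against a
brute-force pairwise oracle and scikit-learn's trapezoidal AUC. The ROC
curve itself (thresholds, FPR, TPR) comes from scikit-learn with calls at
score ≥ threshold. The optimal threshold maximizes Youden's J = TPR − FPR
(the point farthest from the diagonal); ties resolve to the lowest such
threshold.

Feature-group contribution is measured by cross-one-group-out retraining:
per replicate, negatives are subsampled (default 10 per positive, the
benchmark ratio), the model is trained with and without the group, and
ΔAUC is recorded on a held-out split; 15 replicates are summarized by median
and Tukey box statistics. Case/control score distributions are compared with
the two-sided Mann–Whitney U test (scipy, tie-corrected).

## DNM enrichment

Definitions as in the README. Numerical/edge choices:

- M₀ = 0 raises by default; a Haldane-style +0.5 continuity correction on
  both M₁ and M₀ is available behind a flag (and is on by default inside
  `pr_proxy_curve`, where sparse high thresholds make zero counts routine).
- Depletion (R < 1) clamps M₁′ and precision to 0: a deficit has no excess.
- The per-threshold test is a two-sided binomial test of M₁ successes in
  M₁ + round(M₀/α) trials against expected proportion N₁/(N₁+N₀). The
  α-adjustment removes technical inflation from the control count; cohort
  size enters through the expected proportion. Points with p ≥ 0.05 are
  flagged (optionally dropped). The test's parametrization was an open
  choice; this one conditions on the total predicted-pathogenic count.
- Synonymous rates may be supplied as cohort totals
  (`DnmCounts.from_totals`) and are converted to per-person rates.
- The attributable fraction is Σ M₁′ / N₁ over disjoint variant categories.
  Its confidence interval is a delta-method normal interval whose variance
  sums the Poisson contributions of M₁, M₀ and both synonymous counts: the
  excess is a *difference* of noisy counts scaled by a noisy α, and an
  interval that ignores the control and synonymous noise (e.g. a plain
  Poisson interval on the excess) measurably undercovers — 42% vs the
  nominal 95% (93.5% for the delta-method interval) in simulation at
  N = 3000 per arm with a planted fraction of 0.10. The Poisson interval
  remains as a fallback when only the excess count is known.

Multiplying M₀ and S₀ by a common factor (pure technical inflation of the
control cohort) leaves R, M₁′ and precision unchanged — algebraically exact,
and exact in floating point for power-of-two factors.

## Synthetic data

The generator exists so every pipeline stage is testable with known truth.

*Feature tables*: blocks of equicorrelated Gaussians (common-factor
construction, unit variance), one block per feature category; pathogenic
rows get a per-block mean shift. Defaults: 5000 variants, 40 features in 7
blocks, within-block ρ 0.0–0.7, shifts of 1.5 SD (conservation), 1.0
(published scores), 0.8 (protein structure), 0.5 or 0 elsewhere; class
balance 0.27 (the ~32k:87k positive:negative training mix, scaled down);
5% missingness per feature. Gene pLI is drawn from a bimodal Beta mixture
(most genes near 0 or 1, as in ExAC); MAF is log-uniform over 10⁻⁸–10⁻²
with half the variants absent from the population database. A `SEPARABLE_BLOCKS`
preset (1.5 SD on four blocks) defines the condition under which a linear
classifier is near-perfect (logistic AUC ≥ 0.99), used to test that the
network learns what is plainly learnable.

*DNM cohorts*: cohort sizes default to the CHD-study shape (2645 cases,
1911 controls); counts are Poisson at per-person rates (benign missense 0.5,
synonymous 0.3 — both near observed trio rates — risk missense configurable);
benign DNM percentiles are U(0,1), risk-variant percentiles U(0.5,1); a
technical inflation factor multiplies both control missense and synonymous
rates, so α has expectation 1/c and the adjustment is testable against
truth. `planted_enrichment(spec, t)` gives the expected R at any threshold
in closed form.

What the generator does **not** emulate: real feature marginals (heavy
tails, bounded scores, discreteness), label noise in curated databases,
gene-level clustering of risk variants, linkage between MAF and features,
and any sequence context. Passing tests therefore demonstrate that the
machinery is correct and well-calibrated under its stated assumptions — not
that the trained network reaches any particular accuracy on real curated
benchmarks, which require the original external data sets.

## Problem sizes used in the test suite

Unit tests use reduced network configs (4–8 kernels) and hundreds of
samples. The headline learnability check trains the full 32-kernel network
on 5000 variants/40 features (~15–20 early-stopped cycles); enrichment
parameter-recovery runs at 10⁵ person-equivalents per arm; CI coverage uses
200 simulated cohorts of 3000 per arm; determinism runs the full CLI
pipeline twice at 800 variants. These sizes were chosen as the smallest at
which the targeted statistical bands are comfortably stable.

## Known limitations

- Raw features must be precomputed externally; the package deliberately does
  not query conservation/structure/PTM databases.
- Only stride-1, same-padded convolutions and the described pooling are
  implemented; deeper variants are reachable through `n_residual_units` but
  were not a design target.
- The binomial test and the contribution CI are documented parametrizations
  of procedures whose original constructions are underspecified; they are
  defensible defaults, not claimed equivalents.
- Training on CPU NumPy is economical at desk scale but not intended for
  genome-wide (76M-variant) scoring runs.
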