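# Methods

## Ratio variables and the nf3 normalization factor

All analysis operates on Ct differences. For markers A, B the variable
`A:B = Ct(A) − Ct(B)` equals log2([B]/[A]) under ideal (100 %) PCR
efficiency; no efficiency correction is applied, because the classifier
only needs a monotone proxy of the concentration ratio and the logistic
fits are invariant to affine rescaling of covariates.

`nf3` is a pseudo-marker whose Ct is the **geometric mean of the three raw
reference Cts** (miR-103a, miR-191, miR-378). This is the literal
construction used here by default (`nf3_mode="geometric_ct"`). It is worth
flagging that the geNorm tradition defines a normalization factor as the
geometric mean of the reference *quantities*, which in Ct space is the
**arithmetic** mean of the Cts; both are implemented
(`nf3_mode="arithmetic_ct"`), and for reference Cts within a few cycles of
each other the two differ by well under 0.1 cycles.

The choice has one observable consequence: a per-sample constant added to
every Ct (loading offset) cancels *exactly* in marker:marker variables and
in `:nf3` variables under the arithmetic mode, but only to first order
under the geometric mode (the geometric mean is not translation-
equivariant). At a loading spread of τ = 1 cycle the residual is of order
10⁻³ cycles — negligible against Ct noise of 0.5 cycles — and the test
suite asserts exactness where it holds and a small bound where it does not.

Variables are enumerated as all unordered pairs of the 29 entities
(25 targets + 3 references + nf3) in panel order, the earlier entity being
the numerator. Orientation is a sign convention only; every downstream
statistic is either sign-invariant (Mann–Whitney, AUC after orientation of
the positive class, logistic metrics) or flips coherently.

## Exact Mann–Whitney test

The univariate screen uses the exact two-sided Mann–Whitney test,
conditional on the observed pooled multiset of values. Ties get mid-ranks;
the null distribution of the rank sum is computed by the shift
(count-generating) dynamic program over doubled mid-ranks, which makes the
tie pattern explicit and reduces to the classical no-tie distribution on
continuous data. The two-sided p doubles the smaller tail, capped at 1 —
the convention of standard exact implementations; the distribution layer is
cached by (group size, rank multiset), so screening 406 continuous
variables costs one dynamic program, not 406.

Counts are accumulated in float64. C(114, 48) ≈ 3 × 10³² is far inside
float range and the dynamic program only adds non-negative numbers, so even
tail probabilities below 10⁻³⁰ keep ~12 significant digits — the
fully-separated 48 vs 66 case reproduces 2/C(114, 48) to 10⁻⁹ relative.

For sample sizes with n1·n2·(n1+n2) beyond a budget (default 5 × 10⁶,
covering the study's 48 vs 66 with two orders of margin) the tie-corrected
normal approximation with continuity correction is used and flagged in the
result's `method` field.

Multiplicity: raw p-values are multiplied by the fixed family 4 comparisons
× 406 variables = 1624, deliberately **uncapped** so that table formatting
can render values above unity as ">1". Significance is the strict rule
p_raw < 0.05/1624, applied to the raw value. The multiplier stays 1624 even
when a caller screens a subset of variables — the family is a property of
the study design, not of the call — but both factors are arguments.

## Balanced logistic regression and LOOCV

Groups are unbalanced (e.g. 48 vs 66), so each sample carries weight
w_i = N/(2·n_class(i)): both classes contribute total weight N/2. Only the
weight *ratio* matters for the fitted probabilities; this normalization
keeps the effective sample size at N. Fitting is Newton/IRLS on the
weighted log-likelihood with intercept, gradient-norm tolerance 1e-8, at
most 100 iterations, no regularization. Complete separation has no finite
maximiser; the fit then returns its last iterate flagged `converged=False`,
whose predictions saturate on the correct sides — sufficient for
threshold-0.5 classification. A fit is reported converged only when the
gradient tolerance is met with all training logits below the numerical
saturation ceiling (|η| < 35), since past that ceiling the float gradient
vanishes for the wrong reason. Newton iterations for saturated folds are
also cut short once no probability can change by more than 1e-14, which
leaves the output bit-comparable to running out the iteration cap at a
fraction of the cost.

LOOCV refits N times with the balancing weights recomputed on each
training fold (fold class counts differ from the full data by one; the
balance property belongs to each fitted model). A fold that loses its last
member of a class predicts the balanced prior 0.5 and logs a warning. The
N per-fold Newton recursions run simultaneously as one array program,
warm-started at the full-data fit; a test pins the batched path to the
explicit per-fold loop at 1e-8.

Metrics at threshold 0.5 use the ≥ rule (a predicted probability of
exactly 0.5 counts as a positive call). Sensitivity is keyed to each
comparison's named group (NTP, ALL, AML, and ALL for ALL-vs-AML).

## DeLong AUC interval

AUC is the normalized Mann–Whitney statistic of the scores (ties ½), which
the tests verify against the rank-test module on shared data. The variance
uses DeLong's structural components from mid-rank placement values:
Var = S10/n_pos + S01/n_neg with sample variances of the per-case and
per-control placements. The Wald interval auc ± z·√Var (z = 1.959964 at
95 %) is clipped to [0, 1] and the clipping is recorded; degenerate
variance (perfect or constant scores) gives a zero-width interval. AUC is
not floored at ½ — below-chance models report below-chance AUC.

## Exhaustive model search

Every covariate subset of sizes {2, 3} is evaluated by the same
LOOCV-plus-metrics pipeline; each variable's value vector is computed once.
Ranking is (cv_accuracy desc, cv_auc desc, covariate names asc). Because
LOOCV accuracy takes values on a 1/N grid, ties are real and meaningful;
the streaming top-n therefore keeps every model tied with the n-th boundary
on (accuracy, AUC), and pruning only discards models strictly worse than
the running boundary. That invariant makes the result independent of
evaluation order, hence serial runs, deterministically sharded runs
(subset index mod n_shards), and merged shard reports are identical.

The full space is 11,153,835 models per comparison; at the ~400 models/s of
the batched LOOCV this is an overnight run on one core, which is what the
sharding flags are for. The desk-scale driver (`analysis/03_model_search.py`)
searches the top 30 univariate variables (4,495 models per comparison) —
chosen as a size that exercises every code path while a full analysis run
stays in minutes.

## Synthetic cohorts

`Ct_ij = base_j + shift(j, group_i) + offset_i + ε_ij`, with
offset_i ~ N(0, τ²), ε_ij ~ N(0, σ²). Defaults: 48 NTP / 22 ALL / 44 AML,
σ = 0.5 cycles, τ = 1.0 cycles, fixed per-marker baselines spread over
[20, 34] cycles, and planted shifts of 1.5–2.5 cycles (≈ 3–6-fold
concentration changes) on miR-150 (up-Ct in both leukemias), miR-223
(up-Ct in ALL), miR-100 (down-Ct in ALL) and miR-221 (down-Ct in AML),
directions matching the strongest reported group differences in this
setting. References never receive effects — that is what makes them
references.

What the generator does *not* emulate: marker–marker correlation beyond the
shared loading offset, heavy-tailed or censored Cts (no non-detects),
PCR-efficiency differences between assays, and biological heterogeneity
within groups. Consequently the synthetic cohorts are *cleaner* than real
bone-marrow data — planted effects of 2 cycles yield near-perfect
classifiers, where a real cohort of this size tops out around 93 %
sensitivity / 92 % specificity. Passing recovery tests therefore
demonstrates that the machinery finds structure it is pointed at under the
stated noise model, not that real cohorts are this separable.

## Numerical and design choices

- Ct plausibility window [5, 45] cycles, hard validation failure outside;
  missing values are rejected rather than imputed (an `impute` pathway was
  considered and dropped: the study design has complete panels).
- Exact-test two-sided rule: doubled smaller tail, capped at 1.
- p-display: two significant figures as plain decimals, ">1" above unity;
  CV-separation p floored at 2.2 × 10⁻¹⁶ for display only.
- Hessian singularity (collinear covariates, saturation) is handled by a
  1e-10 ridge on the Newton step only, never on the objective.
- The acceptance script scales Monte-Carlo loops (100 null-cohort seeds,
  20/10 recovery seeds) to keep a full from-scratch run in minutes; the
  test suite runs the larger versions (200 and 50 seeds).

## Known limitations

- The exact test is conditional on the observed tie pattern; discrete data
  with heavy ties make it conservative (as any exact rank test).
- The geometric-vs-arithmetic nf3 ambiguity is exposed as a switch rather
  than resolved; results in this codebase default to the geometric reading.
- LOOCV metrics on 114 samples have granularity 1/114 ≈ 0.009; accuracy
  ties among top search models are expected and preserved, not broken
  arbitrarily.
- No multiplicity correction is applied *within* the secondary search
  beyond reporting the global Bonferroni bound; the search is exploratory
  by construction.
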