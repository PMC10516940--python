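# Methods

## Synthetic score model

Real image-activated sorters classify each cell image with a CNN; the
distribution of its softmax outputs is a property of the trained network and
its imagery and cannot be reproduced without them. `iacsim` therefore
treats the score distribution as a modelling primitive: for a cell of true
class *j* the logit vector is

    z = s·e_j + ε,   ε ~ N(0, σ²I),   scores = softmax(z)

with separability *s* (default 4, dimensionless) and logit scale σ
(default 1). At *s* = 0 all classes are exchangeable (mean score 1/K); as
*s* grows the argmax converges to the true label and, with common random
numbers, every one-vs-rest ROC AUC is non-decreasing in *s* (each pairwise
ordering indicator is individually monotone). Because this family is a
stand-in, no result in the package depends on matching any particular
trained model's AUC or confusion diagonal; those quantities are emitted as
outputs, not asserted as targets.

Quality classes (`debris`, `out_of_focus`) are ordinary classes with their
own mixture fractions. The `circulating_cell_mixture` preset uses 39.01%
out-of-focus and 6.57% debris, mirroring the training composition of a
circulating-cell classifier; the evaluable remainder is split between
target and background at the requested target proportion π.

## Mixture evaluation

ROC curves sweep every distinct score as a threshold (a cell is positive
when score ≥ t); tied scores move between thresholds as a block, and the
endpoints (0,0) and (1,1) are always present. The trapezoidal AUC of this
tie-grouped curve equals the Mann–Whitney pair-ordering statistic with ties
counted ½ — a property-tested invariant against a brute-force pair count,
and cross-checked against scikit-learn's independent implementation.

Precision–recall at target proportion π is obtained by pointwise
reweighting, precision = π·TPR / (π·TPR + (1−π)·FPR). Conventions: where
TPR = FPR = 0 (nothing called positive), precision is defined as 1; argmax
ties in the confusion matrix break by class-name sort order. Reweighting,
rather than physically constructing the mixture, is the default because a
1:100,000 mixture needs ≥10⁷ cells for one target at meaningful resolution;
`empirical_mixture_pr_curve` constructs an explicit resampled mixture for
cross-validation of the two routes. Note that the Monte-Carlo error of an
explicit mixture at small π is dominated by the order-statistic noise of the
few resampled targets (not by binomial counting), which is why the
cross-validation tests estimate it from replicate mixtures.

Quality-filtered evaluation: mixture proportions refer to evaluable cells,
i.e. filtering debris/out-of-focus happens before proportions are
interpreted.

## Sorter simulation

Arrivals are a homogeneous Poisson process at the configured total cell
rate (inertial-focusing-induced regularity in real channels is ignored — a
known limitation that makes simulated coincidence slightly pessimistic at
high rates). Per run, all randomness (interarrivals, labels, logit noise,
prediction errors) is drawn up front from one seeded generator and does not
depend on valve settings, so tradeoff grids share common random numbers
across every grid point; along the rate axis the exponential draws scale
deterministically with λ.

The valve model, per triggering cell at true arrival *t* with prediction
error *e* ~ N(0, jitter_scale_ms²):

- the valve opens over the absolute interval [t + e − w/2, t + e + w/2];
- the triggering cell is captured iff |e| ≤ w/2;
- every other cell whose arrival falls inside an open interval is collected
  (coincidence); a second target collected this way counts toward yield but
  does not retrigger;
- after a window closes, `dead_time_ms` (default 0) must elapse before the
  next trigger;
- cells *predicted* as a quality class do not trigger unless
  `trigger_on_quality` is set (quality predictions report sample quality,
  they do not sort).

Every arrived cell is therefore collected, discarded, or (targets only)
missed, exactly once — an invariant asserted per run.

In the rare-target, zero-jitter, zero-dead-time regime each window holds
one target plus Poisson(λ·w) contaminants, giving the closed-form purity
1/(1 + λ·w) that `analytic_coincidence_purity` evaluates; the simulation is
tested against it across λ·w ∈ [0.1, 2] within three Monte-Carlo standard
errors. At 3000 cells/min and w = 15 ms the limit is 4/7 ≈ 0.571.

Yield loss has no mechanism in the coincidence arithmetic alone; the
package's chosen mechanism is the capture condition |e| ≤ w/2. The helper
`jitter_scale_for_capture(w, p)` solves σ = (w/2)/Φ⁻¹((1+p)/2); with
w = 15 ms and p = 0.8 it returns σ ≈ 5.85 ms, which reproduces an ~80%
yield / ~57% purity operating point at 3000 cells/min as a *demonstration
preset* — the jitter scale is a free parameter, not a validated instrument
property.

Monotonicity regimes. Purity is monotone non-increasing in window width
only when capture is not jitter-limited: with σ > 0 and small w, most
windows miss their own triggering target (capture probability
2Φ(w/2σ) − 1 is small) yet still collect coincident background, so purity
*rises* with w before coincidence turns it back down. The monotonicity
tests therefore check purity in the zero-jitter regime and yield under
jitter, both with common random numbers.

## SNP purity estimation

Dosage arithmetic assumes copy-neutral, equal-ploidy genomes: a genotype
contributes its dosage g ∈ {0, 0.5, 1} to the pool allele fraction, so
f_i(p) = p·g_t,i + (1−p)·g_b,i. The estimator maximises the binomial
log-likelihood over informative variants (g_t ≠ g_b) by bounded scalar
search on [0,1] (tolerance 1e-10) followed by a Newton polish on the
analytic score function, so closed-form cases (single variant, opposite
homozygotes: p̂ = alt fraction) are exact to machine precision. Standard
errors come from the observed Fisher information at p̂; 95% CIs are Wald
intervals truncated to [0,1]; boundary solutions with an outward-pointing
score are flagged `clamped`. Expected fractions are clipped to
[1e-12, 1−1e-12] inside the likelihood to keep boundary dosages finite.
A closed-form weighted-least-squares estimator is exposed for depth-free
fraction inputs.

The synthetic allele-count generator draws per-variant depth from
Poisson(mean depth) — sequencing depth is never exactly uniform across a
panel — and alt counts Binomial(depth_i, f_i). Parameter recovery is tested
at 50 informative SNPs × depth 1000 over 200 replicates per purity level
(0.01–0.9): mean bias below 0.01 and Wald CI coverage within [0.90, 0.99].

Fold enrichment is post-sort purity divided by pre-sort target fraction,
with a delta-method CI on the ratio when both are estimates. Because how a
"pre-sort fraction" was measured can differ (nominal spike ratio vs a
measured fraction), enrichment reports carry the pre-sort estimate
explicitly rather than assuming the nominal value.

## Annotation workflow

Clustering is scipy average-linkage agglomerative clustering on Euclidean
distances by default (cosine exposed: CNN embeddings are often
directionally structured); the merge tree is returned, and flat clusters
come from cutting it at a cluster count or a cophenetic-distance height.
Cluster ids are renumbered densely from 0 in input order, making
assignments deterministic for identical inputs.

Label constraints are equality predicates on sample metadata mapping to
disallowed label subsets; a predicate referencing a missing metadata field
is an error, not a silent non-match. `batch_assign` validates every staged
assignment against the active constraints before mutating anything, so a
rejected call leaves no partial labels. Inter-labeler QC flags a run for
re-labeling only when the mismatch rate strictly exceeds 0.05 (5/100
passes, 6/100 is flagged). Hard-example mining ranks misclassified cells
by the weak model's confidence in its own wrong call, most confident first,
truncated to a per-class quota; ties keep input order. The
nearest-labeled-neighbour suggestion mode proposes labels only within a
distance ceiling (default: 90th percentile of within-cluster pairwise
distances) and never assigns.

## Problem sizes and tolerances

Simulation-based tests use 2×10⁵ arrivals for the operating-point purity
check (three Monte-Carlo SEs of the analytic value), 4×10⁴ arrivals per
tradeoff grid point, 10⁵-cell explicit mixtures for the reweighting oracle,
and 200×5 replicate fits for purity parameter recovery; these sizes put
every Monte-Carlo check well inside its stated tolerance while keeping the
full suite in the tens of seconds. All stochastic tests and the acceptance
script are seeded; identical parameters and seed reproduce outputs
bit-for-bit.

## What the synthetic data does not show

The generators emulate the statistical *structure* the downstream methods
assume — class-conditional softmax scores, isotropic embedding clouds,
Poisson arrivals, binomial allele counts — not the content of real imagery.
Passing tests therefore validate the evaluation arithmetic, the sorting
physics model, and the estimators, but say nothing about how well any
particular CNN separates real cell classes, nor about wet-lab effects
(WGA bias, CNV, cell damage) excluded from the dosage model.
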