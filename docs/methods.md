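# Methods

This note records the models, estimators, defaults and numerical choices the
package implements, what the synthetic generators do and do not emulate, and
the known limitations.

## Signatures

`compute_signature` scores every gene with a Welch (unequal-variance)
two-sample t statistic, signed positive when the condition-B mean exceeds
the condition-A mean.  Welch rather than pooled t is the safer default at
the 2–6 samples per group typical of these designs; with equal group sizes
the two statistics coincide.  The variant is recorded in run metadata.
Genes with zero variance in both groups score 0 when the means are equal;
with unequal means they receive the sign of the difference at a magnitude
one unit above the largest finite score, keeping the ranking well defined
without infinities.

The canonical ranking is a dense 1..N permutation, descending by score with
ties broken by gene id: the enrichment running sum needs integer positions
and byte-identical reruns need a total order.  Tie-averaged ranks are
available separately (`GeneSignature.average_ranks`).

`median_ratio_normalize` computes median-of-ratios size factors (per-sample
median of count / per-gene geometric mean, over genes positive in every
sample).  The median ratios are rescaled to geometric mean 1 before use:
the global scale of size factors is statistically irrelevant (any common
factor cancels in the t statistic), and this choice makes normalization
exactly idempotent.  Note the factors are *not* equivariant to rescaling a
single column by c — the per-gene geometric means also scale, so the
column's factor changes by c^((m−1)/m); only factor ratios transform
cleanly, and the normalized matrix changes by one global scalar.  A
pseudocount is available (off by default) for matrices with no
all-positive gene.

## Regulon enrichment and differential activity

The enrichment score is a weighted two-tail KS-style running sum over the
ranked signature.  Each activated (mode +1) target is a hit at its own
rank; each repressed (mode −1) target is a hit at the rank it would occupy
in the sign-inverted signature (rank reflection), so a single signed ES
covers both tails — matching one DA value per regulator.  Hit increments
are edge weight × |signature score of the target|, normalized to total
mass 1; every non-hit position decrements 1/(N − n_hits).  ES is the
maximum-magnitude excursion, positive when targets concentrate at the top.
Design points:

* The weight-1 exponent on |score| with multiplicative edge weights honours
  the interactome's confidence weights; an `unweighted=True` switch gives
  the classic equal-increment KS statistic.  The variant used is logged.
* Two targets can share an effective position after reflection; misses are
  counted per *distinct* position (the running sum is walked exactly).
* An exact |max| = |min| tie resolves positive, with a 1e-12 tolerance so
  floating-point noise cannot flip the sign between equivalent
  implementations.
* ES depends on gene ids only through ranks (invariant under monotone
  relabeling).  The |score|-weighted ES is *not* monotone under swapping a
  set member for a lower-ranked non-member — removing a high-|score| member
  shrinks the total hit mass and can raise the normalized peak; the
  unweighted ES is non-strictly monotone.

Significance is by gene permutation (the design the small sample sizes
dictate — 3 replicates per condition leave too few sample permutations):
target identities are reassigned uniformly without replacement, preserving
regulon size, modes and weights.  NES = (ES − mean)/sd over the null
(sd with one delta degree of freedom); p = (1 + #{|null| ≥ |ES|})/(n_perm + 1),
two-sided, with floor 1/(n_perm + 1); n_perm defaults to 1,000.  The
sampler uses whole-row rejection for small regulons and argpartition of a
random matrix for large gene sets; both are exactly uniform and make a
100-regulon × 1,000-permutation analysis run in well under a second.

`infer_master_regulators` ranks regulons by NES (descending), attaches the
regulator's own signature score as DE (absence is a value, shown as
not-represented, not an error) and Benjamini–Hochberg FDR across
regulators — reported alongside raw p, never substituted.  One top-level
seed is expanded into per-regulon child seeds in sorted regulator order, so
results are independent of iteration order.

## Pair synergy

`shared_regulon` intersects two regulons; under the default `strict` rule
only targets with the same mode in both parents are kept, with weight = min
of the parent weights (`any` takes mode/weight from the first parent and
logs disagreements).  `synergy_test` scores the shared regulon's ES and
compares it with a pooled null of size-matched random subsets of each
parent's targets, drawn excluding the shared set when the parent has enough
exclusive targets (otherwise from the full parent);
p = (1 + #{null ≥ ES})/(2·n_null + 1).  The pair is canonically ordered
before any draw, making the test exactly symmetric in its arguments.
Defaults: n_null = 500 per parent; min_shared = 10 (below that the subset
null is too discrete for p < 0.05).  Pairs are enumerated among the top-K
regulators by |DA| (default K = 25) to bound the quadratic pair count.

**Calibration limitation.**  The subset null conditions on the realized
parent regulons.  When the parents are not much larger than the shared set
(e.g. 20 shared targets in 40-target parents), the null draws come from a
small finite pool disjoint from the scored set, the conditional null is too
narrow, and the p-value is anticonservative: under fully null simulations at
that geometry the fraction of p ≤ 0.05 is ≈ 0.10–0.15 rather than 0.05.
With parents an order of magnitude larger than the shared set the test is
calibrated (measured 0.03–0.06).  At small-regulon scale the synergy p
should therefore be read as a comparative ranking index across pairs — the
use the discovery workflow makes of it — not as an exact tail probability.

`select_candidate_pairs` keeps pairs with synergy p ≤ α whose members are
both activated, requires at least one member represented in the signature
with DE ≥ threshold (default 2.0 — overexpression is what a reprogramming
experiment can deliver), and ranks by combined DE = max of the members'
DE (`mean` available).

## Signature-versus-signature GSEA

A gene set is the top-k up- or bottom-k down-genes of one signature
(boundary ties broken by gene id; k is a mandatory, logged parameter —
250 per direction is the package default for signature-derived sets) and is
scored on another ranked signature with the same ES machinery, all modes +1
and unit weights, NES/p by gene permutation.  The full running-sum curve
exports as a plain table for plotting.

## Graft statistics

Efficiency is 100 × positive/denominator with denominator = grown grafts by
default — the convention that reproduces the published percentages
(5.6/33/40/46/39%); `performed` is available.  Group-versus-control
contrasts use the two-tailed Fisher exact test in its minimum-likelihood
form: full enumeration over the feasible top-left cell with log-factorials,
summing all tables whose point probability is ≤ the observed (relative
tolerance 1e-7).  This definition reproduces three of the four published
p-values exactly (0.093, 0.041, 0.013); for the pair group printed as
0.026 the same computation gives ≈ 0.012, a discrepancy the package reports
rather than matches.

The additive model works on log efficiencies: slope(factor) =
log eff(single-factor group) − log eff(control); a prediction sums slopes
over the control base (or over an observed pair group's base, for
pair-plus-single combinations) and is capped at 100%.  Zero efficiencies
are floored at half a count, 100 × 0.5/denominator, before the log — the
floor applied is always echoed.  With very few grafts this floor can exceed
the control rate (a 0/3 group floors to 16.7%), inflating that factor's
slope; the limitation is inherent to summary counts and is why the synergy
t-test requires replicate-level efficiencies: a one-sample, one-tailed t of
replicate log efficiencies against the log prediction (df = n − 1),
direction observed > additive.  Pooled summary rows cannot drive this test;
the generator provides binomial replicates for it.

## Synthetic data

The generators provide exactly the structures the pipeline assumes, sized
to the study design they emulate: 100 regulators with 20–50 targets each
(disjoint blocks of the target pool), 500 unregulated background genes,
modes +1 with probability 0.7, weights Uniform(0.5, 1]; 5 planted active
regulators at effect size 2 noise-SD; one planted synergistic pair sharing
20 matched-mode targets, plus 5 decoy pairs among inactive regulators that
share targets without any interaction; Gaussian noise of unit SD on a
log-like expression scale with 3 samples per condition.  In condition B,
targets of active regulators shift by mode × weight × effect; shared
targets of the pair gain an additional interaction shift (default equal to
the effect size) only in the `joint_active` design; `single_active`
silences the second pair member; `concordant_pair` emits two
independent-noise matrices from one truth.  Active regulators' own
transcripts shift by the effect size, so the DE-based candidate filter is
exercised.  Every generator is a pure function of (config, seed).

Gaussian noise (not negative-binomial counts) is the default because the
downstream statistic is a t-test on a log-like scale; an integer-count
path exists only to exercise the normalizer.  The generator does not
emulate platform effects, library-size variation, correlated noise,
combinatorial regulation beyond the planted pair, or mouse–human ortholog
ambiguity (identifier mapping is a caller-supplied synonym table).
Passing recovery tests on these data therefore show the inference machinery
is correct and well-calibrated under its own assumptions, not that those
assumptions hold for any particular real dataset.

## Problem sizes and determinism

The validation experiments run at: 50 studies for master-regulator recovery
(all 5 planted regulators in the top 10 of 100 by |NES|, n_perm = 1,000);
4,000 null regulons for permutation-p type-I error; 25 studies for
planted-pair synergy recovery; 500 null simulations for synergy-p
calibration; 100 study pairs for GSEA concordance; all 2×2 tables with
total ≤ 40 for Fisher oracle equivalence; exhaustive ≤ 12-gene signatures ×
≤ 4-target regulons × all mode assignments for ES oracle equivalence.  The
acceptance script re-runs the stochastic experiments at reduced counts
(20/1,500/10/200/40) chosen to keep a single-CPU rerun brief while leaving
Monte-Carlo error well inside the margins being checked.  All randomness
flows from explicit integer seeds through numpy SeedSequence spawning; one
top-level seed is expanded per stage and per regulon/pair, so any stage can
be re-run in isolation and full pipelines rerun byte-identically.
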