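# Methods

This note documents the statistical model, the defaults, and the design
decisions behind `trnkit`, including what the synthetic study generator does
and does not emulate.

## Expression normalization

Counts are scaled by **median-of-ratios size factors** (each sample's factor
is the median ratio of its counts to per-gene geometric means, over genes
detected in every sample), then transformed to log2(CPM-scale + 1) and
z-scored per gene. The same size factors provide the offsets of the
negative-binomial tests.

We deliberately do not use raw total-count CPM. In a design where a large
fraction of the transcriptome shifts with condition severity, total-count
normalization introduces a global composition factor: stable genes acquire
apparent opposite-direction changes, and all gene and TF profiles become
correlated through the shared denominator. In our simulations this artifact
both saturated DEG calls and destroyed regulator identification; the
median-of-ratios reference (standard in count-based DE) removes it.
Z-scoring makes a *uniform* L1 penalty meaningful across genes — comparable
coefficient scales are an implicit requirement of sharing one penalty.

## Prior construction

Coordinates are 0-based half-open (BED). The TSS window is
`[tss − w, tss + w + 1)` with `w = 5000` by default, so positions exactly
w bases up- or downstream are included. Footprints pooled over tissues are
unioned before intersection; a motif hit is retained if it overlaps occupied
sequence by ≥1 bp. A motif recognized by several family members supports an
edge for each member, unweighted. A genomic site counts once per (TF, gene)
pair even when several TSSs of the gene match. Self-pairs (a TF's motif near
its own locus) are removed so a gene can never predict itself downstream.

## Network inference

Per gene: `minimize (1/2n)·RSS + λ·‖β‖₁` with an unpenalized intercept,
solved by cyclic coordinate descent on the Gram matrix (convergence when the
largest coordinate update < 1e-12; KKT-exact to ~1e-12 in practice, verified
against an L-BFGS-B split-variable oracle and scikit-learn). Candidate
regressors are the gene's prior TFs that pass the expression floor
(log2 CPM ≥ 1 in ≥50% of samples; both knobs configurable).

Penalty selection: per probe gene, a 100-point log grid descends from that
gene's λ_max over three decades (glmnet-style); fold-averaged CV MSE is
computed with warm starts; the 1-SE rule picks the largest λ with
`CV ≤ min + SD(fold errors)/√folds`; the uniform penalty is the lower median
of 100 probe picks. The training split is 80%, stratified by allele × age so
every condition is represented; r² is the squared Pearson correlation of
predicted vs observed (not 1 − SSE/SST), both on the training split and on
out-of-fold predictions from fivefold CV over all samples. Genes with
r²(train) > 0.5 are refit on all samples; nonzero coefficients become the
signed edge list. Penalty selection precedes the training filter.

## Differential expression

A deliberately minimal NB test: per-feature two-group log-linear model with
size-factor offsets, fitted by Newton scoring, compared to an intercept-only
null by likelihood ratio against χ²(1). Dispersions (`Var = μ + φμ²`) come
from within-group moments, shrunk toward a fitted `φ(μ) = a + b/μ` trend
with weight `prior_df/(prior_df + residual_df)`, prior_df = 10. Reported
fold changes use half-count-moderated group means so all-zero groups stay
finite. Type-I error at nominal 0.01 is 0.012–0.016 in our calibration
simulations (n = 8 vs 8, 2,000 null genes) — slightly liberal, inside the
tolerance we test. Externally computed DE tables (e.g. from edgeR or limma)
can be injected through `ingest_de_table` and used everywhere downstream.

## Enrichment and the core-TF rule

One-sided Fisher exact tests (exact hypergeometric tails) compare each
module against up- and down-regulated DEG sets separately; odds ratios are
raw, with a Haldane 0.5 display correction only when a table cell is zero.
Per condition the better direction counts; the condition counts toward the
core rule when P < 1e-6 strictly; core requires ≥5 of 15 conditions. The
permutation null shuffles case/reference labels within each condition's
sample pool (group sizes preserved) and recomputes DE, DEG calling and all
module tests per permutation. The universe for module tests is configurable;
the pipeline defaults to the modeled (kept) genes. Gene-set (GO/cell-type)
enrichment applies size bounds 10–500 after universe intersection and BH
adjustment across sets within a module; CAG-correlation enrichment uses
two-sided t-based P-values for per-protein Pearson correlations at P < 0.01,
split by sign. Fisher's method (−2Σln p ~ χ²(2k)) combines independent
study-level P-values.

## ChIP validation

Peak retention: FDR strictly < 0.01 and ≥10 reads in ≥2 individual samples.
Peak-to-gene distance is summit-to-TSS (an edge-to-TSS mode exists behind a
flag); assignment is inclusive at exactly 10 kb; one peak may assign to
several genes. The >2 SD top-target rule uses the population SD over all
annotated genes, zero-count genes included; ranking is dense. Qualitative
peak overlap is ≥1 bp and reported per side, because multi-overlaps make the
tally asymmetric.

## The synthetic study generator

The generator emulates the allelic-series design: alleles Q20 (reference),
Q80, Q92, Q111, Q140, Q175; ages 2, 6, 10 months; four male and four female
replicates per genotype per age (144 libraries). Defaults, chosen once
during design and then frozen:

- **Network.** Each gene draws `max(1, Poisson(3))` regulators. Each TF has
  a dominant sign (activator/repressor); edges carry it with probability
  0.9. Weights are `sign · (floor + |Laplace(0.4)|)` with floor 0.25 (0.55
  for core-TF edges — master regulators act strongly and, in the generator,
  with fully consistent sign). The five core TFs are domain-structured
  hubs: genes are assigned round-robin to five programs and the matching
  core TF is oversampled (boost 8) as a regulator there, giving large,
  largely disjoint core modules, as for the highest-degree regulators of
  real tissue networks.
- **Perturbation.** Core TF *i* gets an activity shift
  `sign_i · 0.002 · (CAG − 20) · age` (natural log units per CAG unit per
  month), gated by a per-TF CAG activation threshold (80, 80, 92, 92, 80)
  so the set of dysregulated programs grows with allele severity, and with
  shift signs chosen so module response directions are balanced (+,−,+,−,−)
  — mirroring the early/late and up/down program structure of the allelic
  series. The weakest conditions (Q80 and all 2-month contrasts) sit near
  the detection floor; the strongest (Q175 at 10 months) move roughly
  half the transcriptome, without saturating either direction.
- **Expression.** TF log-expression = base (lognormal around 200 counts) +
  an allele-independent per-(TF, age) drift (SD 0.5, cancels in
  case-vs-reference contrasts but gives co-expression signal) + sample
  noise (SD 0.32) + perturbation. Gene log-mean = base + Σ weight ×
  (TF deviation) + per-gene noise whose SD is drawn log-uniformly from
  (0.05, 0.28) — the mixed signal-to-noise that spreads training accuracy
  across genes. Counts are NB with dispersion 0.05 and lognormal library
  factors (SD 0.15). A sex-effect knob exists and defaults to zero.
- **Prior.** `round(0.78 · |true edges|)` true edges plus uniform false
  edges to realized precision 0.22 (the recall/precision observed when
  footprint models are benchmarked against ChIP target sets); realized
  values are recorded. Interval files place one 20 bp footprint with an
  8 bp motif hit per prior edge at a gene-unique offset within ±4.5 kb of
  the TSS (genes 30 kb apart on one synthetic chromosome, so windows never
  collide), plus ~30% decoy hits inside windows but outside footprints;
  the prior builder reproduces the sampled prior edge-for-edge.
- **Peaks.** One table for the first core TF: a peak per true target with
  duplicate mutant/wildtype counts, ~30% of peaks with halved mutant
  occupancy, plus sub-threshold rows that the retention rules must drop.

What the generator does **not** emulate: batch effects, outlier samples,
cell-type composition shifts, isoform structure, sequencing-depth artifacts
beyond a scalar library factor, and any non-linear regulation. Passing tests
on this generator show the machinery is correct and calibrated under the
stated model, not that the model captures every property of real tissue
data.

## Problem sizes and a stated limitation

The test study uses 20 TFs and 200 genes at 144 samples — large enough for
every statistical property we assert, small enough that the full pipeline,
a 100-permutation null and the solver oracles run in seconds to a few
minutes.

At this scale the condition-mean structure is nearly low-rank: one severity
axis (CAG × age) plus a three-level age factor. Severity-driven variance
therefore cannot be attributed to a *specific* core TF by any co-expression
method when several core TFs respond along the same axis — the LASSO
distributes such targets among correlated regulators, and fitted core
modules blend neighboring programs even when edge-level recovery is strong.
Consequently the power/calibration benchmark of the core-TF screen runs the
DE + enrichment + permutation chain on ground-truth modules (membership
known), while fitted-network quality is benchmarked separately at the edge
level; the acceptance script reports fitted-module core recovery alongside,
unthresholded. Real studies escape this partly through hundreds of TFs,
many more conditions, and TF expression signatures richer than a
three-point age series.

Degenerate inputs: constant expression rows are excluded before modeling;
constant abundance rows are excluded (and counted) in correlation
enrichment; zero-variance signals are an error in occupancy correlation;
empty footprint sets and out-of-bounds gene sets produce empty results with
warnings rather than errors; infeasible prior recall/precision combinations
raise configuration errors. Ties in penalty medians use the lower median;
coefficient-path ties resolve by fixed input TF order; dense ranking breaks
peak-count ties.
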