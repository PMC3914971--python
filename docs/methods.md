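# Methods

## Problem and data model

The pipeline classifies tumor samples into two non-small cell lung cancer
subtypes — adenocarcinoma (ACA, the positive class) and squamous cell
carcinoma (SCC, negative) — from genome-wide copy-number profiles.  The
input is a real-valued samples × probes matrix (`CNAMatrix`); the
copy-number scale is deliberately uninterpreted (raw copy number and
log-ratio data behave identically), because every stage uses only ordinal
structure (discretization against per-probe thresholds) or vector angles
(cosine nearness).  Missing values are rejected at load rather than
imputed.  The positive/negative convention is fixed so that sensitivity is
the ACA recall and specificity the SCC recall; with 208 ACA and 93 SCC
samples this assignment is the only one under which the published rates
0.9567 and 0.6452 correspond to integer confusion counts (199/208 and
60/93), which the acceptance checks exploit.

## Discretization and mutual information

Mutual information on continuous copy numbers requires a density estimate;
we instead reduce each probe to three states at mean ± α·sd (sample sd,
n−1 denominator), the convention of the classic mRMR software for
continuous inputs, with α = 1.0 by default.  A zero-variance probe maps
entirely to the middle state and therefore has zero relevance; it can never
outrank an informative probe.  MI is the plug-in estimate in bits (log₂);
the base uniformly rescales all MI values and cannot change a ranking.

One property of this scheme worth knowing: for a probe whose two class
clusters are balanced and well separated, every deviation from the probe
mean is smaller than the pooled sd, so all samples land in the middle state
and the probe's relevance is 0.  With imbalanced classes (as in the
208 vs 93 cohort this pipeline targets) the minority cluster crosses the
threshold and relevance is recovered.  The α parameter trades sensitivity
to shifts against robustness to noise; α → ∞ collapses everything to
state 0.

## mRMR ranking

Greedy forward selection over the discretized matrix: round 1 takes the
maximum-relevance probe (relevance D = I(probe; class)); round m+1 takes
the unselected probe maximizing D − R, with redundancy R the mean MI
between the candidate and the m selected probes.  Both D and R are computed
on the same discretized states (single code path).  The difference form
D − R is the default combination; the quotient D/R is available behind a
flag for sensitivity analysis.  Ties at any round break by input probe
order, making the ranking deterministic and stable.  The default list
length is 1000 probes.

On synthetic data with redundant blocks the penalty behaves as designed:
an exact duplicate of a selected probe drops below its parent and below its
own pure-relevance (MaxRel) position.  With jittered (rather than exact)
copies the guarantee is aggregate, not per-copy — jitter can push an
individual copy's discretized relevance above its parent's — so the tested
property is net deferral of copies relative to their MaxRel ranks.

## Nearest-neighbor classification and jackknife evaluation

Prediction assigns a query the label of the training sample with minimal
nearness 1 − cos(x, y).  Nearness is scale-invariant and lives in [0, 2]
(float round-off is clamped to that range); a zero-modulus vector has no
defined angle and is an error.  Ties break by training-sample order.
Evaluation is jackknife (leave-one-out) cross-validation, vectorized
through the cosine-similarity matrix with the diagonal masked so a sample
can never be its own neighbor; the vectorized path is exercised against a
literal per-sample hold-out loop in the tests.  Metrics follow the standard
definitions; MCC is defined as 0 when any factor of its denominator is 0
(a degenerate one-class prediction), and a fully wrong predictor on a
balanced confusion matrix correctly yields −1, not 0.

## Incremental feature selection

For each prefix size i = 1..max_n of the mRMR list, a fresh jackknife pass
records Sn/Sp/Acc/MCC (the IFS curve).  No early stopping; the full curve
is always produced, and each row is exactly reproducible by a standalone
LOOCV call on the same probes.  The optimum is the smallest prefix
achieving the maximum MCC — parsimony on ties.  The default max_n of 1000
mirrors the ranking length; the study-scale acceptance run uses max_n = 200
probes on a 301 × 2000 cohort, which completes in seconds because each
prefix evaluation is one BLAS matrix product over at most a few hundred
columns.  The heatmap export standardizes each selected probe to mean 0 /
unit sample sd across samples and orders samples positive class first;
zero-variance probes are emitted as zero rows with a warning.

## Probe → gene mapping

A probe maps to a gene when it lies on the same chromosome within the gene
span extended symmetrically by 2 kb (default) on each side; strand is
ignored.  All arithmetic is 0-based half-open: a probe exactly at
end + extension − 1 maps, at end + extension does not, and the extension is
clipped at coordinate 0.  The implementation is a per-chromosome sorted
sweep (binary search per gene) and is tested for equality with the
quadratic all-pairs oracle; the pair set is monotone in the extension.

## Enrichment

Over-representation uses the annotation-table layout a = list genes with
the annotation, b = list without, c = genome (excluding list) with,
d = genome without, and the one-sided Fisher exact p-value
P(X ≥ a) = hypergeometric upper tail with population a+b+c+d, a+c annotated
and a+b drawn — evaluated through the log-space survival function and
checked against exact-rational pmf enumeration to 1e-10 relative error.
Degenerate margins give p = 1.  Raw p-values are reported (sorted by
p, then set id, for determinism); Benjamini–Hochberg q-values are opt-in
because the published tables this layout mirrors report unadjusted values.
The universe should be supplied explicitly (all array genes or all genome
genes); the fallback — union of collection members and the query list —
warns, since it changes d.

## Synthetic cohorts

The generator emulates a two-class SNP-array CNA cohort: Gaussian noise
(sd 0.3) around a diploid baseline of 2.0; by default 208 positive and 93
negative samples and 2000 probes, of which 10 planted informative parents
shifted between classes by 2 noise-sd, each with 4 redundant partners
(parent + jitter of sd noise_sd/3, giving parent–partner correlation
> 0.9), the rest class-independent background.  The shift alternates
between gain and loss across the planted probes because real subtype
contrasts mix gains and losses and because an angle-based classifier needs
direction contrast: if every informative probe shifted the same way the two
class-mean vectors would be nearly parallel and cosine nearness could not
separate them on planted-only panels.  All draws flow from one seeded
generator; equal specs give byte-identical cohorts.

A companion annotation places probe j at position j·10 kb on one synthetic
chromosome with its own 1 kb gene, so each probe maps to exactly one gene
at the default extension, and `generate_genesets` builds one planted set
(genes of all planted probes — parents and partners, which carry the same
signal — padded to the set size) plus random null sets.

What the generator does not emulate: segmentation artifacts, GC waves,
chromosome-scale correlation structure, aneuploidy, tumor purity, or any
array physics.  Passing tests therefore demonstrate that the algorithms
recover planted structure under idealized noise, not that the pipeline
reproduces any particular biological finding on real arrays.

## Numerical and design choices

- MI accumulations can produce tiny negative totals for independent pairs
  through float cancellation; values are floored at 0.
- LOOCV tie-breaking (first minimum in training order) matches between the
  vectorized and the per-sample code paths.
- The published headline selection (266 probes from 256,554) depends on the
  deposited cohort and a specific RefSeq freeze and is not recomputable
  from scratch here; the pipeline's correctness is instead established by
  oracle agreement (brute-force greedy mRMR, exact-rational hypergeometric
  tails, all-pairs interval mapping), desk reproduction of the published
  metric and enrichment arithmetic, planted-signal recovery, and null
  behavior under label permutation and random gene lists.
- Parent vs block recovery: once a cohort is separable, the smallest
  maximum-MCC prefix may represent a planted signal by a redundant partner
  instead of its parent; the acceptance script reports both the strict
  parent-recovery fraction and the block-level fraction (parent or any
  partner present).

## Limitations

Binary classification only (the two-subtype contrast); k = 1 neighbor with
a fixed nearness measure; discrete plug-in MI without bias correction
(adequate for ranking, not for MI estimation per se); enrichment treats
gene sets as flat (no GO-graph propagation); no raw-array processing
(CEL parsing, normalization, segmentation) — the matrix is taken as given.
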