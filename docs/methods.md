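# Methods

This note documents the models, parameters and numerical choices behind
`renalmatch`, and what its synthetic cohorts do and do not establish about
real data.

## Copy-number representation and statistics

All coordinates are 1-based inclusive. Segmented profiles carry either log2
ratios or allele-specific integral copy numbers (total and minor allele per
segment, with minor ≤ total).

**Integral → log2 conversion.** An integral profile is converted by
`log2(CN_i / A)` with `A` the *length-weighted* mean total copy number of
the sample. The weighting is a deliberate choice: an unweighted mean over
segments would let many short segments dominate the ploidy estimate.
Zero-copy segments are floored at −8 (configurable) with a warning; an
all-zero profile is rejected as degenerate.

**Fraction genome altered.** `FGA = Σ L(i)·1[|CN_i| ≥ T] / Σ L(i)` with
segment length `L(i) = end − start + 1` and default threshold `T = 0.2`.
Thresholds are inclusive (≥ / ≤) everywhere — FGA, arm loss, and the
GISTIC-like discretization use the same convention, so a value sitting
exactly on a threshold is always counted as altered.

**Arm loss, two estimators.** The total-copy estimator reports the fraction
of an arm's *covered* length (segments clipped to arm boundaries) with log2
ratio ≤ −0.2; uncovered stretches carry no evidence and are excluded from
the denominator, and a fully uncovered arm is reported as indeterminate
rather than 0. The allele-specific estimator reports the fraction of the
arm with minor-allele copy number 0. The two disagree by construction on
the masked-loss configuration — minor allele lost while the major allele is
amplified enough to keep the total near (or above) the genome average — and
that disagreement is the point: loss of heterozygosity can be invisible in
total-copy data. A second allele-specific quantity flags losses *relative
to ploidy*: arm length with total copy number ≤ sample mean − 0.5. The 0.5
margin separates adjacent integer copy-number states around a fractional
genome mean; the source analyses state the concept but no threshold, so the
value is a documented package choice. The combined arm call is
either-method: `lost` if any available estimator reports ≥ 0.8 of the arm,
`negligible` if all available estimators fall below, `indeterminate` if
neither view covers the arm.

**Discretization.** For synthetic data, gene-level log2 values are mapped to
5-valued GISTIC-like scores at ±0.2 (shallow) and ±1.0 (deep/amplified),
inclusive. Real GISTIC scores, when supplied, pass through untouched.

**Gene projection.** A gene's value is the overlap-length-weighted mean of
the segments intersecting it; no overlap means missing (NaN), and missing
values are excluded pairwise in all correlations.

## Mutation handling

Records carry sample, gene, variant class, protein change, read depth and
alternate-allele fraction. The confidence filter keeps a record iff
depth ≥ 15 and allele fraction ≥ 0.15 (both inclusive) and its class is not
in {intronic, UTR, flank, intergenic, silent, RNA}; filtering is
order-preserving, idempotent, and emits a per-criterion audit count.
Binary mutation profiles (per-sample mutated-gene sets, any surviving
class) feed the Jaccard similarity; Jaccard of two empty sets is defined as
0 because an all-empty pair carries no evidence of similarity.

## Clustering and subtype calls

Samples (tumours and cell lines together) are clustered on gene-wise copy
number with distance `1 − ρ` (Spearman, pairwise-complete, average ranks for
ties) and average-linkage agglomeration; the tree is cut at height 0.9 and
clusters are the components joined below the cut. Cell lines take the
majority tumour subtype of their cluster when the cluster holds at least 5
tumours; smaller clusters and tied majorities yield `outlier`, so clusters
made of cell lines alone never inherit a subtype. Dendrograms are exported
as Newick with branch heights.

## Concordance tiers

Variant identity is protein-level: the pair (normalized protein-change
string, variant class), case/whitespace-normalized with the `p.` prefix
stripped. Protein-level identity deliberately tolerates alignment-induced
genomic-coordinate shifts between pipelines. Multiple variants per gene are
compared as sets; both sides non-empty but unequal is Tier 2. For
copy-number scores, equal nonzero is Tier 1, same sign different magnitude
Tier 2, opposite signs or one-sided calls Tier 3. A (0, 0) pair is
`concordant_null`: it is agreement, but counting silent genes as Tier 1
would inflate "perfect agreement" claims, so the reliability flags require
only the absence of Tier 2/3 calls. The ranking orders cell lines by total
discordant calls ascending, ties by Tier 1 count descending, then name.

## Batch correction

Parametric empirical-Bayes location/scale adjustment: each gene is
standardized against its batch-free fit (size-weighted grand mean, pooled
residual variance); per-batch location effects γ receive a normal prior and
scale effects δ an inverse-gamma prior, with method-of-moments
hyperparameters; the conditional posterior estimates are iterated to a
1e-6 tolerance and the data back-transformed. Two degenerate cases are
handled exactly: a fully constant gene is left untouched (warning), and a
gene with zero within-batch residual variance but differing batch means —
the noiseless limit — receives the exact maximum-likelihood location fix,
because with no residual variation there is nothing to shrink against.
This makes the correction exact on noiseless location/scale batch effects
while matching the standard empirical-Bayes behaviour on noisy data (an
independent implementation agrees to ~1e-3, the scale of its looser
convergence tolerance).

## Nearest-shrunken-centroid classifier

Per-gene class contrasts `d_kj = (x̄_kj − x̄_j) / (m_k (s_j + s0))` with
pooled within-class standard deviation `s_j`, fudge constant `s0` = median
of `s_j`, and `m_k = sqrt(1/n_k − 1/n)` (the exact standard error of a
class centroid minus the grand mean under equal variance; the common
`sqrt(1/n_k + 1/n)` variant is available as a switch). Soft-thresholding
`d′ = sign(d)(|d| − Δ)₊` shrinks uninformative genes to zero contribution;
genes with all-zero shrunken contrasts drop out. Class priors are uniform
(they only matter in the degenerate zero-gene case, which is reported, not
an error). Constant genes are handled through `s0`.

Δ is selected on a 30-point grid spanning [0, max |d|] by seeded,
class-stratified 10-fold cross-validation, ties toward larger Δ (fewer
genes). By default the cross-validation scores the *deployed* decision
rule — Spearman correlation with the shrunken centroids and the 0.05 margin
cut, an unclassified sample counting as an error. The rationale: scoring
the standardized-distance discriminant instead (available as
`cv_rule="discriminant"`) leaves a flat zero-error plateau out to extreme Δ
on well-separated data, and the tie-break then selects a Δ whose shrunken
centroids are nearly collapsed, destroying every margin at deployment.
Scoring the rule actually used makes over-shrinking visible to the
selection. A consequence worth knowing: on cleanly separable data the
selected Δ keeps a *subset* of the true markers (all surviving genes are
markers, but not all markers survive) — minimizing gene count and retaining
every marker are incompatible goals when the error curve is flat.

Final calls correlate each sample (Spearman) with the two shrunken class
centroids over the surviving genes (raw class means available as a switch);
a sample is called for a class only when its correlation exceeds the
other's by at least the margin (0.05, inclusive, with a 1e-12 float-safety
term); otherwise it is unclassified. Samples covering fewer than 90 % of
the surviving genes are rejected; fewer than 3 usable genes yields a
flagged unclassified call.

## Aggressiveness comparison

The with/away split takes the cluster holding the most cell lines as focal;
when that split degenerates (no mixed cluster, or an empty side — which
happens precisely when subtype recovery is perfect), the quartile variant
ranks tumours by mean Spearman correlation with the cell lines and compares
top versus bottom `floor(n/4)` (stable order on ties, n ≥ 8 required).
Stage is dichotomized 1–2 vs 3–4 and grade G1–2 vs G3–4. Fisher tests are
exact: the two-sided p sums hypergeometric probabilities ≤ the observed
table's, evaluated in rational arithmetic (ties included exactly; tables
with total > 2000 delegate to the standard floating-point implementation).
The reported odds ratio is the cross-product ratio `(a·d)/(b·c)`. Per-gene
p-values are reported unadjusted for multiplicity and labelled as such,
matching per-gene reporting practice.

## Synthetic cohorts: what they emulate

The default genome miniaturizes the human karyotype: 22 autosomes at 1/1000
scale with loosely decreasing lengths, centromeres at 35–50 % of each
chromosome, 25 non-overlapping genes per arm (≈ 1,100 genes), and the
24-gene kidney-cancer panel pinned to canonical arms (VHL/PBRM1/SETD2/BAP1
on 3p, MET on 7q, TP53 and FLCN on 17p, ...).

Copy-number cohorts draw, per sample, the archetype's arm events with their
penetrance — set to the event frequencies reported for the subtypes in
large tumour cohorts (ccRCC: 3p loss 0.9, 5q gain 0.67, 8q gain 0.35,
chr 14 loss 0.45; pRCC: chr 7 gain 0.9, 17 gain 0.8, 16 gain 0.55, 9p loss
0.2; chRCC: monosomies of 1, 2, 6, 10, 13, 17 at 0.85–0.9). Arm magnitudes
are ±0.5 log2 units, a calibration for the synthetic scale (no published
log2 effect sizes exist for these events). Each arm is split into 6 base
segments with independent Gaussian noise (sd 0.1 per segment), mirroring
the granularity of real segmentations — single whole-arm segments would
make noise perfectly correlated across each arm's genes. Each archetype
additionally carries a shared low-amplitude arm-dosage background (per-arm
sd = 0.8 × noise sd, per-sample intensity U(0.5, 1.5)) representing the
recurrent subtle dosage tendencies that make same-subtype tumours correlate
beyond their discrete events; both noise and background vanish in the
noiseless setting, keeping the exact-value contracts of the generator.
Focal events (Poisson rate 1/sample, exponential lengths, magnitudes
±U(0.3, 1)) add private variation. Cell lines receive doubled penetrance of
the non-hallmark events, doubled focal rate, and Poisson(2) culture-acquired
random ±0.5 arm events; the last component is what makes the *pooled*
cell-line FGA median robustly exceed the tumour median (doubling alone does
not, because high-burden chRCC tumours dominate the pooled tumour median).
Mutations combine per-driver Bernoulli rates with a uniform passenger rate
(0.008/gene ≈ 9 per sample) — driver-only profiles would be unrealistically
sparse and make binary-profile similarity degenerate.

Two-source views duplicate the truth and inject discrepancies: `drop`
removes a call from one randomly chosen view, `alter` perturbs a protein
change, `extent_shift` moves a score between magnitudes 1 and 2; each truth
call receives at most one injection, and all injections are written to a
ledger against which recovery is scored count-exactly.

Expression cohorts give the two classes balanced ± signed effects on the
marker genes (half up in ccA, half down, magnitudes U(0.75, 1.25) × effect
/ 2). The signs matter: a uniform same-direction shift on every marker
would leave the *ranks* of the class centroids identical, making
rank-correlation calling impossible in principle — real subtype signatures
mix up- and down-regulated genes. Intermediate samples sit at the exact
midpoint. Batch effects follow the location/scale model the correction
assumes: per-batch per-gene shifts N(0, batch_shift²) and noise-scale
factors log-normal around batch_scale (exactly 1 when batch_scale = 1).
Clinical covariates link stage and grade to FGA through a logistic curve
centred at FGA = 0.25 with slope 8 by default.

Every generator is a pure function of its arguments and seed, with random
streams split per sample, so outputs do not depend on group ordering.

**What passing tests show — and don't.** The synthetic cohorts have clean
arm-level events, no tumour purity or subclonality effects, no germline
contamination, no platform-specific wave artifacts, and discrepancies
injected independently at known rates. Tests against them establish that
the statistics are computed exactly as specified, that the clustering and
classifier recover structure *of the kind assumed*, and that tier counting
is exact against a known ledger — not that real cohorts are this separable.
Real subtype clustering produces mixed clusters and outliers; the pipeline's
outlier and indeterminate paths exist for exactly those cases.

## Problem sizes and determinism

Default analysis sizes — 300 tumours + 30 cell lines on the ~1,100-gene
genome for clustering, 200 training + 130 held-out samples on 1,100 genes
for the classifier, 500 random profiles for oracle checks — keep a full
pipeline run and the whole test suite in the minutes range on one CPU while
leaving every statistical contract testable. Agglomeration ties are broken
deterministically by the underlying implementation given a fixed input
order; cluster ids are renumbered by first appearance; quartile ties keep
stable input order; the Δ grid tie-break is toward larger Δ. Re-running any
stage with the same config and seed reproduces its outputs.

## Known limitations

- The ccA/ccB classifier is two-class by design; the multi-class extension
  is out of scope.
- The concordance scheme adjudicates agreement, not correctness: it cannot
  say which source is right.
- The allele-specific simulation is noise-free integers (PICNIC-style
  calls); real integral calls carry errors the pipeline does not model.
- No liftover, VCF parsing, variant-effect annotation, GISTIC peak
  detection, or survival analysis.
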