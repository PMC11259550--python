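# Methods

`methylaging` re-implements a whole-blood DNA-methylation aging analysis
as a tested pipeline: discovery of age-related differential methylation
positions (DMPs), integration of the methylome with a transcriptome,
construction of transformed-age elastic-net clocks, and stratification of
individuals by aging pace.  Because cohort-scale array data of this kind
are access-restricted, every stage is exercised against a synthetic
cohort generator that carries its own ground truth; this note records the
models, the defaults and why, and what the synthetic results do and do
not show.

## Beta values and global summaries

A CpG probe's methylation fraction is `beta = M / (M + U)` with M and U
the methylated and unmethylated intensities; `M + U = 0` yields a missing
value.  Normalisation, dye-bias and batch correction, and imputation are
assumed to have happened upstream: the package consumes a normalised beta
matrix.  Probe filtering removes user-supplied exclusion lists (SNP
probes, multi-hit probes) and, optionally, sex-chromosome probes;
annotation coordinates are 1-based (array-manifest convention).

Two per-sample summaries describe the global methylome: the arithmetic
mean beta over probes, and the methylation entropy, defined here as the
mean over probes of the binary Shannon entropy
`-(b log2 b + (1-b) log2(1-b))` after clipping betas to
`[eps, 1-eps]` with `eps = 1e-6`.  This is the standard per-site
definition; it is normalised to [0, 1], maximal for a fully intermediate
methylome, and symmetric under `b -> 1-b`.  Missing betas are excluded
pairwise rather than imputed.

Cell composition is estimated by reference-based deconvolution: each
sample's marker betas are projected onto purified cell-type profiles
under non-negativity and sum-to-one constraints.  The implementation is
the constrained projection step of the reference-based approach
(non-negative least squares with a heavily weighted sum-to-one row,
followed by exact renormalisation); the full two-stage EWAS variant of
that method is not reproduced.  The six whole-blood types carried by the
default synthetic reference are CD8T, CD4T, NK, Mono, Bcell and Neu.

## Age-related DMPs

For each probe an ordinary-least-squares model regresses beta on age plus
covariates (sex as 0/1, BMI, and five of the six cell proportions -- one
type is dropped to avoid sum-to-one collinearity).  The reported slope is
the age coefficient in beta units per year; significance is the
two-sided t-test on that coefficient, Benjamini-Hochberg-adjusted across
all tested probes.  A probe is a DMP when adjusted p < 0.01 **and**
|slope| > 0.002 beta/year; direction is the slope sign.  The reference
analysis used a moderated (empirical-Bayes) variance estimate; this
package deliberately uses plain per-probe OLS t-statistics, which makes
the estimator exactly checkable against a normal-equations oracle.  At
cohort-scale n the moderation refinement is minor relative to the joint
effect-size/significance gate, and the gate thresholds are the defining
logic; both thresholds are configurable.

Called DMPs are summarised by genomic context (island / shore / shelf /
open sea, and gene-feature classes) as per-direction proportions, and by
genomic density in half-open 1-Mb bins `[k*1e6, (k+1)*1e6)` per
chromosome, with per-chromosome totals.

### Sliding-window age peaks

To localise the ages at which methylation change concentrates, candidate
center ages are placed every `parcel` (default 5) years.  At center `c`,
samples within `window` (default 5) years of the center are dichotomised
at the center -- ages in `[c-window, c)` versus `[c, c+window)` -- each
probe receives a Welch t-test, BH adjustment is applied across probes
within the center, and the count of probes with adjusted p < 0.05 is
reported with an up/down split (up = higher methylation in the older
group).  Centers with fewer than 2 samples on either side are skipped.
The exact contrast used by sliding-window age-peak tools is defined in
several slightly different ways in the literature; the dichotomise-at-
center form used here is specified precisely so it can be tested against
its own contract (a constructed step change at age 35 peaks at the
center 35), which a window-versus-flanking-parcels contrast cannot
satisfy (it is blind exactly at a change point).

## Methylome-transcriptome integration

DMPs in distal regions or promoters (TSS200/TSS1500) are candidates for
probe-gene pairing.  For each candidate probe, samples are ranked by that
probe's beta; the top and bottom 20% form groups M and U, and each of the
10 nearest upstream and 10 nearest downstream genes is tested for lower
expression in M with a one-sided Mann-Whitney U-test (methylation up,
expression down -- and symmetrically for hypomethylating probes, where
the same alternative captures expression rising as methylation falls).
An empirical p-value recomputes the identical statistic on `n_perm`
(default 1000) genes drawn uniformly from the non-candidate gene pool,
with the add-one rule `(1 + #{null <= observed}) / (1 + n_perm)`, so it
is never zero and converges to exhaustive enumeration on small cases.
Pairs with empirical p < 0.05 are reported as `repressed`
(hypermethylating probe) or `activated` (hypomethylating probe).  The
permutation unit (random genes, uniform over the pool, one draw set per
probe) is a documented choice: the upstream tool this emulates does not
specify its null precisely.  No multiplicity correction is applied to
the empirical p (matching the published rule), so the expected
false-positive rate among tested null candidate pairs is the nominal 5%,
not an FDR.

Motif enrichment takes a direction-specific probe set and a precomputed
motif-occurrence table (occurrences within probe +/- 250 bp; the package
does not scan sequences).  Each motif gets a 2x2 table (probe in set vs
rest of background x motif present vs absent), a one-sided Fisher exact
p BH-adjusted across motifs, an odds ratio with Haldane-Anscombe 0.5
correction when a cell is zero (a motif present in every probe of both
groups is reported as OR 1, no association), and a Wald 95% CI on the
log odds ratio.  Enrichment requires all three gates: at least 10 in-set
occurrences, CI lower bound > 1.1, and adjusted p < 0.05.  For an
enriched motif, transcription-factor involvement is screened by Pearson
correlation between the motif's per-sample mean beta and the TF gene's
expression (significant at p < 0.05).

## Epigenetic clocks

Chronological age is transformed before fitting with the piecewise map
(adult age 20):

    f(age) = (age+1)/21 - 1     if age >= 20
           = ln((age+1)/21)     if age <  20

and predictions are mapped back through the exact inverse
(`t >= 0 -> 21 t + 20`; `t < 0 -> 21 e^t - 1`).  The transform is
continuous at the adult age and the round trip is exact to floating
point.

Training follows the elastic-net protocol: the cohort is split 50/50
into training and validation sets, stratified by sex and age decile (a
250-sample cohort yields exactly 125/125).  For each mixing parameter
alpha in {0.1, ..., 0.9}, the penalty lambda is selected by seeded
10-fold cross-validation on the training set; each candidate is scored
by MAE on the validation set **in years after inverse transform**
(scoring on the transformed scale is available as an option), and the
argmin-MAE model is returned with its nonzero probe weights on the
original beta scale.  Predictors are standardised internally; the
selected model is refit to a coordinate-descent tolerance of 1e-7 (the
lambda search runs at a looser tolerance, which does not affect the
selected model's coefficients).  At prediction time, model probes absent
from the input matrix are imputed with the stored training-set mean
beta; an intercept-only model (possible under a null target) predicts a
constant.  Models serialise to JSON and round-trip to bit-identical
predictions.  Published clock coefficient lists can be applied through
the same predictor via a coefficient-CSV importer; no third-party
coefficients are vendored.

The reduced panel is built by backward elimination from an OLS fit on a
small starting probe set: at each step every single-probe deletion is
scored by AIC and the best deletion is taken, until `stop_k` (default 5)
probes remain.  The elimination criterion is AIC by default (BIC
available) because the upstream description of "contribution" is not
specific; the implementation is tested against a brute-force
single-deletion search rather than against any published probe list.

Multi-modal clocks replace the chronological target with a biological
age derived from other data modalities (composite, facial, transcriptomic,
... ages), fitted on the identity scale -- the piecewise transform is a
chronological-age device.  Performance is assessed by leave-one-out
cross-validation: for each alpha, lambda is fixed by CV on the full
target set, every sample is predicted by a model trained on all others,
and the alpha with the lowest LOO MAE wins; the final model is refit on
all samples.  Samples are processed in a canonical sorted order, so
results are invariant to input column order.

## Age pace

Predicted age is regressed on chronological age (OLS, within the
evaluation subset of interest, which is a config input); a sample's
*pace* is its residual.  Paces are mean-zero and orthogonal to
chronological age by construction.  The top and bottom 20% of the pace
distribution (each exactly `ceil(0.2 n)` samples, ties broken by sample
id) are labelled accelerators and decelerators.

Group comparisons by modality: numeric phenotypes and lifestyle scores
use the Welch two-sided t-test (the unequal-variance form, matching the
R default; a rank-sum option is provided), flagged at p < 0.05.
Dichotomous factors use the uncorrected chi-squared test, falling back
to Fisher's exact test when an expected cell is below 5 (noted in the
output).  Protein/metabolite/transcript matrices use a common rule:
features detected (> 0, non-missing) in more than 2/3 of the compared
samples are retained; optional per-sample mean normalisation (each
sample divided by the mean of its detected values, making results
invariant to per-run scale factors) precedes a log2 transform; each
feature gets a Welch t-test and a log2 fold change of group means, and
passes at p < 0.05 and |log2FC| > 0.5.  For transcripts the p-gate is
BH-adjusted.  The negative-binomial count model and the
variance-stabilising/KNN-imputation pipeline used upstream for these
modalities are deliberately not reproduced; the joint fold-change +
p-value contract is the portable definition, and missing values are
handled as complete cases per feature.  Note that mean normalisation is
compositional: shifting a large fraction of total abundance between
groups displaces the normalisation itself, so planted-signal tests keep
perturbed features a small minority.

## Synthetic cohort generator

The generator is the package's study-conditions definition, not a tuning
surface.  Defaults: 250 samples, ages uniform on [20, 87]; 2000 probes
of which 5% hypermethylate and 10% hypomethylate with age, per-year
slope magnitudes uniform on [0.002, 0.008] (bracketing the 0.002 calling
threshold); Gaussian beta-scale noise with SD 0.03, clipped to [0, 1]
(clipping fraction logged); baselines drawn per island context
(islands ~Beta(2,10), open sea ~Beta(9,3), shores/shelves intermediate)
so the methylome is bimodal, hypermethylating probes sit mostly in
island/TSS contexts and hypomethylating probes in open sea.  Because
hypomethylating probes outnumber hypermethylating ones and start high,
mean methylation declines and entropy rises with age, reproducing the
qualitative global trends.  Ages are uniform rather than
demography-matched: uniform coverage maximises regression power at small
n.

Two structured noise components make the cohort realistic:

* **Biological-age scatter** (`bioage_sd`, default 4 years): a
  per-sample offset added to age in every age-drifting probe.  Without
  it, a clock averaging hundreds of CpGs drives its error to a fraction
  of a year; with SD 4 y the synthetic clock lands at MAE ~3-4 years and
  r ~0.97-0.98, the scale reported for real cohorts of this size.  It
  also gives the pace analysis a real signal (accelerators are the
  individuals with positive offsets).
* **Cell-composition confounding** (`confound_cells`): the neutrophil
  fraction rises and the CD8T fraction falls with age (the generated
  sample table asserts at least one cell column with |r| > 0.3 against
  age), and ~2% of ground-truth-null probes are driven by the neutrophil
  fraction alone.  These probes are miscalled by an unadjusted per-site
  model and correctly dropped when cell proportions enter as covariates
  -- the property the covariate correction exists to provide.

Sex and BMI nuisance effects are planted only on null-class probes, so
the planted age slope of non-null probes is exact (zero-noise examples
are exact to floating point).  Expression matrices plant anti-correlated
probe-gene links (`expr = 5 - coupling * zscore(beta) + noise`) with
linked genes placed within 80 kb of their probe on a synthetic shared
coordinate (probe i at (i+1) Mb), so distance-ranked candidate lists
recover them; unlinked genes are pure noise.  Motif tables plant three
motifs at a 0.40 occurrence rate in hypermethylating probes against a
0.05 background.  The cell-type reference uses orthogonal marker blocks
(0.85 vs 0.10), which makes small mixtures exactly identifiable.

What the generator does **not** emulate: array chemistry (Type I/II
probes), sex chromosomes, batch structure, realistic linkage between
neighbouring probes, count-based transcript noise, or demographic age
structure.  Passing tests therefore demonstrate that the estimators
recover the structure they assume, at realistic effect sizes and noise
-- not that the pipeline is robust to artefacts the generator omits.

## Numerical and reproducibility choices

All randomness flows from named seeds (`numpy.random.default_rng`);
identical seeds give bit-identical outputs, and result files are written
with a fixed float format so pipeline reruns are byte-identical.  The
per-site OLS is solved once for all probes via the shared design's
normal equations; a design condition number above 1e8 is rejected with
the offending columns named.  Deconvolution renormalises NNLS solutions
so proportions sum to one within 1e-8.  BH adjustment is applied once
per family (all probes; all motifs; probes within a window center).
Stepwise ties break on probe id; pace-group ties break on sample id.

Default problem sizes used by the test-suite and acceptance runs (n=250
x p=2000 for DMP recovery and the clock; p=500-800 for confounding and
integration checks; a 160 x 1200 demo pipeline) were chosen as the
smallest cohorts at which the planted effects are comfortably
identifiable; all complete in minutes on a single CPU.

## Known limitations

* Moderated-variance (empirical-Bayes) test statistics are not
  implemented; a hook for a custom variance estimator is the natural
  extension point in `dmp.fit_site_models`.
* The empirical pairing null is uniform over non-candidate genes rather
  than matched on distance-rank distribution; on the synthetic data the
  two coincide because unlinked genes are exchangeable.
* Transcript differential analysis ignores count overdispersion.
* Sex-stratified (X/Y-inclusive) analysis and region-level (DMR) calling
  are out of scope.
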