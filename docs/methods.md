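# Methods

`sepstrat` implements an integrated transcriptomic/genetic analysis of
sepsis cohorts: unsupervised discovery of sepsis response signature (SRS)
patient groups from blood leucocyte expression, moderated-t differential
expression between groups, a sparse gene classifier for group assignment,
directional gene-set testing by rotation, covariate-adjusted cis/trans
eQTL mapping with group-specific calling, epigenetic-mark enrichment of
lead eSNPs, and survival analysis by group. Because patient-level data of
this kind cannot be redistributed, the package ships a synthetic cohort
generator that emulates the statistical structure these analyses assume
and carries the planted ground truth needed to score recovery.

## Synthetic cohort generator (`sepstrat.simulate`)

The generator plants, per cohort:

- **Two latent groups** of unequal size. Group labels are assigned
  deterministically (the first `ceil(f*n)` samples of a seeded shuffle),
  so group sizes are exact for testing. Default split 41%/59% at n = 265.
- **A differential-expression program** on `n_de_probes` probes (default
  3080 of 26 185). Signed log2 effects for group 1 are
  `±(0.585 + Exp(0.45))` — i.e. every planted effect exceeds the
  fold-change call threshold of 1.5 in expectation — with 73.4% of signs
  negative (the immunosuppressed group presents as a broadly repressed
  program).
- **Gene-wise noise variances** drawn from a scaled inverse chi-square
  `s0sq*d0/chi2(d0)` with defaults `d0 = 4`, `s0sq = 0.05` (log2 scale),
  so the empirical-Bayes moderation machinery operates under its own
  generating model. The draw is truncated at `sigma2_max = 2.0`: arrays
  that survive quality control and variance-stabilising normalisation do
  not contain probes with arbitrarily large noise, and the untruncated
  tail (variances up to ~40) produces single-sample outliers that
  dominate the most-variable-probe selection and distort cluster-number
  selection in a way real normalised data does not.
- **Additive eQTL effects**: 200 cis pairs (SNP within 1 Mb of the probe
  start on a synthetic genome of six 40 Mb autosomes plus one X-like
  chromosome) and 20 trans pairs (SNP on a different autosome), with
  |beta| uniform in [0.5, 1.5] log2 units per allele copy and dosages
  drawn Binomial(2, MAF), MAF uniform in [0.1, 0.5]. Twenty cis pairs are
  group-restricted (beta = 0 in the excluded group), alternating between
  group-1-only and group-2-only.
- **A cell-proportion confounder** (neutrophil fraction, mean 0.89 in
  group 1 vs 0.82 in group 2) loading on a random 10% of probes with
  N(0, 0.15) coefficients. The default strength is deliberately moderate:
  the study context this emulates exhibits cell-count confounding yet
  still shows a clean two-cluster structure with no within-group
  sum-of-squares reduction for k between 2 and 4, and a stronger gradient
  breaks that property.
- **Survival**: exponential event times with baseline hazard
  `-ln(0.90)/14` per day (10% 14-day mortality in group 2) multiplied by
  a hazard ratio of 2.4 in group 1 (≈22% 14-day mortality), with
  administrative censoring at 180 days.
- **Epigenetic-mark intervals**: four marks of fixed 1 kb width covering
  0.8% of each chromosome at random, plus targeted intervals over true
  cis eSNPs placed so each eSNP's total overlap probability is
  `enrichment_factor × background` (default factor 4, i.e. ≈3.2%).

All randomness flows from one seed through fixed-index `SeedSequence`
spawns (plan / genotypes / expression / survival / covariates / one
stream per mark), so each generation step is individually reproducible
and the whole cohort is bit-identical across runs.

What the generator does **not** emulate: raw intensity scale and
normalisation artefacts, batch effects, linkage disequilibrium between
SNPs, genotyping error, correlated gene-gene noise beyond the planted
confounder, and informative censoring. Tests passing on this generator
therefore demonstrate the correctness and calibration of the statistical
machinery under its stated assumptions, not robustness to every
real-data pathology.

## SRS discovery (`sepstrat.discovery`)

Samples are clustered on the top 10% most variable probes (variance with
denominator n−1; ties broken by probe id so selection is order-stable).
Ward minimum-variance agglomeration on Euclidean distances initialises
the partition, which Lloyd k-means then consolidates starting from the
hierarchical centroids — no random restarts, so the step is
deterministic; an empty cluster is re-seeded at the point farthest from
its assigned centroid.

The number of groups is the smallest k (in 2..4) whose within-group
sum-of-squares reduction at k+1 is no larger than noise. "Noise" is
measured on the data themselves: each probe's values are permuted across
samples (three seeded permutations), destroying any sample grouping
while preserving marginals, and the observed k→k+1 reduction must exceed
twice the median permuted reduction (plus a 0.1% absolute floor) to
justify k+1. A fixed relative threshold was rejected because the null
reduction from splitting structureless data depends strongly on the
sample count and the number of clustered probes; the permutation
reference adapts to both.

For k = 2, the group in which the majority of differentially expressed
probes (quick Welch-t pass at p < 0.01) are downregulated is named SRS1;
an empty or tied vote falls back to naming the smaller group SRS1 with a
warning.

## Differential expression (`sepstrat.de`)

Per-probe OLS against a shared design (intercept, SRS1 indicator,
optional covariates); the group coefficient is the log2 fold change.
Residual variances are shrunk by the standard hierarchical model:
`(d0, s0sq)` are estimated by matching the mean and variance of
`log s_g^2` against their digamma/trigamma expansions, with `d0`
obtained by Newton inversion of the trigamma function. The posterior
variance is `(d0*s0sq + df*s_g^2)/(d0 + df)` and the moderated t has
`d0 + df` degrees of freedom; `d0 = 0` reduces exactly to the ordinary
t and `d0 = ∞` pools all variances at `s0sq` with a normal reference.
Probes are called at |FC| > 1.5 (applied on the anti-log scale in both
directions) and Benjamini-Hochberg FDR < 0.05. Zero-variance probes are
excluded from moderation and reported with p = 1.

## Sparse signature classifier (`sepstrat.classifier`)

L1-penalised logistic regression over a 20-point penalty path, features
standardised internally with the scaling stored for exact reapplication.
The path point is chosen by the **extended BIC**
(`-2 loglik + k log n + 2 γ k log p`, γ = 0.5), which is consistent for
support recovery when features vastly outnumber samples. Cross-validated
deviance with the one-standard-error rule is available
(`penalty_selection="cv1se"`) but is not the default: spurious
whole-sample correlations are present in every CV fold, so CV deviance
keeps dozens of noise features in strong-signal regimes and occasionally
under the null, while EBIC recovers exactly the planted support in both.
When nothing survives the penalty the model degrades to an
intercept-only predictor (majority class, probability from the training
log-odds) that still records the strongest univariate feature with a
zero coefficient.

Leave-one-out cross-validation repeats everything — optional univariate
screening, the penalty path and the EBIC choice — inside each fold, so
the reported misclassification rate has no selection leakage. The
probability cut for class assignment is fixed at 0.5.

## Rotation gene-set test (`sepstrat.rotation`)

The data are transformed into the orthonormal effect space of the design
(QR with the contrast column last): one dimension carries the group
contrast, the remaining d−1 the residuals. Each signature gene's
moderated t is computed in that space, signs flipped so "down" genes
count positively when concordant, and the set statistic is the signed
mean. The null replaces the contrast direction with uniformly random
unit vectors in the d-dimensional effect space — preserving gene-gene
correlation — and the p-value is `(1 + #{rotations ≥ observed})/(n+1)`,
with floor `1/(n+1)`, right-tailed. `n_rotations = 0` returns the
statistic alone; fewer than 99 rotations is refused as too coarse.
Signatures are derived from reference DE tables by thresholding
(FDR < 0.05, |FC| > 1.5 per table), intersecting sign-consistent genes
across references, and restricting to the measured universe.

## eQTL mapping (`sepstrat.eqtl`)

Pairs are classed cis (same chromosome, |SNP − probe start| < 1 Mb),
trans (different chromosome, or > 2.5 Mb on the same chromosome,
restricted to autosomes by default), or excluded (the 1–2.5 Mb
same-chromosome gap). The probe start is used regardless of strand.
Expression and dosage are residualised once against the covariates
(expression PCs — 30 for the full cohort, 25 within each SRS group,
recomputed per group — always with an intercept), and every pair is then
a one-regressor OLS evaluated by vectorised cross-products; this is
algebraically identical to per-pair multiple regression and is checked
against a naive loop to 1e-8. BH FDR runs separately within the cis and
trans streams. Lead SNP per probe is the minimum-p record, ties broken
by larger |beta| then snp id. SRS-specific calls require FDR < 0.01 in
one group and > 0.05 in the other; pairs below 0.05 in both are shared.
Monomorphic SNPs in the analysed subset are skipped and counted.

## Epigenetic-mark enrichment (`sepstrat.epimarks`)

Intervals are merged per chromosome before testing. A SNP at 1-based
position p overlaps [s, e) iff s ≤ p−1 < e (binary search). The
comparator set is all SNPs within 1 Mb of any probe start. Overlap
proportions are compared by two-sided Fisher's exact test; distance to
the nearest mark (0 when inside; SNPs on chromosomes without marks are
excluded with a log note) by two-sided Mann-Whitney, exact only for tiny
untied arms, otherwise the tie-corrected normal approximation.

## Survival (`sepstrat.survival`)

Kaplan-Meier estimation (via lifelines) with Greenwood variance and
log-log 95% intervals; two-group log-rank; Cox proportional hazards with
Efron tie handling — appropriate for the day-granularity ties the
generator produces — plus an independently implemented partial-likelihood
score statistic at beta = 0 whose chi-square equals the log-rank
statistic for a binary covariate without ties (an identity the tests
verify numerically). Hazard-ratio CIs are Wald on the log scale; a
monotone likelihood (one group without events) is flagged and the CI
reported as unbounded on the affected side. Fixed-horizon mortality uses
raw proportions with exact binomial CIs when follow-up is
administratively complete, otherwise the KM complement with a flag.
Covariate comparisons use Welch t for continuous columns and chi-square
(Fisher for 2×2 tables with any expected count under 5) for
categoricals.

## Pipeline and problem sizes

`sepstrat pipeline run` executes simulate → discover → de → classify →
geneset → eqtl → epimarks → survive from one seeded config, writing
per-stage outputs, SHA-256 manifests and a markdown report (with a
recovery-vs-truth section whenever the generator's ground truth is
available). Reruns with the same config are bit-identical. The demo
configuration keeps all 265 samples at any `--scale` and thins only the
probe/SNP panels, because the cluster-number criterion is calibrated to
the cohort size. The test suite and `scripts/acceptance.py` use the full
265 × 26 185 layout for discovery-related checks and reduced panels
(≈2000 probes, ≈1500 SNPs, 20 000 random pairs) for eQTL recovery, which
keeps a complete run to a few minutes on one CPU without changing any
statistical setting.

## Known limitations

- Independent SNPs: no linkage disequilibrium, so lead-SNP recovery is
  easier than on real genotypes.
- The rotation test assumes the two-group linear model; it is not a
  competitive (between-set) test.
- The permutation-calibrated elbow decides only within k ∈ 2..4 and, like
  any elbow rule, can absorb genuine weak substructure into noise.
- Cox and KM assume non-informative censoring, which the generator's
  administrative censoring satisfies by construction.
- The classifier's EBIC criterion targets sparse supports; if the true
  signal were dense and weak, `cv1se` would be the better switch.
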