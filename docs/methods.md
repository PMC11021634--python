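# Methods

## The capture-recapture model

`clonetrack` treats a pair of TCR repertoire samples as a mark-recapture
experiment. Clonotypes (by default a CDR3 nucleotide sequence plus V
segment, alleles stripped) observed in a "pre" sample are the marked
population; the "post" sample is the recapture attempt. Clonotypes are
binned by their pre-sample UMI count into size groups — singleton (1),
doubleton (2), tripleton (3), large (4+) — and each group's capture
probability is the observed fraction

    P = n / N

with `N` the number of pre clonotypes in the group and `n` the number of
those also present in the post sample. Clonotypes present only in the post
sample ("novel") have no pre size group and never enter a capture record;
clonotypes present only pre-side are the "missing" mass that the model is
designed to explain.

Capture probabilities are modelled on the natural-log scale by ordinary
least squares:

    log P ~ size_group + log N_pre + log N_post + G

where `N_pre` and `N_post` are the unique-clonotype richness of the two
samples. These diversity covariates are what makes pairs of very different
sequencing depth comparable: under near-neutral sampling the intercept of
the size curve shifts with the post/pre diversity ratio, and the model
absorbs that shift instead of confounding it with biology. `G` is any set
of user factors — transplantation protocol, cell subset, antigen
specificity, "emerging" status — whose coefficients are interpretable as
log fold changes in capture probability at fixed size and diversity.

Assumptions worth keeping in mind:

* records are cell-level aggregates, not clone-level outcomes; the OLS
  error term conflates binomial counting noise (larger in small-`N` cells)
  with real heterogeneity. Rows are unweighted by default, matching a plain
  linear model; an inverse-variance weighting (`w = N P / (1 - P)`, the
  delta-method precision of `log P`) is available via `weighted=True`.
* pairs are pooled into one fit; there are no per-donor random effects.
  `include_pair=True` adds `pair_id` as a fixed covariate if desired.
* `log P` is undefined for cells with `n = 0`. The default policy drops
  those cells with a warning; `zero_policy="continuity"` substitutes
  `P* = (n + 0.5) / (N + 1)` everywhere instead. Dropping induces a mild
  survivor bias for very small cells, which is why degenerate single-clone
  cells are best avoided by merging bins (see below).

### Uncertainty per cell: the beta posterior

Each cell's capture rate carries a conjugate posterior under a uniform
prior, `Beta(n + 1, N - n + 1)`, exposed via `beta_posterior` and drawn by
`plot_beta_ridgeline`. It is a visualisation and reporting device only —
the regression uses log-transformed frequencies, never the posterior.

### Inference

The sequential (type-I) ANOVA reported by `CaptureResults.anova()` is
computed by successive least-squares projections onto growing design
blocks, strictly in declared formula order (size, then the diversity logs,
then each factor). This matches R's `anova()` convention for linear models;
it is built directly rather than delegated because patsy reorders
categorical terms ahead of numeric covariates, which would silently change
the decomposition. A projection-matrix oracle in the test suite pins the
implementation.

`compare_factor` refits the model with one factor added and reports its
coefficients against an explicit reference level, the factor's sequential
F p-value, and optionally a post-hoc two-sample t-test on the raw `log P`
values (Welch by default). Reference levels are always explicit because a
coefficient's sign is meaningless without one.

`permutation_factor_pvalues` permutes a factor column across records and
recomputes the factor's partial F p-value each time (a fast design-matrix
path, verified against the refit route). The fraction of permuted p-values
below 0.05 estimates the test's empirical type-I error; mild inflation
above the nominal level reflects the heteroscedasticity noted above.

### Size bins

Default bins are {1}, {2}, {3}, {4+}. For shallow sorted-subset samples
with too few clonotypes per bin, `SizeBins.from_spec("1,2,3+")` merges
tripletons into "large"; the singleton reference level and treatment coding
are unchanged. Size groups for capture analysis are always taken from the
pre-sample count; post-side groups are carried for reporting only.

## Population frequency and diversity

Under Poisson sampling, a clone of population frequency `phi` sampled at
depth `R` (cells, cDNA molecules, or UMIs) is captured with probability
`P = 1 - exp(-phi R)`. `infer_population_frequency` inverts this per size
group, `phi_s = -ln(1 - P_s) / R`, and averages with weights
`w_s = N_s / sum N` — the fractions of clonotypes per size group — to give
the frequency of a typical clone. Multiplying by a body-wide T-cell count
(default 1e11) turns `phi` into a rough cells-per-clone figure; at
`phi ~ 1e-8` this is ~1e3 cells.

Richness comparisons across depths use rarefaction: UMIs are subsampled
without replacement (multivariate hypergeometric), the bias-corrected Chao1
estimator `S_obs + f1 (f1 - 1) / (2 (f2 + 1))` is applied to the
downsampled table, and the estimate is averaged over seeded replicates
(default 100, at the minimum depth of the samples being compared). The
bias-corrected form is the default because the classical `f1^2 / (2 f2)`
diverges at `f2 = 0`; the classical form sits behind a flag. The analytic
rarefaction curve `sum_i 1 - C(T - c_i, d) / C(T, d)` is exposed for
checking the subsampler and for rarefaction plots.

## Specificity annotation

Clonotypes are labelled by lookup against a table of TCRs with known
specificity (a VDJdb export or a minimal two-column file). A clonotype is
"specific" when its CDR3 amino-acid sequence is within Hamming distance 1
(configurable) of a database entry; unequal lengths never match, and there
is deliberately no indel-tolerant mode — epitope-specific TCR neighbourhoods
are well captured by substitutions at fixed length, and Levenshtein matching
would blur clonotype identity. V-gene agreement is off by default and
available as a flag, as is nucleotide-level matching. The scan is
vectorised per sequence length and equals a naive all-pairs comparison
(property-tested).

## The synthetic-data generator

`simulate_timecourse` emulates the sampling process the model assumes:
a fixed clone catalogue with power-law rank frequencies (`f_i ∝ i^-alpha`,
default `alpha = 2`) or log-normal frequencies, multinomially sampled at
two time points. Perturbations applied before the post draw: a labeled
fraction of clones multiplied by an expansion factor (frequencies then
renormalise, so unexpanded clones are diluted — intended competition), and
a death fraction set to zero frequency. Identities are format-valid
synthetic TCRs (random non-stop codons between a cysteine and a
phenylalanine codon, translated amino-acid CDR3, real V/J gene names) so
every I/O path is exercised; there is no V(D)J generative model and no
recombination statistics. All randomness flows from the scenario seed via
`SeedSequence.spawn` (child 0: identities and labels; 1: pre draw; 2: post
draw), so outputs are bit-reproducible.

What the generator does *not* emulate: sequencing error and UMI collisions,
PCR amplification bias, clone birth (novel clones arise only by sampling,
not by generation), and the heavy contact between expansion and death that
real antigen responses show. Passing tests therefore demonstrate the
statistics under the sampling model, not robustness to library-preparation
artefacts.

### Test and acceptance problem sizes

The packaged checks run on scenarios chosen to mirror the study designs the
model targets while staying small:

* neutral ordering and factor calibration: 6 replicate pairs of 2x10^4
  clones at 10^5 UMIs per time point (pooled, as multi-donor fits pool
  pairs);
* capture-vs-count curve: 4 replicate pairs of 3x10^4 clones, depth
  3x10^5 pre and 9x10^4 post — a post/pre diversity ratio of ~0.3, in the
  range observed for repeat samplings years apart;
* expansion detection: 1% of clones expanded 50-fold, 6 pairs, depth ratio
  0.3 (lower baseline capture makes expansion effects visible);
* oracle equivalence: 1,000 random toy pairs over 15 keys, checked exactly.

With the power-law default, observed richness grows like the square root of
depth, so these settings yield hundreds to thousands of clonotypes per size
group — the regime where the capture model is intended to operate.

## Numerical notes and limitations

* Gene calls are truncated at the first `*` (and MiXCR score annotations
  stripped) before entering identity keys, since exports differ in allele
  annotation.
* Duplicate rows under an identity mode are merged by summing counts at
  read time; counts below 1 are an error, never silently dropped.
* A capture model fitted to a single pair has constant `N_pre`/`N_post`;
  those covariates are then absorbed into the intercept with a warning
  rather than producing a rank-deficient design. Genuinely aliased user
  factors still abort the fit, naming the aliased terms.
* Fold-change confidence intervals are delta-method on the log scale
  (exact for a contrast of coefficients) and exponentiated.
* `track_pair` output is sorted by clonotype key, so all downstream tables
  are invariant to input row order and reruns are byte-identical.
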