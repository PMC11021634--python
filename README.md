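# clonetrack

Capture-recapture statistics for T-cell receptor (TCR) repertoire time
courses.

Repertoire sequencing sees only a sliver of the T cells in a body, so when
a clonotype present in one sample is absent from the next, that is usually
sampling, not biology. `clonetrack` is for immunologists and
bioinformaticians who need to separate the two: it tracks clonotypes
between samples (time points, donor/recipient after HSCT, sorted subsets),
bins them by abundance, and models the probability of seeing a clonotype
again — so that real differences in clonal survival or expansion can be
tested on top of the sampling baseline.

## The model

Clonotypes in a "pre" sample are grouped by UMI count into **s** =
singletons (1), doubletons (2), tripletons (3) and large (4+) clonotypes.
For each group (optionally crossed with other labels), the recapture
probability in the "post" sample is

> *P* = *n* / *N*

where *N* clonotypes from the group were seen pre and *n* of them again
post. These cell-level probabilities follow a log-linear law,

> log *P* ~ **s** + log *N*<sub>pre</sub> + log *N*<sub>post</sub> + **G**

with *N*<sub>pre</sub>, *N*<sub>post</sub> the unique-clonotype richness of
the two samples (the covariates that normalise away unequal sequencing
depth) and **G** any grouping factors of interest — transplantation
protocol, cell subset, antigen specificity. Exponentiated coefficients are
fold changes in capture probability. Per-cell uncertainty is summarised by
the conjugate beta posterior Beta(*n*+1, *N*−*n*+1) for visualisation.

Supporting estimators: Chao1 richness normalised to analysis depth by
hypergeometric downsampling, and inversion of the Poisson capture law
*P* = 1 − exp(−*φR*) into per-clone population frequencies *φ*.

## Worked example

Simulate six replicate pre/post repertoire pairs with no biology at all —
20,000 clones with power-law sizes, multinomially sampled at 100,000 UMIs
per time point — then track, summarise and fit:

```python
import clonetrack as ct

scenario = ct.SimulationScenario(
    n_clones=20_000, depth_pre=100_000, depth_post=100_000, seed=11
)
records = ct.concat_records([
    ct.summarize_capture(ct.track_pair(pre, post, pair_id=f"pair{i}"))
    for i, (pre, post, _) in enumerate(ct.simulate_pairs(scenario, 6))
])
results = ct.fit_loglinear(records)
print(results.summary())
```

```
Log-linear capture model
  formula: log_P ~ C(size_group, Treatment(reference="singleton")) + log_N_pre + log_N_post
  records used: 24 (dropped 0 with P = 0)
  adjusted R^2: 0.9836   residual df: 18

                   name   estimate        se         t            p
              Intercept -14.635106 11.700444 -1.250816 2.270166e-01
size_group[T.doubleton]   0.850255  0.036004 23.615699 5.372202e-15
    size_group[T.large]   1.219642  0.036004 33.875363 9.333012e-18
size_group[T.tripleton]   1.077003  0.036004 29.913594 8.436005e-17
              log_N_pre   1.183069  1.008187  1.173461 2.559052e-01
             log_N_post   1.021149  1.117124  0.914087 3.727535e-01
```

Even with zero biological change, clonotype size dominates recapture: a
doubleton is `exp(0.85) ≈ 2.3` times more likely to be seen again than a
singleton, purely because two sampled molecules witness a bigger clone.
That is the sampling baseline any claim about survival or expansion must
beat. Consecutive fold changes with delta-method CIs:

```python
print(results.size_fold_changes()[["level_a", "level_b", "fold_change",
                                   "ci_low", "ci_high"]].round(2))
```

```
  level_a   level_b  fold_change  ci_low  ci_high
doubleton singleton         2.34    2.18     2.51
tripleton doubleton         1.25    1.17     1.35
    large tripleton         1.15    1.07     1.24
```

To test a biological factor, attach labels and compare: e.g. after
annotating clonotypes against a VDJdb export
(`ct.annotate_specificity(sample, db, max_mismatch=1)`) or labelling
clonotypes that emerged between two earlier time points
(`ct.flag_emerging(day0, day7)`),

```python
tracked.add_label("specific", annotation)          # per-key labels
records = ct.summarize_capture(tracked, group_by=["specific"])
cmp = ct.compare_factor(records, "specific", reference="False")
print(cmp.estimate, cmp.se, cmp.pvalue)            # log fold change of capture
```

The same workflows are scriptable from the shell:

```bash
clonetrack simulate --n-clones 20000 --depth-pre 100000 --depth-post 100000 \
    --seed 11 --out-dir sim/
clonetrack track --pre sim/pre.airr.tsv --post sim/post.airr.tsv --out-dir trk/
clonetrack fit --captures trk/captures.tsv --out-prefix fit/model
clonetrack annotate --input sim/pre.airr.tsv --db vdjdb.tsv --out annot.tsv
clonetrack diversity --input sim/pre.airr.tsv --depth auto --out div.tsv
```

Input tables may be AIRR Rearrangement TSV, MiXCR-style exports, or any
delimited table with a TOML column map (`--dialect generic`).

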