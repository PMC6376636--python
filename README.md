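# rhythmdiff

Differential analysis of rhythmic transcriptome data: detect genes that are
**rhythmic**, **differentially rhythmic** (their rhythm's amplitude or phase
changes between conditions), or **differentially expressed** (their average
level changes, accounting for rhythmicity) from circadian time-course
expression experiments — two-condition designs (e.g., wild-type vs. clock-gene
knockout mice), designs with a continuous moderator (e.g., donor age), and
subject-blocked time-of-day designs.

## The model

Cosinor regression turns time of day into linear covariates: a sample taken at
zeitgeber/circadian time `t` (hours) enters the model through
`cos θ` and `sin θ` with `θ = 2πt/24`.  For a two-condition design with
condition indicator `h`, each gene `g` is fit to

    E(y_gi) = β_g0 + β_g1 h_i + β_g2 cos θ_i + β_g3 sin θ_i
              + β_g4 h_i cos θ_i + β_g5 h_i sin θ_i

Differential rhythmicity is the hypothesis that both interaction coefficients
(β_g4, β_g5) are zero; differential expression is the main effect β_g1 in the
additive model (interaction terms removed).  Because every hypothesis is a
coefficient set in a linear model, arbitrary covariates — continuous age,
brain region, subject blocks, extra harmonics, a linear drift term — slot in
without changing the machinery.

Inference uses empirical-Bayes moderated statistics: gene-wise residual
variances `s_g²` are shrunk toward a scaled inverse-chi-square prior (df `d0`,
scale `s0²`, optionally a smooth function of average expression — the
mean-variance trend) estimated from all genes by moment matching on `log s_g²`,
and t/F statistics use the posterior variance
`s̃_g² = (d0·s0² + d_g·s_g²)/(d0 + d_g)` with `d0 + d_g` denominator degrees of
freedom.  p-values are converted to q-values by Benjamini–Hochberg step-up.

The three-step workflow:

1. **Rhythmicity** — per-condition cosinor moderated F (or an external
   per-condition p-value table); the minimum p across conditions gives
   `q_rhy`, the maximum gives `q_rhy_max` (rhythmic in *both* conditions).
2. **Differential rhythmicity** — interaction moderated F on genes with
   `q_rhy ≤ 0.01`, giving `q_dr`.
3. **Differential expression** — main-effect moderated t on genes *without*
   strong evidence of differential rhythmicity (`q_dr > 0.1` or
   `q_rhy > 0.01`), giving `q_de` and a log₂ fold-change.

Rhythm amplitude `A = √(β_cos² + β_sin²)` (half peak-to-trough) and acrophase
(peak time, `atan2(β_sin, β_cos)·24/2π` mod 24) are reported per condition,
with Δamplitude (arithmetic) and Δacrophase (circular, in (−12, +12] h,
positive = phase advance in the alternate condition).

A seeded simulation module generates two-condition datasets with known truth
labels (sinusoidal signal, additive Gaussian noise), and an evaluation module
scores differential-rhythmicity detection by exact ROC/AUC and the true
positive rate at a nominal p cutoff.  A within-timepoint label-permutation
null estimates false-positive tendency on any dataset.

## Worked example

```python
from rhythmdiff import (SimulationSpec, WorkflowConfig, generate_dataset,
                        run_two_condition_workflow)

spec = SimulationSpec(n_genes=2000, n_dr=100, delta_amp=1.5, delta_phase=None)
expr, meta, truth = generate_dataset(spec, seed=1)
result = run_two_condition_workflow(expr, meta, WorkflowConfig())
print(result.class_counts().to_string())
```

```
label
non-rhythmic               1574
rhythmic-only               325
differentially-rhythmic     101
```

The generator planted 100 differentially rhythmic genes (amplitude difference
1.5 about a mean amplitude of 1, noise SD 1) among 500 rhythmic genes; the
workflow recovers 101 DR calls at `q_rhy ≤ 0.01`, `q_dr ≤ 0.1`.  The strongest
calls carry their estimated rhythm-parameter changes:

```python
print(result.table.nsmallest(3, "q_dr")[
    ["gene_id", "q_rhy", "q_dr", "delta_amplitude", "delta_acrophase"]])
```

```
  gene_id    q_rhy     q_dr  delta_amplitude  delta_acrophase
gene_1921 1.12e-09 1.42e-06              1.5            -9.01
gene_1935 1.12e-10 5.88e-05             1.96            -6.47
gene_1957 1.62e-09 6.88e-05             1.44             6.32
```

Here `delta_amplitude ≈ 1.5` matches the planted effect; Δacrophase is noisy
for genes that are nearly arrhythmic in one condition, as the peak time of a
flat curve is poorly determined.

The same analyses are available from the shell:

```sh
rhythmdiff simulate --seed 1 --out run/sim
rhythmdiff fit --expr run/sim/expression.tsv --meta run/sim/metadata.tsv --out run/fit
rhythmdiff evaluate --results run/fit/results.tsv --truth run/sim/truth.tsv --out run/eval
rhythmdiff permute --expr run/sim/expression.tsv --meta run/sim/metadata.tsv \
    --seed 1 --out run/perm
```

Every command writes a JSON sidecar with the resolved configuration and seed;
identical invocations produce byte-identical outputs.

## Documentation

See `docs/methods.md` for the statistical model, estimation details, defaults
and their rationale, numerical choices, and known limitations.
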