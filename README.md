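# tsdbn

Two-slice conditional-Gaussian dynamic Bayesian networks (DBNs) for
longitudinal compositional microbiome data.

Given a longitudinal cohort of per-sample taxon counts plus clinical
covariates, `tsdbn`:

- converts counts to relative abundances and pairs each sample with the
  immediately preceding sample of the same subject (`tsdbn.data_io`);
- scores and fits conditional linear Gaussian families with a conjugate
  normal–inverse-gamma prior (equivalent sample size ν, assumed variance
  σ²₀) and Dirichlet–multinomial families for discrete nodes
  (`tsdbn.cgbn_core`);
- learns a two-slice structure (edges only from time *t* to *t+1*) by
  greedy hill climbing with per-edge natural-log Bayes factors
  (`tsdbn.structure_search`);
- predicts next-sample composition via the CLG expectation, renormalizes
  to the simplex, and evaluates by leave-one-subject-out and subject-level
  k-fold cross-validation with paired t-test comparisons
  (`tsdbn.prediction_eval`);
- scores each observed transition's −log10 plug-in likelihood, converts to
  z-scores and flags abruption events at one-sided p < α/m
  (`tsdbn.abruption`);
- iterates predictions forward from arbitrary initial conditions,
  including a six-scenario convergence suite (`tsdbn.trajectory`);
- generates synthetic cohorts from a known ground-truth model with a
  Bacilli → Gammaproteobacteria → Clostridia succession pattern, injectable
  abruptions, and planted-VAR recovery benchmarks
  (`tsdbn.synthetic_data`).

Two prior regimes are preset: sparse (ν=10, σ²₀=1, ≤3 parents) and dense
(ν=50, σ²₀=1, ≤5 parents).

## CLI

```sh
# synthetic 58-subject cohort
tsdbn simulate-cohort --out cohort.csv --seed 1

# learn a structure + parameters (sparse regime by default)
tsdbn learn --input cohort.csv --out run/

# leave-one-subject-out evaluation
tsdbn evaluate --input cohort.csv --out run/

# abruption scan (two-stage: scan, exclude flagged subjects, rescan)
tsdbn abruptions --input cohort.csv --out run/

# iterative forward simulation from the six standard initial conditions
tsdbn simulate-forward --fitted run/fitted.json --out run/ --steps 20

# everything at once
tsdbn run --input cohort.csv --out run/
```

All subcommands accept `--config config.yaml` (flags override file
values), `--regime sparse|dense`, `--nu/--sigma2/--max-parents`, and
`--exclude-vars/--exclude-taxa` for sensitivity reruns.

## Input format

CSV/TSV with one row per sample: `subject_id`, `day_of_life`,
`gestational_age_at_birth`, `postconceptional_age`, `antibiotics`,
`open_room`, then one integer count column per taxon.  A reader for the
original study spreadsheet is included (`format="study-xlsx"` with the
column mapping in `src/tsdbn/study_mapping.yaml`).

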