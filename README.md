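# mbrisk

Markov-blanket and interaction learning for discrete clinical risk-factor
tables, with a synthetic-cohort generator and a reporting layer for
partner-frequency tables.

Given a flat table of categorical predictors and a binary outcome per
follow-up horizon (5/10/15 years), the package:

1. scores candidate parent sets of the outcome with the **BDeu** log
   marginal likelihood at a configurable prior equivalent sample size
   (alpha, e.g. 1 / 120 / 480);
2. reports **interactive risk factors** — variable sets whose joint family
   score beats every proper subset (a nonadditive joint effect) — ranked by
   score;
3. learns the outcome's **Markov blanket** (its direct causal sets, both
   singles and interactive sets) by greedy forward selection with backward
   pruning over those candidates;
4. **tabulates** per-focus partner frequencies, per-horizon counts and
   causal-set listings, merging race/ethnicity, smoking/alcohol and the two
   lymph-node columns for quantitation.

A packaged schema describes the 31-predictor clinical table; a ground-truth
network builder plus forward sampler produce test cohorts with planted
single, pairwise-XOR and three-way "jackpot" effects, so learner recovery
is testable end to end without any real data.

## Layout

| module | contents |
| --- | --- |
| `mbrisk.schema_io` | variable schema, CSV dataset I/O, discretization, result files |
| `mbrisk.bdeu` | count tables, BDeu local score, sequential-predictive oracle, score cache |
| `mbrisk.learner` | interaction detection, blanket search, full (horizon × alpha) sweep |
| `mbrisk.synthetic` | ground-truth specs, forward sampling, recovery metrics |
| `mbrisk.report` | variable merging, partner-frequency tables, causal-set rendering |

Packaged data (`mbrisk/data/`): the clinical schema
(`clinical_schema.yaml`) and verbatim transcriptions of published per-focus
partner-count tables (`interactions_alpha{1,120,480}.csv`).

## CLI

```sh
mbrisk simulate --spec builtin:clinical --n 5000 --seed 1 --out cohort.csv
mbrisk validate --data cohort.csv
mbrisk learn --data cohort.csv --alphas 1,120,480 --horizons 5,10,15 \
             --max-size 3 --out results/
mbrisk tabulate --alpha 480 --focus HER2
```

`learn` writes `results.csv` (one row per reported set), a plain-text
causal-set summary and a `search.log` recording every accepted/rejected
greedy step. Built-in simulation specs: `builtin:clinical` (31-predictor
schema-shaped cohort with planted effects), `builtin:benchmark`
(17-variable binary network with in- and out-of-blanket XOR pairs),
`builtin:null` (outcome independent of all predictors).

## Notes

- Scores are natural-log marginal likelihoods under a uniform structure
  prior (no structure-prior term).
- Missing cells (token `NA`) map to an explicit per-column "missing"
  category; records are never dropped.
- Binned-numeric variables use lower-inclusive / upper-exclusive bins with
  the last bin open above; raw numbers in a CSV are discretized on load.
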