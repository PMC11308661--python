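# ticonomics

Utility mapping plus decision-tree cost-utility analysis for oral
aripiprazole dosing in children and adolescents with tic disorders.

The package has two stages:

1. **Mapping** — regressions converting Yale Global Tic Severity Scale
   (YGTSS) scores to EQ-5D-Y utility indices. Two families (Gaussian-identity
   linear regression and logit-link beta regression) are crossed with four
   predictor sets (total score; motor + vocal subscores; each plus sex),
   compared on AIC/BIC, adjusted R², MAE and RMSE. Beta regression first
   squeezes observed utilities into (0, 1) with the boundary transform
   `(y·(N−1) + 0.5) / N`. A fixed reference total-score mapping
   (`0.9881 − 0.0035 × total score`) feeds the economic model. Because the
   original survey data are not public, a synthetic-cohort generator
   (`ticonomics.cohort`) reproduces the survey's marginal structure —
   including the utility ceiling at 1 — so the mapping stage is fully
   testable.
2. **Cost-utility analysis** — a 52-week decision tree comparing low-dose
   (5 mg/day) and high-dose (10 mg/day) strategies (plus placebo): branch on
   adverse-event discontinuation, then on a post-hoc / partial / non-response
   split among continuers. Outputs per-arm expected cost, expected QALYs,
   responder counts per 1000 patients, the pairwise ICER/dominance
   classification and net monetary benefit, plus one-way sensitivity
   (tornado), a 1000-iteration probabilistic sensitivity analysis,
   cost-effectiveness acceptability curves and a plot-ready incremental
   scatter export.

The utility assigned to the AE-discontinuation branch is underdetermined by
the reference inputs; three explicit conventions are implemented
(`baseline_minus_disutility` — default, `nonresponse_minus_disutility`,
`response_mix_minus_disutility`) and selectable everywhere QALYs are
computed. Under all three, the high-dose strategy is dominated at baseline
(costlier and fewer QALYs), so it is not cost-effective at the
$36,832.95/QALY threshold regardless of convention.

## Command line

All commands accept `--params <file.yaml>` (see `examples/params.yaml`;
omitted fields fall back to built-in baselines) and exit with status 2 on
validation errors.

```bash
ticonomics simulate-cohort --n 144 --seed 2 --out cohort.csv
ticonomics fit-mapping --cohort cohort.csv --family gaussian --model 1 --out fit.json
ticonomics compare-models --cohort cohort.csv --out mapping_comparison.csv
ticonomics run-cea --out cea_results.csv
ticonomics owsa --out tornado.csv
ticonomics psa --iterations 1000 --seed 20240807 --out psa.csv
ticonomics ceac --psa psa.csv --wtp-max 200000 --step 1000 --out ceac.csv
ticonomics scatter --psa psa.csv --wtp 36832.95 --out scatter.csv
ticonomics full-run --out-dir out/ --seed 7     # whole pipeline + manifest
```

`full-run` writes a bundle (cohort, mapping comparison, base-case table,
tornado, PSA, CEAC, scatter, JSON manifest with seeds and a config hash);
stochastic outputs are byte-identical across reruns of the same
configuration.

## Python API sketch

```python
from ticonomics import (
    CohortConfig, generate_cohort, MappingSpec, fit_mapping,
    default_parameters, evaluate_arm, icer, default_ranges, run_psa, ceac,
)

records = generate_cohort(CohortConfig(n=144, seed=2))
fit = fit_mapping(records, MappingSpec("beta_logit", 1))

params = default_parameters()
low = evaluate_arm(params.low, params.econ, params.util)
high = evaluate_arm(params.high, params.econ, params.util)
print(icer(low, high))

psa = run_psa(params, default_ranges(params), n_iterations=1000, seed=0)
print(ceac(psa, [params.wtp]))
```
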