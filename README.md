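# vaxtrace

Process-tracing analysis and hierarchical Bayesian prospect-theory
modelling of COVID-19 vaccination decisions.

People deciding whether to accept a vaccine can inspect evidence about its
side effects, benefits, and their probabilities — or deliberately ignore
some or all of it.  `vaxtrace` implements the full computational pipeline
for studying such decisions with Mouselab-style process tracing:

* a packaged **vaccine evidence table** (8 licensed COVID-19 vaccines ×
  3 side effects + 3 benefits, with per-million frequencies and
  effectiveness percentages);
* **preprocessing** of hover-event logs into trial-level deliberate-
  ignorance levels (full / partial / none) and probability-neglect indices
  (by outcome category and side-effect severity), after removing incidental
  inspections (< 200 ms);
* a **hierarchical prospect-theory decision model**: for individual *i*
  and vaccine *v*,

      P(accept) = logistic(β_i + X_v·β_j + φ·V_iv),
      V_iv = Σ_se v(a_se)·w(p_se) + Σ_b v(a_b)·w(p_b),

  with loss-averse valuation of signed affect ratings
  (v(a) = −λ_i·|a|^α for side effects, (1−λ_i)·a^α for benefits, 0 for
  ignored outcomes), Prelec probability weighting
  w(p) = exp(−(−ln p)^γ_i) for inspected probabilities and w = 0.5 for
  neglected ones, and individual parameters (β_i, λ_i, γ_i) drawn from a
  multivariate normal hierarchy on the probit scale — fitted per attitude
  group (anti / neutral / pro) with an in-package NUTS sampler over the
  hand-derived joint density and gradient;
* **supporting hierarchical regressions** (logistic and cumulative
  ordered-logit, participant random intercepts, sum-to-zero contrasts,
  Student-t(3, 0, 2.5) priors) with HDI-based pairwise comparisons;
* a **synthetic-cohort generator** that samples complete study datasets
  (participants, affect ratings, hover logs, decisions) from the model
  with known ground truth, so every stage is testable against planted
  values.

See `docs/methods.md` for the model, priors, sampler and design choices.

## Worked example

Generate a synthetic group, preprocess its logs, fit the decision model at
the default configuration (4 chains × (2000 + 3000), thinned by 2 → 6000
draws), and check that the group-level posteriors recover the generating
parameters:

```python
import vaxtrace as vt
from vaxtrace import cohort, inspection, ptmodel, inference

table = vt.load_evidence_table()
config = cohort.default_cohort_config(sizes={"anti": 0, "neutral": 200, "pro": 0})
bundle = cohort.generate_cohort(config, seed=0)
frame = inspection.process_events(bundle.events, bundle.decisions, table)
ds = ptmodel.build_model_dataset(table, bundle.ratings, frame, bundle.decisions)

fit = inference.fit_pt_model(ds, inference.SamplerConfig(seed=0))
truth = bundle.truth["groups"]["neutral"]
report = inference.recovery_report(
    {"beta": truth["beta"], "lambda_probit": truth["lambda_probit"],
     "gamma_probit": truth["gamma_probit"], "alpha": truth["alpha"],
     "phi": truth["phi"]},
    fit,
)
print(report.to_string())
print("max R-hat", fit.max_rhat(), "draws", fit.n_recorded)
print("LOO balanced accuracy",
      inference.posterior_predictive_accuracy(fit, ds, "loo"))
```

Output (≈ 6 minutes on one core):

```
       parameter     truth    median   hdi_low  hdi_high  covered   bias_sd
0           beta -0.600000 -0.432494 -0.822988 -0.055559     True  0.849043
1  lambda_probit  0.841621  0.508050 -0.701544  1.503278     True -0.593455
2   gamma_probit  0.253347 -0.166467 -1.599143  1.518965     True -0.540815
3          alpha  1.000000  0.988124  0.305101  1.970171     True -0.025520
4            phi  0.300000  0.219311  0.002438  0.574205     True -0.484752
max R-hat 1.0026032891424675 draws 6000
LOO balanced accuracy 0.7230812531327528
```

Every 95% HDI covers its generating value (`covered`), chains are well
mixed (R-hat < 1.01 on all ~600 coordinates), and the model classifies
held-out decisions well above chance: with 200 participants × 8 trials the
group-level hierarchy is recovered even though each individual contributes
only eight binary decisions.

The same pipeline runs from the shell:

```bash
vaxtrace run-all --config config.yaml --seed 7 --out-dir out/
```

with stages `generate`, `preprocess`, `fit-pt`, `fit-assoc`, `report`
(also available as individual subcommands); outputs land in `out/` as CSV /
JSON plus a markdown report, with a manifest of checksums for the
deterministic stages.

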