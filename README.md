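# gaitlda

Gait phenotyping of dystrophic dogs by canonical linear discriminant
analysis.

Golden retriever muscular dystrophy (GRMD) dogs are the large-animal model
of Duchenne muscular dystrophy, and objective, longitudinal outcome
measures of their locomotion are needed to evaluate candidate therapies
during the growth period (roughly 2–12 months of age).  Trunk-mounted
accelerometry summarizes each 10-second walking sequence by seven gait
parameters — stride frequency (SF), stride regularity (Reg), total power
of accelerations (TP), the cranio-caudal, dorso-ventral and medio-lateral
fractions of that power (CCP/TP, DVP/TP, MLP/TP), and stride length
normalized to height at withers (SL/HW).  Dystrophic gait shows lower
power, regularity, stride frequency and relative stride length, and a
power shift from the cranio-caudal to the medio-lateral axis.

This package implements the full analysis pipeline for such data, for
preclinical researchers working with quadruped gait accelerometry:

* **Canonical LDA from first principles** (`gaitlda.lda`): solves
  S_B v = λ S_W v by Cholesky whitening of the pooled within-group
  scatter; returns at most g − 1 canonical axes F1…F(g−1) with
  eigenvalues λᵢ, canonical correlations √(λᵢ/(1+λᵢ)), variance-explained
  fractions, factor loadings, Gaussian membership probabilities
  P(k|x) ∝ πₖ·exp(xᵀΣ⁻¹μₖ − ½μₖᵀΣ⁻¹μₖ), observation-coverage and
  standard-error confidence ellipses, and exact refit-per-fold
  leave-one-out (LOO) validation.
* **Three model designs** (`gaitlda.models`): Model 1 discriminates
  genotype (Healthy vs GRMD); Model 2 uses genotype × half-month age
  classes (Healthy_2…Healthy_9.5, GRMD_2…GRMD_12); Model 3 adds age in
  days as an eighth explanatory variable, which separates neighbouring age
  classes while keeping the genotype axis.
* **Blind phenotype calling** (`gaitlda.phenotype`): per time point the
  posterior mass on Healthy classes is averaged over replicate sequences;
  p > 0.95 is a healthy-like gait, p < 0.05 a GRMD-like gait, anything
  between intermediate; a dog is called Healthy/GRMD when strictly more
  than half of its time points agree, otherwise "n.c.".
* **Treatment evaluation** (`gaitlda.treatment`): centroid trajectories of
  a treated cohort on the (F1, F2) plane with mean-confidence ellipses,
  traffic-light colours (green/yellow/red by the same membership rule) and
  a calibrated age-in-days axis projected onto the plane.
* **A synthetic cohort generator** (`gaitlda.synthetic`): longitudinal
  cohorts sampled twice monthly with ±7-day age jitter, shared
  within-group covariance (the LDA assumption), per-dog random intercepts,
  dystrophic-biased dropout of the second run, and a treated cohort whose
  means interpolate between the GRMD and healthy trajectories.  The real
  colony data are not public; the generator provides cohorts with the same
  statistical structure so every stage is testable end to end.

## Worked example

```python
import gaitlda as g
import gaitlda.models as gm

obs = g.apply_regularity_filter(g.simulate_cohort(g.default_config(seed=1)))
spec = gm.model_spec(3)                      # gait variables + age (days)
fitted = gm.fit_model(obs, spec)
data, _ = gm.build_design(obs, spec)
report = gm.run_report(fitted, data, loo=True)
print(round(100 * report["variance_explained_f1_f2"], 1))          # 99.9
print([round(c, 2) for c in fitted.model.canonical_correlations[:2]])  # [1.0, 0.97]
print(round(100 * report["loo"]["misclassification_rate"], 1))     # 4.3
print(100 * report["loo"]["phenotype_misclassification_rate"])     # 0.0
```

The two leading canonical axes carry 99.9 % of the between-class variance;
full-class LOO misclassification is 4.3 % (age classes half a month apart
are occasionally confused) but collapses to 0.0 % once predictions are
read at genotype level — the same structure as a Model 2 fit without age,
where full-class confusion is high (88.1 %) yet genotype confusion stays
near zero.  The same thing from the shell:

```sh
gaitlda simulate --seed 1 --out obs.csv
gaitlda fit --model 3 --input obs.csv --out model.json --report report.json
gaitlda classify --model model.json --input obs.csv --grid grid.csv
gaitlda evaluate-treatment --model model.json --input obs.csv \
        --plot fig.png --table trajectory.csv
```

`gaitlda run --seed 1 --out-dir run/` chains everything and stamps each
artifact with the configuration hash and seed.

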