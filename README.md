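# phenoclust

Subtyping of heterogeneous clinical cohorts by consensus clustering of mixed
continuous and categorical data.

Many common conditions — lower urinary tract symptoms, asthma, type 2
diabetes, sepsis — are symptom complexes rather than single diseases:
patients present overlapping combinations of symptoms with different
underlying mechanisms.  `phenoclust` is for biostatisticians and clinical
researchers who want to identify such subtypes from baseline study data
that mix continuous measurements (questionnaire scores, exam values) with
binary-expanded categorical variables (comorbidities, medication use),
contain missing values, and may include a data domain observed on only part
of the cohort (e.g. diary measurements returned by a subset of
participants).

## The method

Given cases `A_in` and a control reference population:

1. **Multiple imputation** (pluggable; seeded chained-regression default).
2. **Control-referenced scaling** `S_in = (A_in − Ā_iC)/σ_iC`: standardize
   by the *control* mean and SD, not the cohort's, so subtype-driven
   multimodality is not shrunk the way cohort z-scores would shrink it.
3. **Redundancy weighting** `w_i = 1/(1 + c_i/c̄)` with `c_i` the mean
   absolute correlation of variable i with the rest — the least redundant
   variable weighs most.
4. **Row normalization** to unit weighted length, so the *pattern* rather
   than overall severity drives clustering.
5. **Consensus k-means**: 1000 resamples of 80% of subjects, k-means with 8
   restarts, `M_nq = Q_nq/I_nq` the empirical probability of co-clustering,
   averaged over imputations.
6. **Weighted Tanimoto distance** for binary indicators, each weighted by
   `w_j²·erf(γ_j)²` where `γ_j = |ln(F_j/F_jC)|` compares case and control
   frequencies (an indicator equally frequent in both drops out).
7. **Fusion** `D_nq = sqrt(((1−M_nq)² + μ²(1−T_nq)²)/(1+μ²))` with
   `μ = Σw_cat/Σw_cont`.
8. **Semi-supervised refinement** `G_nq = max(D_nq + ρ(BD_nq − mBD), 0)` for
   pairs inside the fully observed subset, where `BD` is the pairwise
   distance recomputed with the extra domain included.
9. **Selection** of (K, ρ) by maximizing the **contrast criterion**
   `CC = mean_k (within-cluster similarity − similarity to the rest)`,
   with the **proportion of core cluster members** (PCC: fraction of
   subjects with `π_nk > 0.5` for their own cluster) reported alongside,
   plus PAC, consensus score, CDF delta-AUC and classical indices.

See `docs/methods.md` for assumptions, edge conventions, and limitations.

## Worked example

```python
import phenoclust as pc

cfg = pc.SimulationConfig(n_cases=150, n_controls=40, n_continuous=12,
                          n_binary=10, k_true=3, effect_size=2.0,
                          missing_rate=0.05, subset_fraction=0.35,
                          n_subset_vars=3, seed=42)
sim = pc.generate_cohort(cfg)

pcfg = pc.PipelineConfig(seed=7, n_imputations=3, n_resamples=100,
                         k_range=[2, 3, 4, 5], rho_grid=[0.0, 0.3, 0.6])
res = pc.SubtypeModel(sim.cases, sim.controls, pcfg).fit()
print(res.summary())
print("misclassification vs planted truth:",
      round(pc.misclassification_error(sim.true_labels, res.labels), 4))
```

```
Consensus subtyping results
===========================
subjects: 150   controls: 40   subset: 52
selected K = 3, rho = 0.6, mu = 0.7907
contrast criterion CC = 0.4634   overall PCC = 0.6704
PCC elbow K (second-difference) = 3

cluster   size   contrast   PCC
      1     57     0.4484   0.667
      2     50     0.4963   0.740
      3     43     0.4455   0.605

criterion grid (per K at selected rho):
 K    rho     CC    PCC    PAC     CS
 2 0.6000 0.2817 0.4279 0.8072 0.4724
 3 0.6000 0.4634 0.6704 0.5558 0.5337
 4 0.6000 0.3357 0.2994 0.5621 0.4427
 5 0.6000 0.3190 0.2170 0.5582 0.4265

misclassification vs planted truth: 0.0467
```

The scan correctly prefers K = 3 (the planted number of subtypes): the
contrast criterion peaks there (0.4634 against 0.28–0.34 elsewhere), the
proportion of core members jumps to 0.67, and the ambiguity measure PAC
drops.  The final partition misassigns under 5% of subjects relative to the
planted truth.  `res.plot_consensus()`, `res.plot_criteria()` and
`res.plot_radar()` draw the reordered consensus heat map, the criterion
curves, and per-cluster profile radars; `res.pairwise_tests()` returns the
per-variable rank-sum/chi-square comparisons with BH-FDR per cluster pair.

The same pipeline runs from the shell:

```sh
phenoclust simulate --seed 42 --out cohort/
phenoclust run --cases cohort/cases.csv --meta cohort/meta.csv \
               --controls cohort/controls.csv --seed 7 --out results/
```

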