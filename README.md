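# rcdgp — regulated-cell-death gene-pair prognostic signatures

`rcdgp` builds and evaluates a **normalization-free prognostic score for
glioma transcriptomics** based on regulated cell death (RCD). The unit of
information is the within-sample comparison of two genes,

```
Score(x, y) = 1  if E_x > E_y,   0  if E_x ≤ E_y
```

and a patient's risk score is the integer sum over a fitted panel of such
pairs,

```
RCD.GPscore = Σ_i RCD.GP(i) .
```

Because each indicator depends only on the ordering of two genes *inside the
same sample*, the score is invariant to any per-sample monotone transform of
expression — it transfers across cohorts, platforms and normalization
pipelines without renormalization. The package is aimed at computational
oncologists who want to build, audit or stress-test such rank-based
signatures, and ships every stage of the surrounding analysis:

* **synthetic data** (`rcdgp.synthetic`) — multi-cohort bulk expression +
  survival with planted pathway activities, subtypes and prognostic gene
  pairs; a small single-cell counts generator with cell-type structure.
* **pathway scoring** (`rcdgp.scoring`) — single-sample ssGSEA (weighted
  running sum over the per-sample gene ranking) for bulk data and AUCell
  (top-rank recovery-curve area) for single cells; median-split grouping and
  the per-cell dominant-RCD call.
* **subtyping** (`rcdgp.subtype`) — consensus clustering (subsampled PAM /
  k-medoids, co-clustering consensus matrix, PAC model selection) and
  Wilcoxon rank-sum differential expression with BH adjustment.
* **candidate funnel** (`rcdgp.candidates`) — per-pathway Spearman (Ga) and
  median-split rank-sum (Gb) gene associations, the geometric-mean `C.gene`
  filter (geometric mean of |rho| over qualifying pathways > 0.3), and the
  intersection with cluster DEGs.
* **the signature** (`rcdgp.pairs`, `rcdgp.model`) — all C(n,2) pair
  indicators, a vectorised Efron-tie univariate Cox screen, the dual-cohort
  retention rule (Wald p < 0.05 in both discovery cohorts) and the integer
  score, wrapped in a statsmodels-style
  `GenePairSignatureModel` → `fit()` → `GenePairSignatureResults` interface.
* **survival evaluation** (`rcdgp.survival_eval`) — maximally selected
  rank-statistic cutpoints, Kaplan–Meier/log-rank, Cox models, Harrell
  C-index, IPCW time-dependent AUC at 12/36/60 months, and fixed-effect +
  DerSimonian–Laird meta-analysis of per-cohort hazard ratios.
* **consensus feature screen** (`rcdgp.mlscreen`) — the four-step
  therapeutic-target funnel with a 14-variant vote (Lasso, elastic net at
  α = 0.1…0.9, componentwise Cox likelihood boosting, Boruta with
  survival-forest importance, random survival forest, Cox-objective XGBoost);
  genes selected by ≥ 10 variants in both cohorts pass.
* **io + CLI** (`rcdgp.io`, `rcdgp.cli`, `rcdgp.pipeline`) — TSV/GMT/MTX
  readers and writers, a YAML-configured end-to-end pipeline with a JSON run
  manifest, and the `rcdgp` command with subcommands
  `simulate score cluster pairs evaluate screen run-all`.

## Worked example

```python
from rcdgp import CohortSpec, generate_cohort, GenePairSignatureModel

truth_spec = CohortSpec(n_samples=500, pair_beta=1.0, seed=100)
expr_a, surv_a, truth = generate_cohort(truth_spec, sample_prefix="A")
expr_b, surv_b, _ = generate_cohort(
    CohortSpec(n_samples=500, pair_beta=1.0, seed=101), truth, "B")
expr_h, surv_h, _ = generate_cohort(
    CohortSpec(n_samples=400, pair_beta=1.0, seed=102), truth, "H")

genes = sorted({g for p in truth.planted_pairs for g in p})
model = GenePairSignatureModel(
    {"gbm": (expr_a, surv_a), "glioma": (expr_b, surv_b)}, genes=genes)
results = model.fit()
results.evaluate(expr_h, surv_h, cohort="holdout")
print(results.summary())
```

prints

```
RCD gene-pair signature
======================================================
pairs in signature : 85
genes in signature : 20
  funnel candidate_genes         : 20
  funnel genes_in_both_cohorts   : 20
  funnel pairs_built             : 190
  funnel pairs_after_portability : 183
  funnel pair_universe           : 183
  funnel pass_cohort_a           : 103
  funnel pass_cohort_b           : 101
  funnel pass_both               : 85
  funnel alpha                   : 0.05
------------------------------------------------------
cohort holdout: n=400, events=275
  high-vs-low HR 1.77 (95% CI 1.32-2.37), log-rank p 1.15e-04 (selection-corrected 2.11e-03)
  C-index 0.574; AUC 12m 0.589, 36m 0.591, 60m 0.583
```

Reading this: of the 190 candidate pairs over the 20 planted-pair genes,
183 survive the constant-indicator filter and 85 are significant in both
discovery cohorts, forming the signature. On the held-out cohort the integer
score, dichotomised at the maximally selected cutpoint, separates survival
with a hazard ratio of 1.8; the C-index and the time-dependent AUCs quantify
discrimination of the continuous score, and the selection-corrected log-rank
p accounts for the cutpoint optimisation. Restricting candidates to the 20
pair-partner genes dilutes the score with many redundant within-pathway
pairs — feeding the full candidate funnel (as `rcdgp run-all` or
`scripts/acceptance.py` do) yields substantially stronger held-out
separation (HR ≈ 4, C-index ≈ 0.68).

The same pipeline runs end to end from the shell:

```bash
rcdgp run-all --synthetic --seed 0 --out rcdgp_run
```

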