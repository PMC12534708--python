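# methylcode

Analysis toolkit for ternary-code DNA methylation: matched total-modification
(5modC) and 5-hydroxymethylcytosine (5hmC) beta-value arrays decomposed into
5mC / 5hmC / unmodified C, with the downstream analyses such data support —
tissue-marker discovery, reference-based cell-type deconvolution,
cross-platform probe imputation, probe-set enrichment, per-CpG EWAS, and
elastic-net epigenetic clocks. A synthetic-data generator with complete
ground truth stands in for array data, so every stage ships with recovery
and calibration checks.

## The problem

Standard bisulfite conversion cannot distinguish 5-methylcytosine (5mC) from
5-hydroxymethylcytosine (5hmC): an array beta value measures their sum,
"5modC". Pairing each sample with an APOBEC-based experiment that reads 5hmC
directly turns the per-CpG measurement into a ternary code,

    5mC = max(0, β_5modC − β_5hmC),    C = 1 − β_5modC,
    5mC + 5hmC + C = 1,

and unlocks 5hmC-aware versions of the classical methylation analyses. The
toolkit implements each of those stages as library functions over validated
beta matrices (probes × samples, values in [0,1], NA allowed):

- **Markers** — per-CpG one-vs-rest Wilcoxon rank-sum tests with AUC =
  U/(n₁n₂) and Δβ (difference of group means); defaults AUC ≥ 0.8,
  |Δβ| ≥ 0.2, with NA caps (>10% target / >50% out-group drops a CpG) and a
  deterministic, hyper/hypo-balanced cap for design-mode selection.
- **Deconvolution** — robust partial correlations: Huber IRLS regression
  (c = 1.345, no intercept) of bulk betas on a marker reference panel,
  negative coefficients truncated, renormalized to proportions; NNLS as an
  independent cross-check solver.
- **Imputation** — nearest retained probe by Euclidean distance across a
  reference methylome collection, gated at cross-sample Pearson r > 0.5;
  substitution of missing legacy probes for applying legacy models to a
  condensed platform.
- **Enrichment** — one-sided hypergeometric tests with BH correction,
  interval colocalization with ±5 kb expansion, an unweighted KS-type ranked
  set-enrichment statistic with a permutation null, mean-rank tissue context
  (Kruskal–Wallis + Dunn), and CpG–gene linking/correlation.
- **EWAS & clocks** — per-CpG OLS of β ~ Age + Sex + Tissue; leave-one-out
  elastic-net age clocks (α = 0.5, 10 inner folds) with feature selection
  strictly inside each fold; a hyper-minus-hypo sex score.

## Worked example

```python
from methylcode.simulate import SimulationConfig, simulate_cohort
from methylcode.ternary import decompose
from methylcode.markers import MarkerThresholds, one_vs_rest_all_contrasts

cfg = SimulationConfig(n_probes=4000, n_celltypes=5, n_samples=40, seed=2026)
modc, hmc, sheet, truth = simulate_cohort(cfg)

tp = decompose(modc, hmc)                      # ternary code, closure to 1e-16
markers = one_vs_rest_all_contrasts(
    modc, sheet.groups("tissue"), MarkerThresholds(min_auc=0.8, min_delta=0.2)
)
```

Running the numbered drivers under `analysis/` on this cohort prints, among
others:

```
closure: max |5mC+5hmC+C - 1| = 1.11e-16 over 156812 cells
markers: 93 selected across 5 contrasts
precision 1.000, recall 0.930 against 100 planted markers
RPC RMSE vs truth: 0.0230 over 50 bulks; max |RPC - NNLS| = 0.0214
neighbor map: 1500 queries, 100.0% matched to generator site
clock: LOOCV Pearson r = 0.928, MAE = 4.34 years over 40 samples
sex prediction accuracy: 100.0% over 40 samples
```

i.e. the decomposition closes exactly, marker discovery recovers the planted
tissue signatures almost perfectly at the default thresholds, deconvolution
reproduces mixing proportions to ~0.02 per component, the cross-platform
neighbor map points every query back to its generating site, and the
held-out clock predictions track true age to within a few years.

The scripts are ordered (`01_simulate_cohort.py` … `08_sex_prediction.py`);
each runs standalone from the repository's `analysis/` directory and writes
its tables under `results/`.

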