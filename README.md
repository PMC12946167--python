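# immunotransit

Longitudinal immune monitoring of peripheral blood (PBMC) single-cell data
for a three-group neuro-oncology immunotherapy design: a control surgery arm
and two thermal-ablation (LITT) + anti-PD-1 groups split by median overall
survival. The package implements, as a tested reusable pipeline:

- **Pseudo-bulk differential expression** — per patient/visit summed UMI
  counts, TMM normalization, a negative-binomial GLM (log link, common
  dispersion via Cox–Reid adjusted profile likelihood) with a
  `~ patient + timepoint` design and likelihood-ratio tests; the FDR top-k
  genes form the expression signature.
- **Group z-scores and preranked GSEA** — per gene,
  `z = (x̄_L − x̄_S) / sqrt(SD_L²/n_L + SD_S²/n_S)` contrasts mean per-patient
  log2 fold-changes between long and short survivors; genes ranked by
  descending z feed a weighted Kolmogorov–Smirnov enrichment score with a
  gene-label permutation null (nominal p, NES, FWER).
- **Pathway activity ratios** — relative-counts (1e6) normalized mean
  pathway expression per patient/visit, `Signal_Change = MeanExpr_B /
  MeanExpr_A`, compared between arms by Wilcoxon rank-sum.
- **TCR clonal diversity** — clonotypes collapsed by CDR3 amino-acid
  identity; Simpson index `D = 1 − Σ pᵢ²` per patient/visit, diversity
  ratios across visits, cohort t-tests, clone-fate tables from a source CD8
  subtype, and a chi-square test of target-distribution independence.
- **Optimal-transport cell-state transitions** — Euclidean cost
  `C_ij = ‖x_i − y_j‖₂` in PC space between consecutive visits, the exact
  Earth-Mover coupling `min_{π≥0} Σ π_ij C_ij` s.t. `Σ_j π_ij = a_i,
  Σ_i π_ij = b_j` with uniform marginals, cell mapping, cluster arrows in a
  2-D display embedding, and row-normalized target fractions.
- **Signature–survival association** — per-patient mean z-scored signature
  fold-change, median split into high/low, age-adjusted Cox proportional
  hazards with a Schoenfeld residuals check, and Kaplan–Meier/log-rank
  summaries.
- **Synthetic cohort generator** — gamma-Poisson counts with marker
  structure, an activated monocyte subcluster appearing post-procedure in
  LITT patients and carrying the programmed DE signal, clone-linked CD8
  subtype transition chains per group, Dirichlet-multinomial TCRβ
  repertoires with programmed expansion, and exponential survival tied to a
  latent signature activity. All programmed effects are recoverable by the
  downstream stages, which is what the test suite asserts.

Real patient-level data for this design are controlled-access and are not
required anywhere: every analysis runs against the generator or against
user-provided bundles (MatrixMarket counts + TSV annotations + CSV
clonotypes + GMT pathways).

## Worked example

```python
from immunotransit import (
    SimConfig, simulate_cohort, ground_truth, split_by_mos,
    aggregate_pseudobulk, fit_nb_lrt, top_k_by_fdr, transition_pipeline,
)

cfg = SimConfig(seed=1, n_genes=1000, n_cells_per_patient_timepoint=300)
ds = simulate_cohort(cfg)

groups = split_by_mos(ds.survival)                  # median-OS split of the LITT arm
litt = sorted(groups.index[groups != "NLS_PEM"])
pb = aggregate_pseudobulk(ds, "non_classical_monocyte", ("PRE", "C1"), patients=litt)
res = fit_nb_lrt(pb)                                # NB GLM, LRT per gene
print(res.summary(top=3))
```

```
Pseudo-bulk NB GLM likelihood-ratio test
  design: ~ patient + timepoint   samples: 24   genes: 1000   common dispersion: 0.004971
  genes at FDR<0.05: 51

       log2fc  lr_stat  p_value      fdr  converged
gene
G0978    1.08      468 9.4e-104 9.4e-101       True
G0989    1.02      413 6.94e-92 3.47e-89       True
G0957    1.08      409 5.26e-91 1.75e-88       True
```

The 51 genes at FDR < 0.05 are the monocyte activation signature; all 50
genes programmed into the generator rank inside the FDR top 100:

```python
truth = ground_truth(cfg)
top = top_k_by_fdr(res, k=100)
len(set(top) & set(truth.de_genes))                 # -> 50  (of 50 programmed)
```

The reported `log2fc ≈ 1.1` is the programmed subcluster effect (1.5)
diluted by the resting monocytes in the pseudo-bulk, as expected.

Tracking CD8⁺ T cells with optimal transport recovers the programmed
central-memory → effector flow of 0.6 in the long-surviving group
(row `CD8_CM` of the target-fraction matrix, 500 cells per side):

```python
summ = transition_pipeline(ds, "CD8_T", [("PRE", "C1")],
                           cohorts=["LITT_GT_MOS"], n_pc=50, seed=0,
                           max_cells_per_side=500)["LITT_GT_MOS"][("PRE", "C1")]
print(summ.target_fractions.loc["CD8_CM"].round(3))
```

```
CD8_CM      0.393
CD8_CYC     0.004
CD8_EFF     0.545
CD8_EM      0.023
CD8_EXH     0.027
CD8_MPEC    0.000
CD8_SLEX    0.008
```

TCRβ diversity drops between cycles 1 and 2 only where clonal expansion was
programmed (mean Simpson diversity ratio 0.96 in the long-surviving group
versus 1.00 elsewhere; two-sample t-tests p ≈ 1e-4 against either other
group).

## Command line

```bash
immunotransit run --config cfg.yaml --seed 1 --out results/
immunotransit simulate --out results/ --seed 3        # cohort bundle + truth.json
immunotransit de --out results/ --seed 1              # DE + signature + GSEA
```

`run` executes simulate → preprocess → DE/signature → survival → TCR →
transport, writes TSV/JSON outputs plus a `manifest.json` with the
parameter hash and per-stage seeds, skips completed stages on re-runs
(unless `--force`), and is byte-reproducible for a fixed seed.

## Acceptance script

`python scripts/acceptance.py --seed 1 --out results/acceptance.json` runs
the full pipeline end to end on a freshly simulated cohort (all six stages
must complete) and writes the results JSON to `--out`.
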