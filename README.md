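# tmtquant

Quantification and downstream inference for multi-plex **tandem mass tag
(TMT)** proteomics, from PSM-level reporter-ion tables to differential
expression, enrichment and cross-species protein signatures.

The package targets the common clinical-cohort design in which tissue
samples are distributed over several TMT 10-plexes, each carrying nine
samples plus one pooled "master mix" reference channel, and implements the
full analysis path:

1. **PSM quality filtering** — reference channel quantified, peptide
   probability ≥ 0.9, precursor purity ≥ 50%, minimum MS1 intensity
   (0.05% of the plex maximum), summed MS2 reporter intensity ≥ 5% of the
   plex median, contaminant exclusion; redundant PSMs resolved by highest
   summed TMT intensity.
2. **Ratio conversion and roll-up** — log2(reporter) − log2(reference) per
   channel, 1.5·IQR outlier removal within each protein × sample group,
   median roll-up to a proteins × samples ratio matrix, integration across
   plexes.
3. **MAD normalization** — per sample *j* over proteins *i*:
   M_j = median(R_ij), Rᶜ_ij = R_ij − M_j, MAD_j = median(|Rᶜ_ij|),
   MAD₀ = median(MAD_j), Rᴺ_ij = (Rᶜ_ij / MAD_j) · MAD₀; back-conversion to
   log2 abundance A_ij = Rᴺ_ij + log2(REF_i) with REF_i the mean over
   plexes of the top-3 summed MS1 precursor intensity.
4. **Multiple imputation** — chained equations with predictive mean
   matching (m = 5, maxit = 50, 5 donors), Rubin's-rules pooling
   (T = W + (1 + 1/m)·B, Barnard–Rubin df), per-protein batch-mean
   correction across plexes.
5. **Inference** — group-mean log2 fold changes with Student's t-tests and
   Benjamini–Hochberg control; one-way ANOVA; hierarchical clustering with
   median centering, uncentered correlation and complete linkage; PCA;
   preranked GSEA (running-sum ES, gene-permutation null, NES, n = 1000
   permutations); significant-protein signatures (p < 0.05, q < 0.1,
   |log2FC| > 1) intersected across species through a homolog map.

A first-class synthetic-data module generates multi-plex PSM-level cohorts
with known ground truth (group effects, batch shifts, intensity-dependent
missingness, contaminants and low-quality PSMs), so every stage is testable
end to end without any external download.

## Worked example

The package ships a small synthetic fixture (3 plexes × 10 channels,
40 proteins, 27 tissue samples). Run the whole pipeline on it:

```bash
tmtquant run-all --config src/tmtquant/fixtures/config.yaml --out demo
# completed 7 stages -> demo
```

`demo/` then contains the quantified abundance matrix, five imputed and
batch-corrected matrices, per-contrast differential-expression and GSEA
tables, the cross-species signature, a dendrogram, PCA scores and a
`manifest.json` recording every stage with its inputs, outputs and
parameters. For example, the tumor-versus-normal GSEA table starts

```
set        size  es      nes     p        p_adj    leading_edge
TRUE_DOWN  7     -1.000  -1.743  0.0017   0.0223   GENE0019;GENE0013;...
```

— the set collecting the truly downregulated genes of the simulation is
the top depleted set (negative NES, adjusted p ≈ 0.02), while the random
sets stay non-significant; and `demo/signature_venn.json` reports that all
planted cross-species overlap genes are recovered as `shared`. Rerunning
with the same config reproduces every output byte for byte.

The same stages are available individually (`tmtquant simulate | quantify |
impute | batch-correct | de | cluster | gsea | signature |
validate-config`), and as library functions:

```python
import tmtquant as tq

bundle = tq.generate_cohort(tq.CohortConfig(n_proteins=200, seed=1))
quant = tq.quantify_cohort(bundle.psm_tables, bundle.designs)
completed = tq.pmm_impute(quant.abundance, tq.ImputeConfig(seed=1))
```

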