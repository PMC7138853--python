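# Demo pipeline configuration over the packaged synthetic cohort.
seed: 20200407
psm_tables: [psm_plex1.tsv, psm_plex2.tsv, psm_plex3.tsv]
design: design.tsv
annotation: annotation.tsv
gene_sets: genesets.gmt
homologs: homologs.tsv
mouse_de: mouse_de.tsv
rollup_by: gene
filter:
  min_peptide_probability: 0.9
  min_precursor_purity: 0.5
  min_ms1_intensity_percentile: 0.0005
  min_ms2_fraction: 0.05
impute: {m: 5, maxit: 50, donors: 5}
de_thresholds: {min_abs_log2fc: 1.0, max_p: 0.05, max_q: 0.1}
signature_thresholds: {max_p: 0.05, max_q: 0.1, min_log2fc: 1.0}
contrasts:
  - "tnbc+spindle+squamous+sarcomatoid:normal"
  - "spindle:tnbc"
signature_contrast: "tnbc+spindle+squamous+sarcomatoid:normal"
gsea: {n_perm: 1000, min_size: 5, max_size: 500, weight_exponent: 1}
cluster: {axis: samples, median_center: true}
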