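# Default configuration of the spdefmeth synthetic-data generator.
# Every key is overridable; unknown keys are rejected.  All percent-scale
# values live on [0, 100], fractions on [0, 1], Ct values in PCR cycles.
#
# The defaults below are CALIBRATED: running the default pipeline at
# n = 180 + 180 reproduces the reference assay's headline statistics
# (group hypomethylation means 92% / 15.5%, sensitivity and specificity
# 177/180 at the <55% methylation cutoff, AUC ~0.999, gel D/C means
# ~0.21 / ~0.83, method concordance R-squared ~0.91).

# Cohort sizes: prostate-cancer cases and benign-hyperplasia controls.
n_pca: 180
n_bph: 180

# "group": two-component mixture of true methylation per group.
# "stratified": PCa subjects are assigned to tumor-stage and ISUP-grade
# strata with fixed counts (tables below).
mode: group

# Core true-methylation component per group: [truncated mean %, sd %].
# The PCa core is truncated to [0, 50] %, the BPH core to [60, 100] %,
# i.e. each core sits entirely on the correct side of the 55% cutoff.
pca_meth: [7.094, 11.76]
bph_meth: [85.692, 15.12]

# Contamination: a narrow component just across the cutoff on the wrong
# side of each group.  3/180 per group reproduces 177/180 sensitivity
# and specificity while keeping the AUC near 1.
contamination_fraction: 0.016666666666666666
contamination_center: [60.0, 48.0]   # [PCa %, BPH %]
contamination_sd: 5.0

# Stratified mode: per-stratum subject counts and mean hypomethylation %.
stage_table:
  - {label: I,   count: 7,  hypomethylation_mean: 10.0}
  - {label: II,  count: 15, hypomethylation_mean: 35.0}
  - {label: III, count: 33, hypomethylation_mean: 64.5}
  - {label: IV,  count: 70, hypomethylation_mean: 96.0}
  - {label: V,   count: 55, hypomethylation_mean: 100.0}
grade_table:
  - {label: '1', count: 15, hypomethylation_mean: 5.66}
  - {label: '2', count: 20, hypomethylation_mean: 30.0}
  - {label: '3', count: 46, hypomethylation_mean: 55.2}
  - {label: '4', count: 20, hypomethylation_mean: 74.0}
  - {label: '5', count: 79, hypomethylation_mean: 100.0}
# Residual biological spread within a stratum (%), and the weight of the
# stage stratum mean versus the grade stratum mean in a subject's
# expected hypomethylation.  Both calibrated against the published
# per-sample regression coefficients (r = 0.9574 stage, 0.9348 grade).
within_stratum_sd: 2.0
stage_grade_weight: 0.65

# Clinical covariates.  PSA is lognormal parameterized by the printed
# [median ng/mL, sd ng/mL]; age and prostate weight are truncated
# normals ([mean, sd]) on [40, 100] years and [1, 200] g.
psa_params:    {pca: [12.0, 21.33],  bph: [4.4, 5.4]}
age_params:    {pca: [69.5, 17.67],  bph: [68.65, 15.6]}
weight_params: {pca: [36.83, 38.36], bph: [56.26, 27.74]}

# PSA-methylation coupling: Gaussian copula on within-group ranks.
# psa_meth_rank_corr is the POOLED Spearman target used by calibration;
# psa_copula_rho is the within-group copula correlation applied
# (calibrated so the pooled Spearman lands on the target).
psa_meth_rank_corr: -0.364
psa_copula_rho: 0.2

# qPCR forward model: undigested Ct ~ baseline + noise; digested Ct ~
# baseline - ln(m)/0.7 + noise, capped at ct_cap (m = 0 never amplifies).
ct_noise_sd: 0.15
ct_baseline: 25.0
ct_cap: 40.0

# Gel densitometry: expected D/C ratio = gel_beta + gel_alpha * m,
# clipped to [0, 1.2]; gel_noise_sd is calibrated to the published
# method-concordance R-squared of 0.91.
gel_alpha: 0.82
gel_beta: 0.14
gel_noise_sd: 0.105

# Mandatory in pipeline runs; all stages draw from fixed substreams of
# this seed, so runs are byte-identical under the same config.
seed: 17
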