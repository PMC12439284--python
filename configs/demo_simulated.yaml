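# Full pipeline on a synthetic lagoon population.
# The analysis constants (75% amplification success, duplicate threshold
# r > 0.95, family threshold rbar_N >= 0.25, balanced bootstrap R = 1000)
# are the pipeline defaults restated here explicitly.
out_dir: pipeline_out
min_success: 0.75
duplicate_threshold: 0.95
family_threshold: 0.25
class_edges: [0.0, 0.0625, 0.125, 0.25, 0.5, 0.6, 0.75, 1.0]
bootstrap_R: 1000
hwe_n_mc: 10000
seed: 1
simulate:
  seed: 42
  n_loci: 21
  alleles_per_locus: [4, 21]
  freq_concentration: 0.265
  family_spec:
    - [FS, 5, 20]
    - [HS, 4, 10]
  n_unrelated: 120
  null_rate_per_locus: 0.05
  missing_rate: 0.05
  n_duplicates: 5
  kin_sigma_km: 1.0
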