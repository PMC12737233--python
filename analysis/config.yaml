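# Shared configuration for the numbered analysis scripts.
# A 146-subject synthetic cohort with well-separated phenotype archetypes,
# reduced per-family hyperparameter grids, and a fixed master seed.
output_dir: results/pipeline
n_subjects: 146
separation: 2.5
master_seed: 7
grid_size: small
fusion_weight: 1.0
mds_dim: 5
consensus_n_features: 25
screening_fixed_cutoff: 13.5
missing_rate: 0.0
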