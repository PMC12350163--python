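bin_size: 1000
duplication_blocks:
- - 1500
  - 2
enrichment_fold: 6.0
fragment_length: 300
gain_fold: 2.0
heterochromatin_fraction: 0.35
knockdown_fold: 8.0
mappability_read_length: 15
mark_background_mean: 20.0
mito_length: 6000
n_replicates: 2
n_sequences: 2
nb_dispersion: 0.1
p_both: 0.05
p_bound_given_both: 0.9
p_bound_given_k27: 0.05
p_bound_given_k9: 0.5
p_bound_given_none: 0.02
p_dual_given_both: 0.6
p_dual_given_k9: 0.06
p_k27_only: 0.12
p_k9_only: 0.13
p_uni_given_none: 0.015
pirna_background_mean: 15.0
pirna_mean: 80.0
pirna_read_length: 26
scaffold_length: 6000
seed: 7
sequence_length: 150000
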