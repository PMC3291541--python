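# demo configuration: all-synthetic end-to-end run
seed = 1
n_self_proteins = 80
n_species = 4
shared_kmer_rate = 0.05
allele = SYN-A01
anchor_strength = 2.0
mean_similar_partners = 1.6
threshold_mode = scaled
target_specificity = 0.1
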