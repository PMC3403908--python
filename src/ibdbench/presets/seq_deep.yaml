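# Deep whole-genome sequencing analog (artifact choice, not a published
# value): densest sites, lowest MAF floor.
n_samples: 54
sites_per_cm: 250
maf_min: 0.01
chrom_length_cm: 50.0
n_founders: 100
switch_rate_per_cm: 1.0
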