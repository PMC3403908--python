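# Low-coverage sequencing analog (artifact choice, not a published value):
# denser sites, rare variants included.
n_samples: 60
sites_per_cm: 120
maf_min: 0.02
chrom_length_cm: 50.0
n_founders: 100
switch_rate_per_cm: 1.0
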