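# Dense genotyping-array analog (artifact choice, not a published value).
n_samples: 60
sites_per_cm: 40
maf_min: 0.05
chrom_length_cm: 50.0
n_founders: 100
switch_rate_per_cm: 1.0
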