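# Sparse genotyping-array analog (artifact choice, not a published value):
# few sites per cM, strong common-variant ascertainment.
n_samples: 60
sites_per_cm: 15
maf_min: 0.10
chrom_length_cm: 50.0
n_founders: 100
switch_rate_per_cm: 1.0
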