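mirna_id	coefficient
hsa-miR-107	-284.08
hsa-miR-130b-3p	250.03
hsa-miR-142-5p	249.36
hsa-miR-146a-5p	-116.58
hsa-miR-148a-3p	624.41
hsa-miR-155-5p	-181.37
hsa-miR-17-5p	1947.24
hsa-miR-216a-5p	-59.90
hsa-miR-221-5p	-364.84
hsa-miR-223-3p	93.85
hsa-miR-30e-3p	54.25
hsa-miR-31-3p	-192.14
hsa-miR-31-5p	-103.83
hsa-miR-4485	-382.17
hsa-miR-486-3p	-3.99
hsa-miR-582-3p	595.41
hsa-miR-758-3p	269.49
hsa-miR-802	-1044.62
hsa-miR-876-3p	167.76
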