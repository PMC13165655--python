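# Frozen reference configuration: four residual stages (one block each,
# two convolutions per block, identity shortcuts; 1x1 projection where the
# channel count changes), max-pool (4) downsampling, flatten head.
name: residual_cnn
kernel: 5
stem_filters: 42
stage_filters: [42, 104, 132, 172]
pool: 4
head: flatten
declared_param_count: 554498
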