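# Frozen reference configuration: plain stacked-conv regressor.
# Four same-padding convolutions with progressively increasing filter
# counts, ReLU + max-pool (4) after each, flatten, two dense layers.
name: baseline_cnn
kernel: 5
filters: [8, 24, 34, 68]
pool: 4
dense_width: 62
declared_param_count: 33826
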