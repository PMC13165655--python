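# Frozen reference configuration: strided stem (stride 4) followed by five
# residual blocks of dilated causal convolutions with exponentially
# increasing dilation (1, 2, 4, 8, 16), GAP head.
name: micro_tcn
stem_kernel: 3
stem_filters: 26
stem_stride: 4
kernel: 7
channels: 24
n_blocks: 5
declared_param_count: 41698
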