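# Frozen reference configuration: depthwise-separable stages (depthwise
# temporal convolution, stride 2, then 1x1 pointwise channel mixing),
# strided stem, GAP head.
name: mobilenet_1d
kernel: 3
stem_filters: 8
stem_stride: 2
stage_filters: [16, 34, 66, 104]
stage_stride: 2
declared_param_count: 10738
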