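# Frozen reference configuration: slim residual variant; same stage layout
# as residual_cnn with reduced filter counts and a GAP regression head.
name: residual_cnn_slim
kernel: 5
stem_filters: 28
stage_filters: [28, 46, 62, 92]
pool: 4
head: gap
declared_param_count: 140034
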