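# Half U-net: stages 0-4, one pooling level fewer than U-net retained; the
# bottleneck is the full model's deepest stage with reduced channels.
# Calibrated to 1.7724 M parameters / 204.0 B FLOPs at 512x512.
name: half_unet
input_shape: [512, 512, 3]
encoder: [63, 126, 255]             # stages 0-2 (last entry = bottleneck)
decoder: [119, 52]                  # stages 3-4
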