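# Quarter MultiResUNet: a single encoder/decoder MultiRes block pair around
# a reduced bottleneck. Calibrated to 0.0445 M parameters / 21.9 B FLOPs
# at 512x512.
name: quarter_multiresunet
input_shape: [512, 512, 3]
stem: 33
blocks: [30, 30]                    # stage 0 and the reduced bottleneck
respath: [26]
decoder: [36]                       # stage 2
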