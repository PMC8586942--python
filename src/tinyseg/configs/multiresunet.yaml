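# MultiResUNet: MultiRes blocks on every stage, residual-path skip
# connections. Calibrated to 13.5469 M parameters / 204.8 B FLOPs at 512x512.
name: multiresunet
input_shape: [512, 512, 3]
stem: 36                            # initial 3x3 conv width
blocks: [30, 60, 120, 240, 1164]    # encoder MRB widths, stages 0-4
respath: [30, 60, 120, 240]         # residual-path widths, levels 0-3
decoder: [924, 492, 60, 30]         # decoder MRB widths, stages 5-8
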