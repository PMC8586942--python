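# Half MultiResUNet: keeps the 0th/1st encoder MultiRes blocks and their
# decoder counterparts; bottleneck is the full model's 4th block with far
# fewer channels. Calibrated to 0.2149 M parameters / 42.9 B FLOPs at 512x512.
name: half_multiresunet
input_shape: [512, 512, 3]
stem: 34
blocks: [30, 60, 120]               # stages 0-2 (120 = reduced bottleneck)
respath: [30, 42]
decoder: [54, 30]                   # stages 3-4
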