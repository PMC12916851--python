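# Demo run: synthetic two-site design with the package defaults
# (10 samples/group, 15 core genera, 100/61 accessory genera, 4 negative
# controls, 20,000 reads/sample, planted positive interaction blocks).
seed: 1
out_dir: mosqnet_out
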