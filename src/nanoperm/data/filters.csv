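label,wettability,mesh_size_um,thread_diameter_um,thickness_um
F118,HI,118,55.46,55.5
F63,HI,63,57.53,57.5
F1,HI,1,49.30,49.3
F9*,HF,9,47.93,47.9
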