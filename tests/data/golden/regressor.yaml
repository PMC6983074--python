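family: dnn
screen_size: [1920.0, 1080.0]
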