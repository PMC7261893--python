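lg	cm
1	60.66
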