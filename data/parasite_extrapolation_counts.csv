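type,count
univariate,73980
combinatorial,6696
analogue,19612
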