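stat,pre,fu,change
mean,17.0,11.8,4.6
sd,2.5,4.1,3.5
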