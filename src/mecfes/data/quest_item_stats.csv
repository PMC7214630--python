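item,mean,sd
adjustments,1.7,0.7
dimensions,2.7,0.9
comfort,3,1.2
durability,3.1,1.1
weight,3.3,1.2
effectiveness,3.3,1
safety,3.4,1.1
ease_of_use,4.3,1.1
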