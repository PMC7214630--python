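activity,percentage
Writing,63
Dressing,63
Manipulating glasses/bottles,52
Cooking,48
Cutting while eating or cooking,48
Heavy object manipulation,44
Personal Care,41
Using a key,37
Using a fork,26
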