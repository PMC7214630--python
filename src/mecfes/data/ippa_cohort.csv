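id,pre,fu,change,q9,level
N1,18,15,3,Yes,C6B
N2,10.2,6.7,3.5,Yes,C5A
N3,18,14.8,3.2,Yes,C7B
N4,15.4,10.6,4.8,No,C5A
N5,14.4,7.4,7,No,C5A
N6,13.2,7,6.2,Yes,C6A
N7,22.5,15.5,7,No,C6B
N8,23.7,18,5.7,Yes,C7A
N9,13,12,1,Yes,C6B
N10,20,13.6,6.4,Yes,C5A
N11,15.7,10.4,5.3,Yes,C6C
N12,20.8,14.2,6.8,Yes,C5B
N13,18,12.7,5.3,Yes,C6A
N14,18.2,7.2,11,No,C5A
N15,17.4,11.8,5.6,No,C5A
N16,21.4,18.4,3,No,C7B
N17,18.5,14.8,3.7,Yes,C6A
S18,18.4,8.1,10.3,Yes,C6A
S19,11.6,9,2.6,No,C7A
S20,15.3,10.4,4.9,Yes,C6A
S21,12.3,10.1,2.1,No,C6A
S22,14.3,10,4,No,C7A
S23,15,14.7,0.3,No,C7A
S24,13.6,11.3,2.3,No,C6A
S25,10.4,9.1,1.3,Yes,C6A
S26,12.4,11.4,1,No,C6A
S27,11.3,9.1,2.1,No,C7A
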