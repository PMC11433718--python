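name,units,low,high
A,mg/mL,2,3
B,mg/mL,1,3
C,ratio,1,3
D,mg,3,5
E,%,0.1,0.3
F,h,1,2
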