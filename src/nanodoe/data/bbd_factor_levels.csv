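name,units,low,center,high
X1,mg/mL,1.5,2.0,2.5
X2,mg/mL,1,2,3
X3,ratio,1,2,3
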