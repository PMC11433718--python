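medium,model,p1,p2,r2
pH5.0 PBS,zero-order,12.9,1.7,0.7559
pH5.0 PBS,first-order,76.5,0.09,0.9874
pH5.0 PBS,higuchi,12.5,1,0.9133
pH5.0 PBS,ritger-peppas,13.2,0.48,0.9139
pH7.4 PBS,zero-order,16.0,1.8,0.7343
pH7.4 PBS,first-order,83.5,0.10,0.9888
pH7.4 PBS,higuchi,14.1,1,0.9076
pH7.4 PBS,ritger-peppas,16.0,0.46,0.9122
artificial intestinal fluid,zero-order,18.2,1.6,0.6337
artificial intestinal fluid,first-order,72.2,0.15,0.9942
artificial intestinal fluid,higuchi,13.2,1,0.8550
artificial intestinal fluid,ritger-peppas,18.1,0.40,0.8753
artificial gastric fluid,zero-order,19.9,1.7,0.6614
artificial gastric fluid,first-order,77.6,0.15,0.9952
artificial gastric fluid,higuchi,14.1,1,0.8641
artificial gastric fluid,ritger-peppas,19.6,0.39,0.9003
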