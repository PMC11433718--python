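run,X1,X2,X3,particle_size_nm,potential_mV,ee_percent,dl_percent,od
1,0,1,-1,144.1,30.2,68.01,14.46,0.6926
2,0,0,0,169.4,34.1,71.74,12.99,0.7476
3,0,1,1,193.8,34.3,60.13,9.85,0.4817
4,0,-1,-1,184.1,30.2,72.41,14.93,0.7043
5,0,0,0,157.6,34.8,75.69,14.44,0.8502
6,-1,1,0,212.3,34.5,55.76,12.52,0.5992
7,0,-1,1,183.1,32.6,53.68,9.00,0.3168
8,0,0,0,205.8,31.1,69.85,14.56,0.6929
9,0,0,0,235.0,34.7,61.47,10.22,0.5031
10,1,0,1,298.6,30.5,37.93,8.61,0
11,1,0,-1,188.3,31.3,66.69,11.78,0.5921
12,-1,-1,0,204.0,34.4,63.33,11.21,0.5947
13,0,0,0,122.5,37.2,83.23,15.23,1.0000
14,1,1,0,191.9,30.1,63.24,10.21,0.4563
15,-1,0,-1,183.6,29.4,65.74,10.50,0.4729
16,1,-1,0,435.2,25.1,77.65,14.56,0
17,-1,0,1,210.3,29.3,60.99,11.17,0.4710
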