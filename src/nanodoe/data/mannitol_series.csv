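mannitol_percent,size_nm,size_sd,potential_mV,potential_sd,pdi,pdi_sd,ee_percent,ee_sd,dl_percent,dl_sd
1,161.0,3.2,22.3,1.0,0.275,0.003,72.38,1.58,10.05,0.52
2,144.4,4.1,29.3,0.5,0.281,0.005,76.92,1.99,12.62,0.21
5,129.9,1.4,33.1,0.2,0.274,0.006,80.18,1.34,15.03,0.49
10,192.3,4.9,26.6,1.9,0.495,0.014,67.62,1.52,8.93,0.15
20,285.4,9.3,43.2,3.7,0.556,0.017,73.57,2.47,6.68,0.35
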