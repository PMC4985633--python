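# Published Guinier parameters for the two protein labelings in four
# ectoine solvent conditions (absolute-scale SANS).
# solvent_sld in 1e10 cm-2 (published values, "table-1" solvent mode);
# i0_over_n in 1e-16 cm2; rg in A.
label,protein,molarity,d2o_fraction,solvent_sld_1e10,i0_over_n_1e16,i0_over_n_err_1e16,rg_A,rg_err_A
H-MBP 2M ect H2O,H,2,0.0,-0.074,0.142,0.004,22.8,0.7
H-MBP 3M ect H2O,H,3,0.0,0.205,0.086,0.003,24.1,1.4
H-MBP 2M ect D2O,H,2,1.0,5.70,0.154,0.002,22.2,0.25
H-MBP 3M ect D2O,H,3,1.0,5.36,0.136,0.002,23.6,0.6
D-MBP 2M ect H2O,D,2,0.0,-0.074,1.075,0.015,25.6,0.3
D-MBP 3M ect H2O,D,3,0.0,0.205,1.025,0.02,25.8,0.4
D-MBP 2M ect D2O,D,2,1.0,5.70,0.043,0.003,30.7,1.7
D-MBP 3M ect D2O,D,3,1.0,5.36,0.086,0.003,28.5,0.7
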