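# Published water H-bond distances (A): bulk heavy water vs the 1.5 M
# ectoine solution.  od_intra and dd are intramolecular; oo and od_inter
# are between adjacent water molecules.
sample,od_intra_A,dd_A,oo_A,od_inter_A
bulk,0.97,1.53,2.82,1.88
ectoine,0.98,1.51,2.80,1.93
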