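# SYNTHETIC stand-in: idealized ectoine (C6H10N2O2) intramolecular pair
# list for solute self-correlation subtraction.  Distances are textbook
# bond lengths / geminal separations for the tetrahydropyrimidine ring
# and carboxylate, not refined values; weights are nominal and the
# Gaussian widths gamma (A^2) are defaults (0.005 bonded / 0.01 geminal).
label,distance_A,weight,gamma_A2
C-H bonded,1.09,0.020,0.005
N-H bonded,1.01,0.008,0.005
C-N ring,1.47,0.012,0.005
C=N amidinium,1.33,0.006,0.005
C-C ring,1.53,0.010,0.005
C-O carboxylate,1.25,0.008,0.005
C..C geminal,2.51,0.010,0.010
C..N geminal,2.45,0.008,0.010
C..O geminal,2.36,0.006,0.010
H..H geminal,1.78,0.012,0.010
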