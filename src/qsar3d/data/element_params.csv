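# Per-element parameters used by the field kernels.
# vdw_radius / well_depth: Tripos 5.2 force-field values (Clark, Cramer &
#   Van Opdenbosch, J. Comput. Chem. 10 (1989) 982), Angstrom / kcal/mol.
# hydrophobicity: coarse per-element atomic contributions in the spirit of
#   Ghose & Crippen atom-additive logP (J. Comput. Chem. 7 (1986) 565),
#   collapsed to one value per element; dimensionless.
element,vdw_radius,well_depth,hydrophobicity
H,1.50,0.042,0.20
C,1.70,0.107,0.50
N,1.55,0.095,-0.50
O,1.52,0.116,-0.45
S,1.80,0.314,0.25
P,1.80,0.314,-0.30
F,1.47,0.109,0.30
Cl,1.75,0.314,0.50
Br,1.85,0.434,0.60
I,1.98,0.623,0.70
Si,2.10,0.310,0.30
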