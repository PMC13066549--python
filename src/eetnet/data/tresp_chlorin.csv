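# Transition-charge template for chlorin rings (Qy-like, dipole along the
# NB->ND nitrogen axis).  Charges sum to zero and the even in-plane
# multipoles vanish by symmetry; charges are rescaled at run time so the
# geometric dipole matches the configured per-class dipole strength.
# nominal_dipole_debye: 3.4295
atom_name,charge
ND,0.300
NB,-0.300
C1D,-0.055
C4D,-0.055
C1B,0.055
C4B,0.055
CHA,0.015
CHD,0.015
CHB,-0.015
CHC,-0.015
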