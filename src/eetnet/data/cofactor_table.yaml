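# Default chemical-component-code -> cofactor-class table.
# Codes follow the wwPDB chemical component dictionary; the table is
# config-driven so deposited entries using different codes can be
# reconciled by editing a copy of this file.
CLA: chl_a
CHL: chl_b
BCR: carotenoid:beta_carotene
DD6: carotenoid:diadinoxanthin
NEX: carotenoid:neoxanthin
PQN: quinone
SF4: fes_cluster
LHG: lipid
LMG: lipid
DGD: lipid
SQD: lipid
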