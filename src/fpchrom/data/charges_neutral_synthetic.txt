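# Synthetic partial-charge table for the chromophore conjugated fragment
# (imidazolinone ring + aryl-alkene bridge + phenol ring), NEUTRAL total.
# These are plausible-magnitude test charges, not a force-field set.
# format: atom_name charge_e
C1    0.91
N2   -0.60
CA2   0.40
C2    0.90
N3   -0.40
O2   -0.55
CB2  -0.20
CG2   0.00
CD1  -0.115
CD2  -0.115
CE1  -0.115
CE2  -0.115
CZ    0.11
OH   -0.54
HO    0.43
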