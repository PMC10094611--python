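# Synthetic partial-charge table for a DEPROTONATED (phenolate) chromophore
# fragment, net charge -1 e.  Exercises origin-dependence of the dipole
# moment for charged fragments; not a force-field set.
# format: atom_name charge_e
C1    1.10
N2   -0.65
CA2   0.30
C2    1.15
N3   -0.50
O2   -0.60
CB2  -0.30
CG2  -0.10
CD1  -0.20
CD2  -0.20
CE1  -0.20
CE2  -0.20
CZ    0.30
OH   -0.90
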