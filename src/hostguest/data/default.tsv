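# Default element-level lipophilic fragment constants (dimensionless),
# in the lineage of published atomic fragmental systems (Broto / Ghose-Crippen).
# Hydrogen contributions are folded into the heavy-atom values; positive =
# hydrophobic contribution, negative = polar contribution.
# fragment_type	constant
H	0.21
C	0.49
N	-0.87
O	-0.39
F	-0.38
P	-0.45
S	0.32
Cl	0.49
Br	0.68
I	0.88
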