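# van der Waals radii (Å), Bondi-style element values
# element	radius
H	1.20
B	1.92
C	1.70
N	1.55
O	1.52
F	1.47
Na	2.27
Mg	1.73
Si	2.10
P	1.80
S	1.80
Cl	1.75
K	2.75
Ca	2.31
Br	1.85
I	1.98
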