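sevoflurane (generated conformer, heavy atoms)
     RDKit          3D

 12 11  0  0  0  0  0  0  0  0999 V2000
    2.3322    0.0891    0.7942 F   0  0  0  0  0  0  0  0  0  0  0  0
    1.9991    0.5088   -0.4493 C   0  0  0  0  0  0  0  0  0  0  0  0
    0.8660   -0.2329   -0.8741 O   0  0  0  0  0  0  0  0  0  0  0  0
   -0.1498   -0.3822    0.1533 C   0  0  0  0  0  0  0  0  0  0  0  0
   -0.7984    0.9122    0.5947 C   0  0  0  0  0  0  0  0  0  0  0  0
   -1.7627    0.7169    1.5187 F   0  0  0  0  0  0  0  0  0  0  0  0
   -1.3430    1.5929   -0.4358 F   0  0  0  0  0  0  0  0  0  0  0  0
    0.1120    1.7385    1.1675 F   0  0  0  0  0  0  0  0  0  0  0  0
   -1.2738   -1.2562   -0.3564 C   0  0  0  0  0  0  0  0  0  0  0  0
   -1.9383   -0.7047   -1.3931 F   0  0  0  0  0  0  0  0  0  0  0  0
   -0.7925   -2.4517   -0.7810 F   0  0  0  0  0  0  0  0  0  0  0  0
   -2.1763   -1.5343    0.6106 F   0  0  0  0  0  0  0  0  0  0  0  0
  1  2  1  0
  2  3  1  0
  3  4  1  0
  4  5  1  0
  5  6  1  0
  5  7  1  0
  5  8  1  0
  4  9  1  0
  9 10  1  0
  9 11  1  0
  9 12  1  0
M  END
$$$$
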