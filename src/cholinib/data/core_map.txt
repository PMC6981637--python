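# Default shared-scaffold atom map for cross-ligand core RMSD.
# One atom name per line; every pose in an ensemble must contain all of them.
# The names cover the THQ ring, the pyrrolidone nitrogen anchor, the methylene
# bridge, and the isoxazole/isoxazoline core common to both series.
THQ1
THQ2
THQ3
THQ4
THQ5
THQ6
THQ7
THQ8
THQ9
THQ10
PYRN
BRC1
ISO1
ISO2
ISO3
ISO4
ISO5
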