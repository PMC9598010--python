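# Default fragmentation scheme: sequences of 2-4 atoms and bonds, colored by
# formal charges, lone pairs and radicals, with atom counts included.
# Lone pairs enter the graph as pseudo-atoms (the calibrated default).
min_len: 2
max_len: 4
use_formal_charge: true
use_lone_pairs: true
use_radicals: true
include_atom_counts: true
lone_pairs_as_pseudo_atoms: true
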