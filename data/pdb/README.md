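# Deposited structures (not redistributed)

The deposited-structure superposition test expects local copies of the
RARγ LBD entries here:

    data/pdb/3LBD.pdb   (wild type, holo LBD)
    data/pdb/5M24.pdb   (S371E phospho-mimetic, holo LBD)

Download them from the Protein Data Bank (https://www.rcsb.org) and drop
the files in this directory; the test then superposes their common Cα
and checks the RMSD. Without the files the test fails with a message
pointing here.
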