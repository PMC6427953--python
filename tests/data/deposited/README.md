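# Deposited reference data (not bundled)

The acceptance tests that check published heme-site distances and
distortion patterns run on local copies of the deposited crystal
structures and database sequences:

    6HIU.pdb  6HIH.pdb  2J3E.pdb  6AMG.pdb  4FAS.pdb
    AAD39218.fasta  AAU93287.fasta

This directory ships empty because the build and test environments have no
network access.  On a networked machine, populate it with:

    python scripts/fetch_deposited.py --out tests/data/deposited

Without these files the corresponding tests in
`tests/test_acceptance.py` fail with a message naming the missing input;
the synthetic stand-in tests in the same file cover the code paths.
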