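# Deposited-structure cache

Place (or fetch) the deposited antibody–pMHC coordinate files here as
`3cvh.cif`, `3gjf.cif`, `7tr4.cif` (mmCIF or PDB):

    python scripts/fetch_structures.py      # requires network access

The structural worked examples (analysis/01, analysis/02, the part-A checks
in tests/test_acceptance.py, and the structural block of
scripts/acceptance.py) read from this directory; everything else in the
package runs without it.
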