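# Reference structures

The four reference PDB entries analysed by
`examples/05_reference_structures.py` and the reference-structure
acceptance test live here as `2mxu.pdb`, `2fkg.pdb`, `1d2s.pdb`,
`3bep.pdb`. They are not redistributed with the package; download them
once with

    python scripts/fetch_validation_data.py

(requires network access to files.rcsb.org).
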