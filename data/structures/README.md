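# Deposited coordinate files (not bundled)

Place plain-text PDB files here to enable the structure-based regressions in
`tests/test_acceptance.py` (part B) and the t1–t9 targets of
`scripts/acceptance.py`:

- `6tne.pdb` — receiver-domain monomer crystal structure
- `4qpj.pdb` — HPt/receiver phosphotransfer complex (grafting template)
- `5idj.pdb` — kinase DHp-CA monomer
- `3q15.pdb` — Spo0F receiver domain

Each is available as `https://files.rcsb.org/download/<ID>.pdb`. Nothing in
this repository downloads files; this environment is offline by design.
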