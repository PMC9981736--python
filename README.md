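# relaykit

Structural and sequence analytics for two-component phosphorelay receiver
(Rec) domains: template-anchored modeling of a phosphotransfer-competent
DHp/Rec complex, protein interface and crystal-contact analysis, family-level
conservation and covariation analysis, and backbone chemical-shift analytics.
Every stage runs on seeded synthetic fixtures, so the whole pipeline is
testable without downloading anything.

## Modules

| module | what it does |
| --- | --- |
| `relay.structure_io` | PDB/mmCIF reading/writing, atom selection, crystallographic symmetry expansion, atom/B-factor summaries |
| `relay.superpose` | Kabsch superposition, sequence- and range-based residue pairing, iterative outlier-pruned RMSD |
| `relay.complex_model` | three-step anchor grafting of donor domains onto a template complex, His–Asp transfer geometry, inter-domain clash reports |
| `relay.interface` | residue contacts, Shrake–Rupley SASA, buried interface areas, crystal-contact scans, salt bridges |
| `relay.msa_profiles` | alignment ingestion (FASTA/Stockholm), conservation profiles and information content, differential conservation between two families, motif scanning (e.g. `FxSGY`) |
| `relay.covariation` | MI-APC column couplings (z-standardized), pair substitution tables, charge-reversal statistics, coupling-vs-distance agreement |
| `relay.nmr_shifts` | amide chemical-shift perturbation (1/5-scaled ¹⁵N), Cα/Cβ secondary shifts vs random coil with 1-2-1 smoothing, HetNOE mobility flags, Gaussian line-width (FWHM) fits |
| `relay.synthetic_data` | deterministic seeded generators with ground truth for every stage |
| `relay.cli_pipeline` | YAML-configured orchestration behind `relay run` |

Note: the covariation scorer is MI with average-product correction,
z-standardized, as an in-repo stand-in for heavier pseudolikelihood inference;
externally computed coupling tables can be imported (`relay coupling agree
--scores ...`) so the distance-agreement analysis can also run on scores from
other engines.

## CLI

```sh
relay structure summarize structure.pdb
relay superpose fixed.pdb moving.pdb --mode sequence --out moved.pdb
relay graft --config graft.yaml
relay interface contacts model.pdb --group-a A,B --group-b C
relay interface xtal crystal.pdb --radius 5
relay msa profile family.fasta
relay msa motif family.fasta FxSGY
relay coupling score family.fasta --out scores.tsv
relay nmr csp reference.csv modified.csv
relay simulate graft --seed 1 --out-dir fixtures/
relay run --config configs/synthetic_pipeline.yaml
```

Shift tables are CSV (`resnum,restype,h,n,ca,cb`) or simple NMR-STAR-style
rows; alignments are FASTA or Stockholm; structures are PDB or mmCIF.

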