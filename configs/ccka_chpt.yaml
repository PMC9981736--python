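# Worked configuration for the hybrid-kinase DHp/Rec grafting case study.
#
# Structure files are NOT bundled (no network in this environment); place the
# deposited coordinate files under data/structures/ as <id>.pdb to enable the
# structure-based regressions:
#   6tne.pdb  - receiver-domain monomer crystal structure
#   4qpj.pdb  - HPt/receiver phosphotransfer complex (template)
#   5idj.pdb  - kinase DHp-CA monomer
#   3q15.pdb  - Spo0F receiver domain
#
# Anchor helix ranges below are the implementer's reading of the helix
# annotations of the deposited entries (the published procedure names the
# anchors as secondary-structure halves, not residue lists). They are
# deliberately configuration, not code.

structures:
  rec: data/structures/6tne.pdb
  template: data/structures/4qpj.pdb
  dhp: data/structures/5idj.pdb
  spo0f: data/structures/3q15.pdb

template_chains:
  hpt: A        # HPt/DHp-like chain of the template complex
  rec: C        # receiver chain of the template complex

anchors:
  # C-terminal half of DHp helix a1' (donor) onto the template HPt a1
  dhp_alpha1_c_half: {donor: [328, 342], template: [28, 42]}
  # N-terminal half of DHp helix a2' onto the template HPt a2
  dhp_alpha2_n_half: {donor: [350, 364], template: [49, 63]}
  # receiver helix a1 onto the template receiver a1
  rec_alpha1: {donor: [578, 592], template: [8, 22]}

active_site:
  his: 322          # phospho-accepting histidine of the kinase DHp
  asp: 623          # phospho-accepting aspartate of the receiver domain
  # template pair resolved automatically (closest His/Asp across the
  # template chains) unless given explicitly:
  template_his: auto
  template_asp: auto

superpositions:
  rec_vs_template_rec: {chains: [C]}         # sequence-mode CA pairing
  rec_vs_spo0f: {chains: [A]}
  # DHp helix pairs, ranges mode (~43 CA positions in total)
  dhp_helix_pair:
    donor_ranges: [[325, 345], [349, 370]]
    template_ranges: [[25, 45], [49, 70]]

crystal_contacts:
  radius: 5.0
  n_points: 240
  max_area: 275.0
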