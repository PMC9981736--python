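# Fully synthetic end-to-end pipeline: generate fixtures, then run the
# alignment, covariation and chemical-shift stages on them.
seed: 1
simulate:
  targets: [msa, shifts]
msa:
  motif: FxSGY
coupling:
  threshold: 3.0
nmr:
  t1: 0.2
  t2: 0.4
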