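# External inputs (not redistributed)

Two optional inputs enable the external reproductions; neither ships with
the package and the tests that need them fail with an explanatory message
when they are absent.

- `yeast_snornas.fasta` — the 43 *S. cerevisiae* box C/D methylation-guide
  snoRNAs from the UMass-Amherst yeast snoRNA database (RNA or DNA
  alphabet; DNA is coerced). Optionally `yeast_targets.tsv` with columns
  `snoRNA_id  substrate_id  position  box_kind` (1-based positions).
- `rnp_components.fasta` — component sequences for the RNP mass checks,
  with record ids `Nop5` (UniProt Q8U4M1), `Fib` (Q8U4M2), `Snu13`
  (P39990), and the guide RNAs `snR51` and `sR26`.
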