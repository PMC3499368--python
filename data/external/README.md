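# External reference data (not redistributed)

Two comparisons in the test suite use third-party reference data that this
repository does not redistribute. To run them, place the following files in
this directory:

- `4FN9.pdb`, `4FNE.pdb` — the AncSR2 ligand-binding-domain crystal
  structures in complex with progesterone and 11-deoxycorticosterone,
  downloadable from the Protein Data Bank
  (`https://files.rcsb.org/download/4FN9.pdb`, likewise for 4FNE). Used by
  the backbone-RMSD comparison (`minspec superpose 4FN9.pdb 4FNE.pdb`).
- `ancestral_lbds.fasta` — a FASTA file with two records named `AncSR1`
  and `AncSR2` containing the reconstructed ancestral LBD protein
  sequences from the study's supplementary tables. Used by the
  sequence-difference count.

When these files are absent the corresponding tests report exactly that;
every other part of the package is exercised on generated data.
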