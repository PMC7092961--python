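# rnaet — Evolutionary Trace for RNA

`rnaet` ranks every column of an RNA multiple sequence alignment by
phylogenetic importance, measures how strongly the top-ranked nucleotides
cluster in three-dimensional (or secondary/primary) structure, tests their
overlap with known functional sites, and optimizes which input sequences to
trace in the first place. It is aimed at people studying structured
non-coding RNAs — ribozymes, riboswitches, ribosomal RNA — who want
single-nucleotide functional predictions from sequence families plus a
structure, without any experimental prior.

## The method

Given an alignment of N homologous sequences, a UPGMA tree is built on
normalized Hamming distances (gaps count as a fifth symbol). Cutting the
tree just below its first n−1 internal nodes, ordered by distance from the
root, splits the leaves into n groups. **Integer ET** ranks column *i* as

    r_i = 1 + Σ_{n=1}^{N−1} δ(n),   δ(n) = 0 iff the column is invariant
                                    within every group at level n

and **real-value ET (rvET)** replaces the 0/1 penalty by the mean in-group
Shannon entropy,

    r_i = 1 + Σ_{n=1}^{N−1} (1/n) Σ_{g=1}^{n} ( −Σ_a f_iag ln f_iag ).

A fully conserved column earns r = 1; a column that varies everywhere earns
the worst rank. Ranks are normalized to percentile **coverage**; nucleotides
in the top 35% coverage are the "ET nucleotides".

Their structural clustering is scored by the **selection clustering
weight** w — the number of contacts (minimum heavy-atom distance ≤ 4 Å)
internal to the selection — standardized against a uniformly random
selection of the same size as z_c = (w − ⟨w⟩)/σ, with ⟨w⟩ and σ in closed
form. Overlap with a functional site of M of N positions is standardized
under the hypergeometric null, z_o = (k − nM/N)/σ. Both are averaged over
cumulative coverage bins from 0 to 35% (**zc35%**, **zo35%**); z ≥ 2 marks
significance. **ET smoothness** SMT = Σ A(i,j)(x_i − x_j)² summarizes how
gradually ranks vary over the structure, and **rank entropy**
RE = −Σ_r f_r ln f_r guards against degenerate traces. An ensemble
optimizer re-selects input sequences by maximizing zc35% (or normalized
RE × smoothness).

## Worked example

Everything runs on synthetic fixtures, so no downloads are needed:

```
rna-et simulate --seed 11 --out fx
rna-et trace   --aln fx/alignment.sto --method rvet --out ranks.tsv --newick tree.nwk
rna-et cluster --ranks ranks.tsv --aln fx/alignment.sto \
               --structure fx/structure.pdb --chain A --context 3d --out zprofile.tsv
rna-et overlap --ranks ranks.tsv --aln fx/alignment.sto --sites fx/sites.tsv \
               --structure fx/structure.pdb --out overlap.tsv
```

which prints

```
INFO traced 60 columns (rvET)
INFO zc35% = 3.046, SMT = 33958.3
INFO planted: zo35% = 4.609, AUC = 0.979
```

The fixture plants a functional site on the conserved and clade-specific
columns of a 16-sequence, 60-column alignment and folds it into a
contiguous stretch of a toy helix. The trace output (`ranks.tsv`) holds one
row per column, e.g. the clade-fixed column 2 gets rank 1.693 (= 1 + ln 2:
perfectly conserved within each of the two clades, split between them) and
coverage 41.7%. zc35% = 3.0 says the top-ranked nucleotides form about
three standard deviations more 3D contacts than random selections of the
same size; zo35% = 4.6 and AUC = 0.98 say they recover the planted site far
better than chance (z ≥ 2 is the significance bar). The same library calls
are available in Python via `rnaet.score_alignment`,
`rnaet.overlap_profile`, etc.

`rna-et optimize --criterion zc35` re-traces random sub-alignments and
returns the member with the best ET clustering — useful when the input
family contains misaligned or overly distant sequences.

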