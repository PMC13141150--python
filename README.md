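# embalign

Progressive multiple sequence alignment with swappable residue-level
scoring backends. The alignment optimizer is a classical exact global
affine-gap dynamic program (Needleman–Wunsch–Gotoh, three states M/Ix/Iy,
gap cost `gap_open + (L-1) * gap_extend`); what varies is only the scoring
layer that fills the dense score matrix consumed by the DP:

* **learned** — a trained symmetric residue-compatibility network
  `f(x, y) = f(y, x)` evaluated on per-residue embeddings (symmetry is
  structural: the feature map `[x+y, x*y, |x-y|]` is invariant under swap,
  so equality holds bit-for-bit);
* **cosine** — cosine similarity of residue embeddings (embedding-based
  alignment control);
* **blosum62** — the standard static substitution table (profile columns
  score as the mean over their non-gap members).

All scoring happens strictly before dynamic programming; the DP layer
receives only fixed numbers and is importable without the scoring module.

The package is self-contained at desk scale: a synthetic simulator
generates homologous protein families with an exactly known true
alignment (substitutions biased toward similar residues, geometric-length
indels threaded through a master coordinate system), matched coding
sequences, and deterministic synthetic residue embeddings whose geometry
carries residue identity plus local context. That makes the learned
scorer trainable and the whole pipeline testable without downloads. An
external protein-language-model embedding provider can be plugged in via
`embalign.embeddings.register_provider`; none is bundled, and requesting
an unavailable provider is an explicit error.

Also included:

* **codon-aware mode** — CDS validation (frame, internal stops, canonical
  alphabet), translation, protein-space alignment, and back-mapping with
  verbatim original codons and codon-length gaps;
* **evaluation stack** — SP/TC scoring against reference alignments,
  paired two-sided Wilcoxon signed-rank tests (exact null up to n=25) with
  Holm step-down correction, gap-penalty robustness summaries, and
  phase-resolved runtime profiling (embedding / scoring / DP).

## Command line

```sh
# generate synthetic families (sequences, true MSA, optional CDS)
embalign simulate --out-dir fams --families 5 --taxa 8 --length 100 --seed 1 --cds

# align (defaults: cosine backend, UPGMA insertion order, penalties -2.5/-0.7)
embalign align --input fams/fam0001/sequences.fasta --output aln.fasta

# train the learned scorer on simulated families, then use it
embalign train --families-dir fams --out scorer.ckpt --epochs 25
embalign align --input fams/fam0001/sequences.fasta --output aln.fasta \
    --backend learned --weights scorer.ckpt

# codon-aware alignment of coding sequences
embalign codon-align --input fams/fam0001/cds.fasta \
    --output-protein p.fasta --output-nucleotide n.fasta --output-report report.tsv

# score a test alignment against a reference
embalign score --test aln.fasta --reference fams/fam0001/true_msa.fasta

# benchmark backends over a gap-penalty grid with paired statistics
embalign benchmark --families-dir fams --out-dir bench \
    --backends cosine,blosum62 \
    --gap-open -3.5 --gap-open -2.5 --gap-open -1.5 \
    --gap-extend -1.0 --gap-extend -0.7 --gap-extend -0.3
```

Every run writes a JSON echo of its resolved configuration next to its
outputs; identical inputs and configuration produce byte-identical output
files. No subcommand performs network access.

## Layout

```
src/embalign/
  seq_io.py       FASTA I/O, alphabets, translation
  synthetic.py    family simulator, synthetic embeddings, reverse translation
  embeddings.py   embedding provider interface + caching
  scoring.py      learned / cosine / BLOSUM62 backends, score matrices
  training.py     pair dataset, numpy MLP training, checkpoints
  align_core.py   exact affine-gap DP (no scoring imports)
  progressive.py  order policies (UPGMA/input/random) + profile assembly
  codon.py        CDS validation, back-mapping, codon pipeline
  evaluation.py   SP/TC, Wilcoxon + Holm, gap robustness, phase profiling
  cli.py          command-line entry point
```
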