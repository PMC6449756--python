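# splitgene

Phylogenetic detection of **split genes**: pairs of annotated gene models
that are actually non-overlapping (or barely overlapping) fragments of a
single gene.  Fragmentary assemblies — large plant genomes in particular —
routinely break genes across contigs, and the pieces then masquerade as
paralogs, polluting orthology inference, tree building and gene counts.
`splitgene` is aimed at genome annotation and comparative-genomics groups
who have a draft proteome, a gene-family assignment (e.g. hierarchical
orthologous groups), and reference proteomes from related species.

## Method

Within each gene family, every pair of target-genome genes with
`l1, l2 >= 50` aa and aligned overlap `a12 < 0.1*l1 AND a12 < 0.1*l2`
(strict) is a candidate pair.  Two complementary tests are combined by
intersection:

1. **Collapsing test.**  Internal branches of the family tree with
   bootstrap support `< 0.95` are contracted; the pair is called split if
   the fragments become sister leaves (polytomies included).
2. **Likelihood ratio test.**  H_s ("split"): the fragments are one gene,
   merged into a single row (n−1 genes).  H_p ("paralogs"): they are two
   genes.  The statistic is `T = 2 ln[L(H_p)/L(H_s)]`.  The hypotheses are
   not nested, so the null distribution is estimated by resampling columns
   of the merged alignment with replacement and recomputing the statistic
   on each replicate after splitting it back at the same (per-column
   tracked) positions.  With `p_B = #{T*_i >= T0}/n`, *failure to reject*
   (`p_B >= 0.01`) yields the split prediction.

Genes involved in several compatible predictions are reported as a
multi-piece chain; predictions whose partner fragments claim the same
alignment region are labelled *ambiguous*.  A self-contained ML engine
(LG model, Felsenstein pruning, NJ + NNI search, Felsenstein bootstrap)
backs both tests; MAFFT/FastTree can be plugged in through adapters.
See `docs/methods.md` for the full model description.

## Worked example

Simulate a small dataset with one planted split gene and one planted
paralog-derived negative pair, run the pipeline, and score it:

```bash
splitgene simulate --out demo --n-refs 4 --seq-length 150 \
    --n-positive 1 --n-negative 1 --dup-depth 0.3 --seed 7
splitgene run --fasta demo/T.fa --fasta demo/R1.fa --fasta demo/R2.fa \
    --fasta demo/R3.fa --fasta demo/R4.fa --families demo/families.tsv \
    --target-genome T --alignments demo/alignments \
    --n-boot 20 --seed 7 --out demo/results
splitgene evaluate --predictions demo/results/predictions.tsv \
    --truth demo/truth.tsv
```

This prints

```
2 candidate pairs, 1 split predictions -> demo/results/predictions.tsv
{
  "tp": 1,
  "fp": 0,
  "fn": 0,
  "n_positive": 1,
  "n_negative": 1,
  "fp_on_negatives": 0,
  "recall": 1.0,
  "precision": 1.0,
  "fp_rate_negatives": 0.0
}
```

i.e. both planted pairs passed the candidate filters, the planted split was
recovered (`tp`), and the paralog negative was correctly not called
(`fp_on_negatives = 0`).  `demo/results/predictions.tsv` holds one row per
candidate pair with the collapse decision, `T0`, `p_B`, the combined call
and the ambiguity label.

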