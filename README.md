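# uaugscan

Upstream AUGs (uAUGs) in 5'-UTR leader sequences repress translation of the
downstream open reading frame, and for several well-studied genes that
repression is cell-type specific even though the mRNA is expressed
everywhere.  `uaugscan` implements a genome-scale test of one proposed
explanation: that uAUG-centered motifs are sequence-specific binding sites
for microRNAs — preferentially for the **3' half** of the mature miRNA, the
arm opposite the canonical seed — so that repression tracks which miRNAs a
cell expresses.  It is written for computational biologists studying
post-transcriptional regulation who want a reproducible, fully seeded
reimplementation of this analysis with a built-in synthetic benchmark.

## What it computes

1. **Motif extraction.**  From human/mouse 5'-UTR alignment pairs, every
   AUG yields an 11-nt window (−4..+7, the A of AUG as +1; clipped windows
   of 7–10 nt kept at UTR ends).  A motif is *conserved* when its alignment
   columns are 100% identical in mouse.
2. **Catalog.**  Mature miRNAs are *conserved* when their base name occurs
   under another species prefix, and are split into 5'/3' halves (the 3'
   half takes the extra nucleotide of odd-length matures).
3. **Two-step screen.**  For each motif × half, find the longest
   antiparallel run of consecutive Watson-Crick or G·U pairs with a bounded
   wobble count (`max_gu` 0 or 1), then score that run with a Turner-2004
   nearest-neighbor duplex energy.  A hit needs a run of ≥ 7 **and**
   ΔG37 ≤ −14 kcal/mol.
4. **Significance.**  Interaction counts per stratum (miRNA end × miRNA /
   motif conservation class) are compared with a null obtained by re-running
   the screen on composition-preserving shuffles of every miRNA; the null is
   summarised as normal and a one-sided Z-test reports enrichment.
5. **Gene reports.**  Printed uAUG windows (wild-type and mutant) are
   scanned against conserved miRNAs (one wobble allowed at the 3' end) and
   joined to repression-fold annotations and per-cell-line miRNA expression
   calls.

A fully seeded synthetic-data module generates alignment pairs, two-species
catalogs and **planted** reverse-complement binding sites with exact ground
truth, so the whole pipeline is testable without any downloads.

## Worked example

Simulate a small dataset with planted 3'-half binding sites, then run the
shuffle-null significance stage:

```bash
uaugscan simulate --seed 42 --out demo --n-utrs 40 --n-mirnas 20 --plant-rate 0.15
# wrote 40 alignments, 32 miRNAs, 14 planted sites to demo

uaugscan significance --alignments demo/alignments.fasta \
    --mirnas demo/mirnas.fasta --iterations 200 --seed 42 --max-gu 0 --out demo_sig
```

which prints (abridged):

```
                 stratum  observed  null_mean  null_sd       z            p
 5p/cons-mirna/all-motif         0      0.405   1.0895 -0.3717 6.449590e-01
 3p/cons-mirna/all-motif        18      0.385   0.9116 19.3242 1.682227e-83
3p/cons-mirna/cons-motif        17      0.295   0.8007 20.8620 5.928845e-97
```

Reading the output: 18 interactions between uAUG motifs and **3' halves of
conserved miRNAs** were observed against a shuffle-null expectation of 0.39
± 0.91 — the planted signal (14 sites, plus background) is recovered at
z ≈ 19 — while the 5'-half stratum shows nothing, matching the planted
asymmetry.  Nearly all of the signal sits in *conserved* motifs because the
generator keeps planted windows identical in mouse.

Other subcommands: `uaugscan extract` (motif tables and per-UTR summaries),
`uaugscan scan` (the hits table), `uaugscan gene-report` (per-gene tables
joining predictions, folds and expression evidence; the printed KLF9 uAUG
windows and a curated two-miRNA catalog are bundled under
`src/uaugscan/data/`).

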