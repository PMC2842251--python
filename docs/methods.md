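# Methods

`uaugscan` asks whether upstream AUG (uAUG) motifs in 5'-UTR leader
sequences can act as sequence-specific binding sites for microRNAs, and
whether such complementarity is enriched beyond what nucleotide composition
alone would produce.  This note documents the model, the parameters that
matter, the synthetic-data generator, and the numerical and design choices
made where the design was genuinely open.

## Motif extraction

Every AUG triplet in a 5'-UTR counts as a uAUG; the curated inputs are
leader sequences only, so no Kozak-context filtering or uORF annotation is
applied, and overlapping AUGs each produce a motif.  For each occurrence an
11-nt window is cut from four nucleotides upstream of the A through four
downstream of the G (positions −4..+7 with the A as +1).  Near the UTR ends
the window is clipped; clipped windows shorter than 7 nt are discarded, and
clipping can only remove flanks, never part of the AUG.

A motif is **conserved** when the human/mouse alignment columns covering it
are 100% identical: any substitution, any mouse gap, and any mouse insertion
(a human-gap column) inside the span breaks conservation.  This is the
strictest reading of full identity; conservation is judged on the supplied
alignment columns, never by re-aligning.

Coordinates are 0-based half-open in memory; 1-based positions appear only
in written reports.

## miRNA catalog

A focal-species mature miRNA is **conserved** when its base name (the name
with the three-letter species prefix stripped) occurs under a different
prefix anywhere in the catalog — a name-level property, irrespective of
nucleotide identity.  Matching is exact up to case; arm and locus variants
(e.g. `miR-219-1-3p` vs `miR-219-2-3p`) are distinct.

Mature sequences are split into a 5' half (containing the seed, positions
2–7) and a 3' half.  For odd lengths the extra nucleotide goes to the **3'
half** (`five = seq[:L//2]`, `three = seq[L//2:]`): the 3' arm is the arm
whose interactions this scan emphasises, and the printed motif sets this
package reproduces require the 3'-terminal 11 nt of 21-nt matures to be
available as one half.

## The two-step interaction screen

For a motif *m* (5'→3') and a miRNA half *h* (antiparallel), step one finds
the longest run of consecutive paired positions in which every pair is
Watson-Crick (A·U, G·C) or a G·U wobble, with the number of wobbles bounded
by `max_gu`.  Runs are enumerated per diagonal with a wobble-budget sliding
window; ties between equal-length runs are broken by fewer wobbles, then
smaller motif start, then smaller half start, so output is deterministic.
Genome-scale runs use the same bound on both ends (0 or 1); gene-level
reports allow one wobble against the 3' half and none against the 5' half.

Step two scores the best run with a nearest-neighbor duplex free energy

    dG37 = duplex_init + sum(stack dG37 over adjacent pair doublets)
           + terminal penalty per non-G·C helix end

using the Turner 2004 stacking parameters (Watson-Crick and G·U doublets;
terminal penalty 0.50 kcal/mol), shipped as a versioned TSV
(`stack_dg37_turner2004.tsv`).  A pair passes only if the run is at least
`min_stretch = 7` long **and** dG37 ≤ `dg_cutoff = −14` kcal/mol; the two
criteria are conjunctive.

Two initiation conventions are bundled.  The screening default,
`turner2004-hybridization`, sets `duplex_init = 0`: screening thresholds of
this kind describe hybridization stability in the convention of duplex-
screening tools, which omit the bimolecular initiation term.  The
`turner2004-duplex` variant adds the +4.10 kcal/mol initiation and
reproduces ViennaRNA cofold evaluation (dangles off) exactly on fully
paired duplexes — it is the cross-checked physical duplex energy and the
tests validate the stack table through it.

**Known limitation.**  The energy is evaluated over the consecutive stretch
only — no bulges, internal loops, dangling ends or pairing outside the
stretch.  This makes the −14 kcal/mol screen substantially stricter than a
full hybridization fold of an 11-mer window: a perfect 7-bp A·U-rich match
tops out near −9 kcal/mol and cannot pass, and a 7-bp one-wobble match such
as the strongest KLF9-window/miR-31 pairing scores −12.9 kcal/mol.  Short,
weakly stacked duplexes that a loop-aware hybridization tool admits at −14
are therefore rejected here; GC-normal stretches of 8+ pairs pass.  An
extended loop-aware duplex model is an explicit hook, not implemented.

## Shuffle null and significance

The null re-runs the identical two-step screen after permuting the letters
of every mature miRNA (a uniform, composition-preserving mononucleotide
shuffle of the **full** sequence, with halves re-derived afterwards —
shuffling halves separately would preserve per-half composition, a
different null; a regression test pins this order).  Counts are
(motif occurrence, miRNA, end) triples, collected per stratum: each miRNA
end crossed with miRNA conservation class over all motifs, and each end
crossed with motif conservation class over conserved miRNAs.

The null over `iterations` (default 1000) shuffles is summarised by its
mean and sample standard deviation (n−1) and treated as normal; the
reported p is the one-sided upper tail (enrichment).  With a degenerate
null (sd = 0) the p-value is 0, 1 or 0.5 by sign and is flagged.  No
multiple-testing correction is applied across strata by default; a
Bonferroni option exists.  An empirical-quantile p is available as a
diagnostic, not the headline.  Iteration *t* draws from the counter-based
stream `default_rng([seed, t])`, so results are reproducible and
independent of execution order.

**Calibration caveat.**  Interaction counts are sums of per-miRNA clusters:
one favorably ordered GC-rich half can hit many motifs at once.  The count
distribution is therefore overdispersed and right-skewed, and the normal
approximation is anticonservative at small means — with stratum means
below ~5 the realised p < 0.05 rate under a true null can approach 0.1 or
worse.  The bundled calibration study
(`uaugscan.benchmarks.null_calibration`) therefore uses conditions chosen
for the approximation to be tenable: the one-wobble screen and the all-hits
stratum (mean ≈ 35–40) and many miRNAs against few motifs (64 UTRs, 128
miRNAs), which shrinks cluster variance at a fixed motif × half budget.
Users applying the Z-test to sparse strata should prefer the empirical p.

## Gene-level meta-analysis

Printed 7–11-nt uAUG windows (or a full UTR) are scanned against conserved
miRNAs only, under the 3'-wobble policy above.  Repression folds (1×–6×,
where 1× means no measurable repression of a downstream reporter) are
experimental annotations consumed as data, never computed.  Expression
evidence is a per-(miRNA, cell line) presence/absence table; hits join to
`True`/`False`/unknown.  Mutant windows (e.g. AUG→AAG) run through exactly
the same search path as wild-type windows — nothing inspects the mutant
flag during scanning — so any change in predictions is attributable to
sequence complementarity alone.  Reports are deterministic and re-emittable
byte for byte.

The bundled curated miRNA subset (`mirna_curated_subset.fasta`) contains
hsa/mmu let-7d and miR-31 — the miRNAs whose mature sequences are
independently checkable against the printed motif sets this package
reproduces.  Gene-level worked examples run against this subset; a full
miRBase-style FASTA can be supplied in its place.

## Synthetic data

The generator emulates: GC-rich leaders (`gc_content = 0.6`; mammalian
5'-UTRs are GC-rich) of 60–300 nt; uAUG counts per UTR that are exactly
Poisson (`uaug_rate = 2.0`, putting ~68% of UTRs at ≤ 2 uAUGs) — incidental
AUGs are stripped before injection so the planted count is the true count;
gapless human/mouse alignments with independent per-column substitutions
(`column_conservation_rate = 0.97`, i.e. ~70% of 11-mers fully conserved);
and a two-species catalog with Bernoulli cross-species presence
(`conserved_mirna_fraction = 0.7`).  All randomness flows from one root
seed via per-stage counter-based streams.

Binding sites are planted by overwriting an 11-mer uAUG window with the
reverse complement of a conserved miRNA's 3'-terminal 11 nt, leaving flanks
untouched (so detection cannot leak from context) and synchronising the
mouse row (so planted motifs stay conserved).  A half is *eligible* only if
its window carries AUG at offset 4 and the perfect 11-bp duplex already
passes the default screen; eligibility filtering — rather than mutating the
planted site — keeps planted sites exact complements, which is what makes
recall on the ground truth exactly 1.  `site_competent_rate` embeds a CAU
triplet at the mapped 3'-half position so eligible candidates exist; it
defaults to 0 and must be enabled for planted runs, because an unplanted
null dataset has to keep motifs and miRNAs independent — with the embedding
on, every catalog carries AUG-complementary triplets at the pairing
register and observed counts sit systematically above the shuffle null.

What the generator does **not** emulate: alignment gaps (gap handling is
exercised by hand-written fixtures), CpG/GC-skew composition structure,
length-dependent conservation, seed-family structure among miRNAs, or
expression data.  Passing tests on synthetic data therefore demonstrate the
pipeline's statistical behaviour under its own assumptions, not performance
on real UTR corpora.

## Problem sizes used by the bundled studies

The recovery study plants sites at rate 0.2 on 200 UTRs against a ~70-miRNA
catalog (~50 conserved / ~20 non-conserved as Bernoulli draws at fraction
5/7) and uses 100 shuffle iterations; the calibration study runs 200
unplanted datasets at 50 iterations each.  These sizes keep each study in
the minutes range on one CPU while leaving stratum counts large enough for
the statistics they examine.

## Degenerate inputs and tie-breaks

Empty motif lists scan to empty hit lists; UTRs with no AUG contribute a
zero bin to the per-UTR histogram; a length-0 stretch (nothing pairable)
is representable and never reaches the energy step; unpairable positions
inside a claimed stretch raise immediately rather than scoring.  All
orderings (hit tables, reports, stratum rows) are total and documented, so
every pipeline stage is byte-identical across reruns with one seed.
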