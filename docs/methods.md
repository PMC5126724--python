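# Methods

`plastomics` implements a comparative analysis of annotated chloroplast
genomes (plastomes): quadripartite architecture detection, inverted-repeat
(IR) junction typing, unique-gene inventories with duplication typing,
reference-projected SNP divergence by sequence partition, and screening of
divergence hotspots as candidate DNA barcodes. A synthetic-data module
generates annotated plastomes with planted ground truth so that every stage
is testable end to end without downloads. This note records the models,
conventions and numerical choices, and what the synthetic benchmarks do and
do not demonstrate.

## Coordinate model

All internal coordinates are 0-based half-open on the forward strand of the
circular molecule; conversions happen only at file boundaries (GenBank and
VCF are 1-based, BED is 0-based). Features may wrap the circular origin; a
`wraps_origin` flag marks an exon split at position 0 so the split is not
counted as an intron. Comparative analyses operate on records in *canonical
rotation*: position 0 is the first base of the large single-copy region
(LSC), giving the segment order LSC, IRb, SSC, IRa. The four junctions are
named JLB (LSC/IRb), JSB (IRb/SSC), JSA (SSC/IRa) and JLA (IRa/LSC), each
defined as the 0-based index of the first base of the downstream segment.

## Inverted-repeat detection

Every base pair of an IR pair satisfies `seq[a] == complement(seq[c - a])`
for a fixed anti-diagonal constant `c` (mod genome length). Detection
seeds exact k-mers of the sequence against its reverse complement
(k = min(21, `min_ir_len`), floor 4), histograms the implied anti-diagonals,
and scans the top candidates base-by-base. Maximal exact match runs are
chained under a mismatch-fraction budget (`max_mismatch_frac`, default
0.005); only *anchor* runs of ≥ 8 exact matches may start or end a chained
segment, so segments cannot creep past a repeat boundary on chance matches
and chained segments always begin and end on matching bases (trailing
mismatches are trimmed by construction). The maximal-length disjoint pair
wins; a palindromic stretch (a run equal to its own image) is split into
two halves; ties are broken by the smallest IRb start, with a warning. The
longer single-copy segment is labelled LSC, and IRb is the copy whose 5'
end follows the LSC in forward orientation. The result is invariant to
rotation and to reverse-complementing the input, and for genomes small
enough to enumerate it equals an exhaustive anti-diagonal scan (tested).

The default `min_ir_len` of 1000 bp rejects dispersed repeats while
accepting all plastid IRs (observed IRs in this group are 27–28 kb). The
mismatch budget is mismatch-only: IR copies that differ by indels are not
modelled, a known limitation (real plastome IRs are homogenised by
concerted evolution and are near-identical in practice).

## Gene inventories and duplication typing

The counting unit is the *gene locus*: features sharing a symbol and an
exon-length signature are copies of one locus, so IR-mirrored and tandem
copies collapse, while structurally distinct loci under one symbol count
separately. This reproduces the standard plastome gene-table convention:
the trans-spliced rps12 contributes two entries (its independently
transcribed 5' and 3' loci), the duplicated or triplicated trnI-CAU
contributes one, and the full catalog totals 115 loci — 81 protein-coding
entries, 30 tRNAs, 4 rRNAs, with 12 intron-bearing protein genes and 6
intron-bearing tRNAs. Pseudo-genes (the truncated ycf1 copy at JSB, the
mirrored boundary-gene fragment at JLA) are excluded from inventories but
retained for junction analysis.

trnI-CAU copy number is counted between the rpl23 and ycf2 anchors within
one IR copy, comparing feature midpoints along the shorter arc between the
anchors; 1, 2 and 3 copies map to the field's "single-copy (Daiswa type)",
"duplicated" and "triplicated (Paris s.s. type)" labels. IR/LSC junction
typing labels a genome "rps3-expanded" when the junction gene is rps3 and
"rps19-type" (the typical monocot architecture) when it is rps19.

## Reference projection and SNP calling

Each query genome is globally aligned to the designated reference with
edlib (bit-vector edit-distance alignment with traceback; both
orientations are tried and the better kept) and projected onto reference
coordinates: one allele per reference position, `-` for deletions,
insertions kept aside as `(position, string)` pairs. Unit gap costs mean
an adjacent substitution pair can be expressed as an equal-cost
deletion+insertion; a local realignment pass therefore re-aligns small
windows around every indel event, anchored on clean match columns, with
weights match 0 / mismatch 4 / gap 5, so a gap pair (10) is dearer than two
mismatches (8) and substitution-only variation always projects as
substitution columns. Queries whose aligned identity falls below 70% are
rejected as too divergent to project.

SNP calling is substitution-only: a reference position is a SNP iff at
least one taxon carries a non-gap, non-N allele different from the
reference base. Indel-only and N-only differences are excluded;
multi-allelic positions collapse to one row. Because calling is
per-reference-position, IR variants count once per IR copy, as in
whole-genome SNP scans. Divergence proportions divide SNP counts by
partition lengths: the total percentage uses the full reference length,
coding and non-coding (introns + spacers pooled) use their partition
lengths; a zero-length partition reports an undefined (not zero) value.

## Partitioning and the barcode screen

The reference is partitioned exhaustively: *coding* is the union of all
annotated exons (pseudo-genes included, so the ycf1 fragment is not
mistaken for a spacer); *introns* are within-gene gaps left uncovered, with
a gene nested inside another's intron (the trnK/matK pattern) splitting
that intron; *spacers* are maximal gene-free intervals labelled
"geneA/geneB" after their flanking genes. Every position belongs to
exactly one class, and each region is tagged LSC/IRB/SSC/IRA by its
midpoint. Regions located in IRA are reported once, under their IRB
mirror.

The barcode screen keeps non-coding regions of 200–1,500 bp (inclusive)
whose SNP percentage strictly exceeds 3%, ordered by SNP percentage
descending; ties are broken by longer region, then label. Primer metrics
use GC% rounded half-up to one decimal and the Wallace rule
Tm = 2·(A+T) + 4·(G+C) by default (a GC-fraction formula,
64.9 + 41·(GC − 16.4)/N, is selectable); published Tm values deviate from
Wallace by ~0.1 °C, so Tm is reported but never used as a pass/fail
criterion. Primer selection itself is user input; an end-anchored picker
(first/last 20-mers of a region) is provided for convenience.

## The synthetic-data generator

The generator emulates the plastomes of the studied group: a circular
~158 kb molecule (defaults LSC 84.5 kb, SSC 18.3 kb, IR 27.5 kb, the
middles of the observed ranges), 37.3% GC, the 115-locus catalog in
canonical angiosperm gene order with realistic approximate lengths,
optional trnI-CAU duplication or triplication between rpl23 and ycf2, the
IR/LSC junction placed inside rps3 or rps19, a 1 kb ycf1 pseudo-fragment
at the IRb end overlapping ndhF by 120 bp, and trnK-UUU's intron hosting
matK. Intergenic spacers are sized to fill each segment evenly, except
seven classically variable spacers given realistic ~750–850 bp widths so
hotspot injection acts on regions in the barcode size range. The bases
flanking the planted IR pair are forced non-complementary so the planted
boundaries are the true maxima and detection can be held to 0 bp error. A
~25-gene scaled catalog (defaults 9/3.5/6 kb segments) keeps every
category, intron pattern and duplication pattern for fast tests.

Taxa evolve independently from the single ancestor (a star phylogeny) by a
Jukes–Cantor-like model: each site substitutes to a uniformly chosen
different base with its partition's per-site probability; hotspot regions
are boosted multiplicatively. IRs evolve concertedly — substitutions drawn
on IRb are mirrored into IRa — so simulated IRs remain exact reverse
complements, as concerted evolution maintains in real plastomes. An
optional indel mode adds short (1–4 bp) indels in single-copy spacers,
shifting annotation coordinates accordingly, for alignment testing.

Because observed divergence proportions are cohort-level aggregates (the
fraction of positions at which any of n taxa differs from the reference)
while the generator's rates are per-taxon, the helper
`per_taxon_rate(R, n) = 1 − (1 − R)^(1/n)` converts a cohort target into
the per-taxon planted rate. The acceptance script additionally scales the
non-coding background down so that the length-weighted aggregate over
background and 3×-boosted hotspot loci equals the cohort target — printed
aggregates already include the natural hotspots they average over.

Default cohort conditions are 11 mutated taxa plus the ancestral
reference, with per-taxon rates chosen so cohort-level coding and
non-coding divergence equal 1.655% and 2.033%.

What passing the synthetic benchmarks does *not* show about real data: the
generator writes random (non-coding-like) sequence inside genes, a star
phylogeny without shared branches, no IR indel divergence, no annotation
error, and no rearrangements; real-data performance depends on annotation
quality and on the aligner's behaviour in repeat-rich spacers.

## Problem sizes used by the test suite

The acceptance-style tests run structure recovery on 20 simulated genomes
(18 scaled, 2 full-scale), oracle equivalence on 50 random toys up to
5 kb and 25 alignment toys up to 200 bp, divergence recovery on 10
replicates of full-scale (157.8 kb) 4-taxon cohorts, and the hotspot
screen on 8 such replicates (80 planted-locus trials). These sizes give
3-sigma binomial checks adequate power while keeping the default suite
in the minutes range.

## Known limitations

- IR detection tolerates substitutions between IR copies but not indels.
- The aligner uses unit gap costs (edlib) plus the substitution-preferring
  polish; long tandem-repeat slippage may still project ambiguously.
- Divergence percentages depend on the annotation-derived partition;
  mis-annotated exon boundaries shift SNPs between classes.
- The cohort report assumes one reference taxon; reference-free multiple
  alignment is out of scope, as are tree inference and biogeographic
  analysis.
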