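# Methods

## The mapping model

In an F2 (or backcross-derived F2) population segregating a recessive
EMS-induced mutation, selecting mutant individuals fixes the mutagenized
haplotype at the causal locus. For a marker at genetic distance *d*
Morgans from that locus, each of the pool's 2n chromosome copies carries
the mutant-parent allele independently with probability 1 − r(d), where
r is the recombination fraction. `bsamap`'s meiosis model is crossover
count ~ Poisson(genetic length) with uniformly placed breakpoints and no
interference, so r follows Haldane's map function

    r(d) = (1 − e^(−2d)) / 2 ,

and the expected pooled allele frequency decays from 1 at the causal
locus to 0.5 for unlinked markers. Pooled sequencing observes this
profile through reads: depth ~ Poisson(mean coverage), each read drawn
from the pool frequency, corrupted at the per-base error rate, and
weighted by base quality.

The mapping signal is the count of *pool-homozygous* variants per fixed
1 Mbp bin. A site is homozygous when its quality-adjusted allele
frequency — quality-passing reads differing from the reference divided
by quality-passing total — is at least 0.99. At ~25× coverage this
effectively demands that every passing read carry the variant allele, so
homozygous counts collapse quickly once recombinant chromosomes enter
the pool, which is what localizes the lesion.

## Filters and their defaults

| parameter | default | role |
|---|---|---|
| `min_base_quality` | 20 (Phred) | base inclusion threshold, inclusive |
| `min_depth` | 8 reads | minimum quality-adjusted depth, inclusive |
| `max_depth_for_mapping` | 100 reads | strict cap; repeat-enriched positions are uninformative for mapping |
| `hom_threshold` | 0.99 | homozygous-call frequency, inclusive |
| EMS filter | G→A, C→T | canonical EMS transitions, reference plus strand; the pair covers both strands of a G:C→A:T lesion, so no gene-orientation flipping is applied |
| `bin_size` | 1 Mbp | binning resolution |
| `min_indel_len` | 15 bp | smallest indel resolvable as a PCR size difference on 3.5% agarose |
| flank distance | 100–150 bp | primer 3' end offset from the indel |
| `k_mad` | 5 | peak-qualification threshold in scaled-MAD units |

Deletion placeholders (`*`) in pileup consume a quality character but
carry no base call; they are excluded from both the numerator and the
denominator of the allele frequency. Ties for the most frequent
non-reference base break in A<C<G<T order for determinism.

## Interval calling

"Counts returned to background" is formalized as: background = the
genome-wide median bin count; a peak must exceed background + k·MAD
(MAD scaled by 1.4826); the primary interval is the maximal run of
contiguous bins, each strictly above background, containing the global
maximum bin. Other runs whose maxima clear the threshold are reported
as *secondary* intervals with their widths. This deliberately preserves
the narrow, sharp-edged single-bin peaks that arise from
reference-stock divergence near telomeres — the shape (width) is the
evidence for discounting them, so they are flagged, never silently
dropped. With a clean background the median is 0 and the rule reduces
to "the contiguous non-empty run around the maximum". All bin edges are
fixed multiples of the bin size from coordinate 1; no sliding windows.

## Consequence calling

Gene models come from GFF3 (gene/mRNA/exon/CDS); coding changes are
computed by substituting the alternate base into the spliced CDS
(reverse-complemented for minus-strand transcripts) and translating
both codons with the standard code. Splice donor/acceptor sites are the
first/last 2 intronic bases of each intron. Tiers: stop_gained,
stop_lost, start_lost, splice_donor, splice_acceptor → HIGH; missense →
MODERATE; synonymous → LOW; intronic and intergenic → NONE (the tier
below LOW, analogous to a MODIFIER class). Exonic-but-non-CDS positions
(UTRs are not modelled) are classified as intronic. Every overlapping
transcript is annotated; there is no canonical-transcript selection.
Only SNVs are effect-called — candidate indels are routed to marker
design instead. Stop-loss and start-loss are included as HIGH even
though lesion triage in practice revolves around nonsense, splice and
missense changes.

## Marker design

Indels of ≥ 15 bp that are homozygous in the mutant pool and inside the
interval become PCR markers. The primer-window search takes, on each
side, the first window of length 18–24 nt whose 3' end lies 100–150 bp
from the indel footprint, with GC fraction 0.40–0.60 and no homopolymer
run longer than 4. Primer length, GC range and the homopolymer cap are
standard PCR defaults added to make the output usable; melting
temperature is approximated by the GC-fraction proxy rather than a
nearest-neighbour model — a deliberate simplification. Expected
wild-type and mutant product sizes always differ by exactly the indel
length.

## Segregation tests

`segregation_chi_square` is the plain Pearson statistic against a
Mendelian ratio with df = classes − 1 and **no Yates continuity
correction**: with the correction, 12 mutants among 26 F1s scored
against 1:1 gives p ≈ 0.84 instead of the conventional ≈ 0.69. At the
very small totals typical of complementation crosses the chi-squared
tail probability can deviate from the exact multinomial tail by up to
≈ 0.3 (characterized by enumeration at totals 8–12 in the test suite);
the test is a conventional screen, not an exact test.

## What the simulator emulates — and what it does not

Two designs are modelled. In `bsa_outcross`, the mutagenized line
carries EMS lesions plus its background's natural polymorphisms
relative to the reference; both segregate in the F2. In
`mutmap_backcross`, only EMS lesions segregate, while parent-vs-
reference polymorphisms are fixed in every individual; parent and
wild-type-sibling pools are emitted so the subtraction path runs end to
end (before subtraction the fixed background swamps the signal; after
it the EMS peak stands alone). Optional residual-heterozygosity sites
(segregating independently of the cross, frequency 0.5) emulate an
incompletely inbred parental stock.

Default study conditions: two 100 Mbp chromosomes of 1 Morgan each
(roughly a 10× scale-down of a maize chromosome with a genome-average
recombination density), the causal lesion mid-arm at chr1:45 Mbp where
called intervals are not telomere-truncated, pools of 50 mutants at 25×
coverage, base error 0.002 with 98% of bases at Phred ≥ 20, and an EMS
spectrum that is 98% canonical G:C→A:T. Marker densities are 5 EMS
SNPs/Mbp and 10 background SNPs/Mbp: the EMS density matches the scale
of filtered homozygous-EMS tracks in real maize MutMap data (a few to
~15 per Mbp inside an interval), and the background density is chosen
of the same order so that per-bin counts are O(10) and 20-replicate
studies run in seconds. Real inbred-cross data carry ~10³× more natural
polymorphisms; the scale-down changes per-bin count magnitudes but not
the frequency law, the filter semantics, or the interval logic that the
tests exercise.

Not modelled: read-level artifacts (mapping bias, PCR duplicates,
adapter chimeras), structural variants, crossover interference, and
recombination-rate variation along the chromosome (the genetic map is
uniform). Passing tests therefore demonstrate the pipeline's logic on
an idealized pool, not robustness to alignment pathology.

A consequence of the model worth stating explicitly: because each
pooled chromosome carries the mutant allele with probability 1 − r(d)
regardless of pool size, the *expected* pooled-frequency profile — and
with it the expected position where binned homozygous counts return to
background — does not depend on the number of pooled mutants. Pool size
mainly controls the variance of the called interval (small pools give
erratic widths; large pools give stable ones); at fixed 25× coverage
the median width is nearly pool-size invariant. Sequencing depth, which
sets how far from the causal locus a site can still appear fully
homozygous, is the stronger lever on interval width — consistent with
the practical advice that coverage matters more than pool size.

## Numerical and degenerate-input choices

* All coordinates are 1-based inclusive in memory (pileup/VCF
  convention); BED export is 0-based half-open.
* Multiallelic VCF records are split per ALT; allele frequency prefers
  per-sample allele depths, falling back to Varscan-style FREQ × DP.
  Records with no usable depth are skipped, warned about and counted.
* Indels are VCF-style left-anchored with the shared leading base.
* Panel subtraction defaults to allele-keyed (chrom, pos, ref, alt) so
  an EMS lesion at a position that is polymorphic for a different
  allele in a panel is not discarded; position-keyed mode is available
  for conservative filtering.
* A flat bin profile (all counts equal) yields no interval rather than
  an arbitrary one; an empty variant input flows through every stage
  and produces empty outputs with success status.
* Simulator outputs are byte-deterministic for a given config + seed
  (single `numpy` Generator threaded through population, selection and
  read sampling).
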