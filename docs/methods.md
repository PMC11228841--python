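# Methods

## Model and procedure

`xrfrag` treats an XR-seq library mapped to a mixed nuclear + organellar
reference as a set of short (≤ 50 nt), single-end, adapter-carrying reads,
each derived from one strand of one genome. The analysis chain is:

1. **Adapter trimming.** The 3′ adapter is located as a full occurrence
   anywhere in the read or as an adapter-prefix overlapping the read's 3′
   end by at least `min_overlap` (default 3) bases, allowing
   `floor(max_error_rate × overlap)` mismatches (default 0). The leftmost
   acceptable hit wins. Reads without an adapter hit are discarded — in
   this protocol an untrimmed read means the insert was longer than the
   sequencing read, so its fragment length is unknown; empty post-trim
   reads are likewise discarded. All discards are counted.
2. **Alignment.** The internal aligner enumerates every perfect
   full-length placement of the read on both strands of every genome.
   Circular genomes are extended by (read length − 1) bases so
   origin-spanning placements are found exactly once. Uniqueness is
   combinatorial: `unique` iff exactly one placement exists. This is a
   deliberate idealization of a MAPQ cutoff: the MAPQ ≥ 30 convention
   exists to remove reads that map equally well to several locations, and
   with mismatch-free short reads the combinatorial definition captures
   that intent exactly while remaining provable against a brute-force
   scan. SAM/BAM import is provided for externally aligned data (MAPQ
   threshold, NM tag; NM recomputed from the reference when absent).
   Indels are not modeled: fragments are short and imperfect alignments
   are discarded anyway.
3. **Filtering.** Keep `unique` fragments with at most `max_mismatches`
   (default 0) mismatches; removals are counted by cause. Filtering is
   idempotent and the two criteria commute.
4. **Weighting.** Fragments overlapping a declared halve-count interval
   (the retained copy of a collapsed inverted repeat) carry weight 0.5 in
   all downstream counting. Any-overlap is used rather than a midpoint
   rule so no read in the collapsed region escapes down-weighting.
5. **Statistics.** Length spectra, positional profiles, mappability and
   RPKM coverage, all weighted.

### Reference edits and coordinates

Edits are declared by the user on 1-based inclusive coordinates (the
convention used when citing genome positions); internally all intervals
are 0-based half-open, converted at I/O boundaries. `remove_interval`
deletes a span and retains an invertible old↔new coordinate map for all
surviving positions; `halve_count_interval` marks a span for 0.5-weight
counting without touching the sequence (its coordinates are mapped through
any removals). Edits may not overlap one another.

### Dinucleotide null

The null expectation for positional TT frequencies is the genome's
forward-strand TT frequency over overlapping windows: denominator L−1 for
linear genomes, L for circular ones (one wraparound window; an O(1/L)
effect included for consistent circular semantics). Windows containing N
are excluded from numerator and denominator. Counting a single strand
matches the magnitude of published null values for AT-rich organellar
genomes; both-strand counting is not exposed as an option. Per-region
counts assign each window to the category of its first base, which makes
per-category counts an exact partition of the genome-wide count.

### Positional profiles and the enrichment band

Pair position p (1-based, p ∈ 1..L−1) denotes the dinucleotide occupying
read positions (p, p+1) on the read's own 5′→3′ axis; fragment-oriented
sequences (reverse-complemented for − placements) are profiled. The
confidence band is the normal approximation the profile statistic calls
for — ci = 2·sqrt(p0(1−p0)/n) with n the (weighted) number of reads in
the length class — rather than an exact binomial interval; at the read
counts where profiles are meaningful (hundreds and above) the difference
is negligible. Classes below `min_reads` (default 100; profiles are only
interpretable for abundant length classes) are computed but flagged.
Cross-length comparison uses a shared right-aligned axis: position p of an
L-nt class maps to p + (L_max − L), and the peak's 3′ offset L − p is the
length-invariant coordinate.

### Region assignment and coverage

Reads are assigned to region categories by their midpoint (start +
length/2, wrapped on circular genomes), which makes per-category counts a
partition of per-genome counts — a testable conservation law. The midpoint
of an even-length read is not mirror-symmetric, so strand-complement
invariance holds exactly only for odd read lengths; for even lengths reads
straddling a boundary may flip assignment (a one-position effect).
Overlapping annotations resolve by fixed priority tRNA > rRNA > CDS >
intron > intergenic (the smallest, most specific feature wins).
Base-pair-overlap apportionment was considered and rejected as the default
because it breaks the partition property.

RPKM uses full (edited-reference) category lengths, not mappable lengths;
mappability is a separate report, so coverage and mappability are not
conflated. The RPKM denominator is the weighted total of all mapped,
filtered reads across all genomes of the assembly, making compartments of
one library directly comparable. Mappability itself is position-level:
the fraction of positions covered in the unfiltered alignment that remain
covered after filtering, which isolates the cost of the uniqueness filter
from sampling depth.

Strand comparisons label a fragment template-strand when its mapped
strand is opposite the feature strand at its midpoint (the template is the
strand the polymerase reads, complementary to the transcript). Counts are
normalized by the di-pyrimidine substrate on each strand within the
category — by default TT only, optionally all of {TT, TC, CT, CC} — since
substrate imbalance alone would inflate one strand's reads. Substrate
windows must lie fully inside the stranded category span: that rule keeps
the normalized ratio invariant under complementing the genome and flipping
all annotations and fragments.

## Synthetic data generator

The generator emulates what the analysis assumes about real libraries:

- **Genomes**: i.i.d. bases with P(A)=P(T)=AT/2; defaults used in tests
  and examples are AT ≈ 0.7 and a few kb length, circular — the AT
  richness and topology of small organellar genomes at a size where exact
  alignment is instant.
- **NUMT/NUPT analogues**: a copy of a donor segment inserted into a
  nuclear genome with per-base substitution probability `divergence_rate`,
  with the planted interval logged.
- **Fragments**: a strand is chosen uniformly, then a TT site uniformly on
  that strand; a length L is drawn from `length_weights`; the fragment is
  laid out so the dimer's 3′ base is among the last `dimer_offset_3p`
  bases — the TT pair occupies 1-based read positions (L − offset,
  L − offset + 1). Defaults (primary length 26 nt, offset 19, trim step
  2 nt) plant the pair at positions 7–8 of the primary class, shifting to
  5–6, 3–4, 1–2 after successive 5′ trims. Two mechanisms produce
  multi-length libraries: `fixed_incision` (several upstream incision
  distances) and `five_prime_trim` (stepwise 5′ degradation of a primary
  fragment); both give the same 3′-anchored geometry, which is exactly why
  they are distinguishable only by additional evidence — the generator
  exposes offset and step as free parameters rather than fixing one
  mechanism.
- **Reads**: emitted in fragment orientation (5′→3′ of the excised
  strand) with a single literal 3′ adapter suffix and constant Phred
  quality; no sequencing errors by default, so pipeline logic is tested
  in isolation from an error model.

Damage sites are restricted to TT — the dominant CPD context and the
dinucleotide the profile statistics key on; uniform site choice is the
simplest null the recovery tests need. The generator does **not** emulate
(6-4)PP-specific chemistry, antibody or ligation sequence biases, PCR
AT-bias, or sequencing errors; passing recovery tests therefore show the
pipeline's correctness on idealized libraries, not robustness to those
real-data artifacts.

Linear-genome placements that would run off an end are resampled (with a
resample counter); circular placements wrap modulo the genome length.

## Numerical and degenerate-input choices

- Frequencies are exact ratios of weighted counts; no smoothing.
- Mappability fractions and strand ratios are NaN when their denominator
  is empty (no unfiltered coverage; no substrate); a template-only strand
  count with nonzero substrate reports ∞ rather than NaN.
- `argmax` over profile positions breaks ties toward the smaller
  position.
- Multi-mapping reads report their first placement (sorted by genome,
  position, strand) so unfiltered coverage is well defined; unmapped
  reads carry no coordinates.
- Spectrum correlation requires ≥ 3 bins in the union; spectra can carry
  explicit zero bins over a configured length range so samples share a
  common axis.

## Problem sizes

Tests and the acceptance script use genomes of 3–8 kb and libraries of
10³–10⁴ reads; at these sizes every stage is exact (no heuristics, no
subsampling) and the planted-geometry, spectrum, mappability and coverage
recoveries are all well inside their sampling tolerances. Two checks
compare the forward-strand TT frequency of the real NC_001224.1 and
NC_037304.1 sequences to their published values; the sequences are small
public downloads and are not distributed with the package.

## Known limitations

- The internal aligner is exact-match only; mismatch-tolerant alignment
  must come through SAM/BAM import.
- Uniqueness from the internal aligner and from MAPQ thresholds are
  different estimators; imported alignments inherit the upstream
  aligner's notion.
- Even-length midpoint assignment is asymmetric by one position at
  boundaries (see above).
- The generator's truth is TT-only; enrichment of TC/CT/CC can be
  profiled but not planted.
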