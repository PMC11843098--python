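# Methods

This note documents the models, rules and numerical choices behind t2tkit,
what the synthetic-data generator does and does not emulate, and the design
decisions taken where the procedure was genuinely open.

## Coordinates and sequence model

All intervals are 0-based half-open, so `length == end − start`
everywhere, including the published centromere table this convention was
checked against. Sequences are uppercased on read and restricted to
{A, C, G, T, N}; soft-masking carries no information for any procedure here
and is discarded. N never matches a motif or a k-mer (k-mer windows
containing N are invalid).

## Read and contig filters

The filters implement threshold wording literally:

* ONT ultra-long: keep reads with length ≥ 30 000 and mean Q **strictly**
  above 9 ("above 9"). A pre-stage (length ≥ 10 000, mean Q ≥ 7) mirrors
  the adapter-trimming step; at the defaults it is subsumed by the main
  thresholds, but both stages are independently configurable because the
  original two-stage procedure leaves the first stage's Q handling open.
* HiFi: keep reads with ≥ 3 passes ("fewer than 3" removed) and
  SNR ≥ 2.5 ("below 2.5" removed) — both boundaries inclusive.
* Organelle contamination: a contig is excluded iff the **union** of its
  organelle-aligned intervals covers strictly more than 50 % of its
  length. Unioning matters: two overlapping alignments must not be summed.

Filters raise when the metadata they need is absent; silently passing an
unfiltered read would corrupt downstream counts.

## Telomeres

Telomere evidence is the count of non-overlapping exact motif copies
(TTTAGGG forward / CCCTAAA reverse; configurable pair constrained to be
reverse complements). Greedy non-overlapping counting is exact for a 7-bp
tandem motif, where overlap is impossible. Chromosome calls scan a
20-kb terminal window (the same scale as the 20-kb patch-distance rule):
the 5′ window with the C-rich motif, the 3′ window with the G-rich motif;
a call is "present" at ≥ 10 copies. The calling threshold is far below the
smallest published per-end count (158) and far above the chance expectation
in 20 kb of random sequence (≈ 1.2 copies), so the decision is insensitive
to its exact value; it is configurable regardless. Counts are measured on
the genome sequence (not on consensus reads), and a window count can exceed
the planted array size by the few chance copies in flanking sequence.

Terminal patching follows the published rule exactly: a consensus may
replace a terminus only if alignment identity ≥ 0.80 and the alignment's
near-terminus boundary is within 20 kb of the chromosome end; rejections
carry a reason (`low_identity`, `too_far`, `no_alignment`). Consensus
location uses terminal probes of the chromosome infix-aligned within the
consensus (the consensus normally extends past the assembled end, making
this an overlap alignment). The bundled consensus caller is a deliberately
simple per-position majority vote over pairwise alignments — plumbing that
stands in for a polishing workflow, not a reimplementation of one. Votes
are derived from the same refined alignment model as variant calling (see
below) so that substitution-rich reads are never misread as indel pairs.

## Centromeres

Candidate calling uses two windowed covered-fraction tracks: tandem-repeat
(TRF) coverage and gene coverage. The window defaults to 10 kb — the scale
at which the density contrast is meaningful — with the window fully
configurable. Windows with TRF ≥ 0.5 and gene ≤ 0.05 are selected, runs
separated by ≤ 5 windows are merged, runs shorter than 100 kb are dropped,
and the longest survivor per chromosome is the single candidate (the
toolkit deliberately reports at most one per chromosome; secondary runs
are simply not reported). The two density thresholds are not published
values; they are the package's own defaults, chosen as a clear separation
between satellite arrays (near-1 coverage) and gene-bearing arms, and are
exposed in the API and CLI.

The built-in tandem-array finder reports maximal intervals where
`seq[i] == seq[i+p]` for some period p in [2, 500], with run length
≥ 1 kb. With mismatch tolerance enabled, the per-position match indicator
is smoothed over a 100-bp window and positions with local match fraction
≥ 0.9 count as periodic — this absorbs the few percent of monomer
divergence real satellites show. External TRF/BED intervals bypass
detection entirely. Hi-C evidence is out of scope: no algorithmic rule for
it exists, and candidates remain predictions pending experimental
validation.

## Gaps

Gaps are maximal N-runs; scaffold joins insert exactly 100 N between
contigs, so joining then re-scanning returns `n_contigs − 1` gaps of 100.
Fill candidates must span the gap: both 1-kb flank anchors (exact-match
windows immediately bordering the N-run; anchor width configurable) must
occur, in order, in the candidate. Ranking is source priority
(error-corrected genome > HiFi > ONT), then aligned span, then identity,
then id — a total deterministic order. When a candidate implies a filled
length different from the N-run (gap sizes are placeholders, not
measurements), the candidate wins and the delta is recorded. No identity
floor is enforced beyond ranking (configurable, default 0), since the
source hierarchy already encodes trust.

## k-mer QV

QV uses the standard k-mer-spectrum estimator: assembly k-mers are counted
per position (a multiset; N-containing windows excluded), read k-mers form
a presence set (optional minimum count ≥ 1 to absorb read errors), and all
k-mers are canonical (min of forward and reverse-complement encoding) so
read strand is irrelevant. With missing fraction *b*,
*e* = 1 − (1 − *b*)^(1/k) and QV = −10 log₁₀ *e*, capped at 99 when
*b* = 0 so serialization never meets infinity. Defaults k = 21,
min_count = 1; both configurable since the published evaluation does not
state them. A single interior substitution in otherwise unique sequence
removes exactly k position-k-mers, which the tests use as a closed-form
check alongside an explicit set-difference oracle.

## Two-assembly comparison

The aligner is a desk-scale anchor chainer, not a general-purpose
whole-genome aligner: it assumes genomes of at most ~100 Mb combined and
accepts external PAF/TSV blocks for anything larger.

1. **Anchors.** Canonical 21-mers unique in both assemblies. A secondary
   pass takes k-mers unique in one assembly but with 2–4 copies in the
   other: duplicated sequence has no mutually-unique k-mers, so without
   this pass duplications would be invisible. When primary anchors are
   dense (> 500 k) they are thinned 8-fold; anchor deserts created by real
   events are orders of magnitude wider than the thinned spacing, so
   breakpoints are unaffected.
2. **Chains.** Anchors grouped by (ref chromosome, qry chromosome, strand)
   are split where the ref gap exceeds 1 kb, the diagonal jumps by more
   than 100 bp (beyond the 50-bp indel class), or colinearity breaks.
   An inversion preserves the diagonal, so the 1-kb gap limit is what
   separates it from its forward context — inversions below ~1 kb merge
   into the flanking block and are instead expressed as in-block
   differences. Secondary (duplication) anchors are chained per exact
   diagonal because one reference position now has several query partners.
3. **Bridging.** Satellite arrays, telomere arrays and N-runs have no
   unique k-mers and would otherwise surface as fake presence/absence
   calls. Neighbouring forward blocks on the same diagonal (ref and qry
   gap lengths within max(100 bp, 2 %)) are merged after verifying the
   intervening segments align at ≥ 0.8 identity; the outermost blocks are
   extended to the chromosome termini under the same test. Inverted or
   length-discordant interruptions fail the identity or length test and
   correctly remain breakpoints.
4. **Small variants.** Within forward blocks (cut at anchor positions into
   ≤ 500-kb chunks — anchors are exact matches, so cutting there cannot
   change the alignment), edlib provides the base-level alignment. Because
   unit-cost alignments may legally split one indel into equal-cost pieces
   separated by chance single-base matches, clusters of events within
   30 bp are locally realigned with affine gap scoring (match 1, mismatch
   −2, gap open −4, extend −0.5): the gap-open penalty makes the
   contiguous representation strictly optimal, and mismatches are never
   expressed as insertion/deletion pairs. Indels are then left-aligned
   against the reference. The 2–50 bp class is the reported indel range;
   1-bp events are tallied separately and > 50 bp events fall to the
   SV/PAV logic.
5. **SVs.** Per reference chromosome, the dominant query partner and a
   maximum-weight colinear backbone (weighted longest increasing
   subsequence over query position) are computed from unique forward
   blocks. Reverse-strand blocks on the dominant partner → inversions;
   off-backbone or off-partner blocks → translocations; reference regions
   covered by ≥ 2 non-unique blocks with disjoint query loci →
   duplications. SV length is the reference-interval length, binned as
   50–1000, 1001–2000, …, 8001–9000, > 9000.
6. **PAV.** Maximal regions of either assembly uncovered by any block and
   ≥ 50 bp (N-runs subtracted) are presence (query-only) or absence
   (reference-only) variants. `pav_min` = 50 matches the SV minimum; both
   configurable.
7. **Context.** Records are labelled at their reference midpoint with
   precedence exon > intron > upstream2k > downstream2k > intergenic,
   flanks resolved by gene strand. For two-way summaries, "gene region"
   means exon or intron; everything else counts as intergenic.

All variant coordinates are reported against the reference-role assembly.
Syntenic bases are reported per assembly separately (union of block
intervals on each side); a single syntenic percentage is deliberately not
printed because its denominator is ambiguous between two assemblies of
different sizes.

## Synthetic data generator

Each simulated chromosome is: 5′ telomere array (CCCTAAA copies) — arm —
centromeric satellite — arm — 3′ telomere array (TTTAGGG copies). Defaults
emulate the architecture the toolkit targets at desk scale: 4 chromosomes
× 2 Mb; per-end telomere copy counts drawn uniformly from 158–612 (the
published per-end range), with any subset of ends droppable to reproduce
incomplete-telomere patterns; a 171-bp random monomer tandem-repeated to
200 kb at 45 % of the chromosome with 1 % monomer divergence (171 bp is
the canonical plant centromeric monomer scale; 1 % divergence keeps
detection honest without defeating it); ~100 genes/Mb in the arms (the
gene density of a ~28 k-gene, ~266-Mb genome) with 5 exons per gene;
Gypsy-enriched LTR fragments inside the centromere (30 % target coverage
vs 3 % outside) and uniform Copia; optional N-runs. The derived assembly
applies, in recorded non-overlapping positions: SNPs at 6·10⁻⁵/bp and
2–50 bp indels at 2.5·10⁻⁵/bp (≈ 500 SNPs and 200 indels per 8-Mb
genome — sparse enough for unique anchoring, the regime the comparison
module is specified for), two inversions (5 kb, 3 kb), one 20-kb
inter-chromosomal translocation, two tandem duplications (3 kb, 1.5 kb),
and four presence/absence segments (0.8–3 kb).

Placement keeps edits out of telomere arrays, the satellite, N-runs and
the outer 5 kb of each chromosome, and enforces a 150-bp (small variants)
or 400-bp (SVs/PAVs) spacing buffer. The buffers are what make "recall =
precision = 1" a well-posed claim: they guarantee each event is flanked by
unambiguously alignable sequence. Truth indels are left-normalized with
the same routine used by the caller, so positional comparison is exact by
construction rather than by luck.

Randomness: each operation (genome build, mutation, read simulation) draws
from its own stream keyed by (seed, operation), so adding one stage never
perturbs another's output; fixed seeds give byte-identical FASTA. Reads
are substitution-error only, with recorded provenance; homopolymer bias,
quality strings and chimeras are not modelled. Consequently, passing tests
demonstrate correctness of the algorithms under clean, planted conditions —
they do not certify performance on real ONT/HiFi error profiles, diverged
satellite families, or polyploid genomes.

## Problem sizes and determinism

The test suite and the acceptance script run the full comparison pipeline
on twenty 4 × 2 Mb genome pairs, centromere recovery on one 8 × 2 Mb
genome, and oracle checks on hundreds of small random fixtures; these
sizes were chosen so the complete battery demonstrates every claim while
remaining a routine desk run. Brute-force oracles (per-position N scan,
per-base coverage union, per-base context annotation, explicit k-mer set
difference, regex motif counts) are implemented independently in the test
suite and never share code with the paths they check.

## Known limitations

* The anchor aligner requires low variant density and unique sequence
  flanks; it is not a substitute for minimap2/nucmer on real, repeat-rich
  genomes, and inversions under ~1 kb are not separated from their
  context.
* Duplication calling counts disjoint partner loci; nested or highly
  diverged duplications collapse into single clusters.
* The consensus caller ignores insertions relative to the reference read
  and is substitution-oriented; it is not a polisher.
* Centromere candidates are density predictions; experimental validation
  (FISH/ChIP) is explicitly out of scope.
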