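# Methods

## The protocol being modeled

`synthlr` reconstructs long DNA molecules ("synthetic long reads") from
barcoded Illumina-style short reads produced by a circularization library
protocol. The wet-lab steps the simulator emulates are:

1. Target fragments (up to ~20 kb; here lognormal around 8 kb by default)
   are ligated at each end to adapters carrying a degenerate barcode, so
   every molecule is tagged by two unique barcodes.
2. PCR makes many copies of each tagged fragment. Substitution errors accrue
   per copy; transitions (A↔G, C↔T) dominate.
3. Each copy receives a Poisson(λ) number of enzymatic breaks.
   Intramolecular circularization joins a newly exposed internal end to the
   barcode at the opposite end of its piece, and only barcode-bearing
   junction molecules amplify in the subsequent limited-cycle PCR. A copy
   with no break yields no junction; unbroken circles instead feed a
   supplemental product in which the molecule's two barcodes flank a
   constant spacer (the "pairing read"), spiked into the library at a few
   percent.
4. Sequencing yields paired 150-bp reads whose forward mate begins with the
   barcode (optionally followed by a 6-bp multiplexing index), a short
   constant anchor, and then fragment sequence running from the break
   toward the barcoded end.

Because junction positions are the minimum (left side) or maximum (right
side) of the break positions on each copy, read coverage decays with
distance from the barcoded end, and the two barcode groups of one molecule
cover complementary ends — merging them both raises and evens coverage.

## Simulator model and defaults

| parameter | default | meaning |
|---|---|---|
| `n_molecules` | 200 | target fragments drawn from the reference |
| reference | 1 Mb random, GC 0.5 | or any FASTA |
| fragment length | lognormal(8000, 1000) bp, truncated [6000, 10000] | shearing-length model |
| `barcode_length` | 18 nt | 4^18 makes accidental collisions negligible; collisions are resampled |
| `copies_per_molecule` | Poisson mean 300 | PCR yield per molecule |
| `break_lambda` | 1.0 | mean breaks per copy; zero-break copies become pairing-read sources |
| `pcr_sub_rate` | 2e-4 /base/copy | substitutions, applied independently per copy |
| `transition_fraction` | 0.756 | share of PCR substitutions that are transitions |
| `seq_sub_rate` | 1e-3 /base | sequencing substitutions, applied to the whole read including the barcode |
| insert length | normal(500, 50) bp, floor 2R−50 | clipped at the barcoded piece end, never wrapped |
| `pairing_read_fraction` | 0.03 | pairing reads as a share of all read records |
| qualities | two-level: Q37 body, Q2 tails on 5% of reads | just enough structure to exercise trimming |

Randomness flows from one seed through named per-molecule substreams
(`default_rng([seed, stream, molecule])`), so per-molecule output is stable
under reordering and the whole library is byte-reproducible.

What the generator deliberately does not model: GC-dependent PCR dropout
(none was detectable in the protocol's data), indel sequencing errors
(substitutions dominate this chemistry), fragmentase sequence bias, error
genealogy across the PCR tree (per-copy errors are independent), and
adapter read-through (the reverse read is clipped at the adapter prefix).
Passing tests therefore demonstrate correctness of the algorithms under
this idealized but protocol-shaped error structure, not robustness to
real-library artifacts such as chimeric PCR products or adapter
contamination.

## Pipeline stages and the choices inside them

**Quality trimming** scans non-overlapping 4-base windows from the 3' end
and cuts after the first window whose mean quality reaches Q20; reads
shorter than 30 payload bases are dropped. Only the 3' end is trimmed — the
barcode occupies the 5' end and is removed by extraction, not trimming.

**Pair merging** reverse-complements the reverse mate and scores every
overlap of at least 10 bases, accepting the overlap with the lowest
mismatch fraction (ties to the longer overlap) when that fraction is at
most 0.25. Overlap conflicts resolve toward the higher base quality, ties
toward the forward read.

**Barcode extraction** takes the first B bases (rejecting any N), matches
the optional 6-bp multiplexing index against the sample table with at most
one mismatch under a unique-best rule (standard Illumina demultiplexing
practice), and verifies the anchor with at most one mismatch. Rejections
are values with enumerated reasons, not exceptions.

**Grouping** is by exact barcode text — O(n), with error tolerance handled
afterwards. Groups with fewer than 50 read pairs are dropped. Spurious
barcodes created by sequencing errors in the barcode region are collapsed
greedily: barcodes are visited in decreasing order of associated length
(group size before assembly, synthetic-read length after), and a barcode is
kept only if no already-kept barcode lies within Hamming distance 2. The
greedy longest-first order makes the rule deterministic and handles chains.

**Barcode pairing** parses pairing reads (two barcodes around a constant
20-bp spacer, at most 2 spacer mismatches), accumulates a symmetric
co-occurrence graph, and resolves disjoint pairs with a strict mutual-best
rule at a minimum count of 2: an edge is accepted only if each endpoint is
the other's unique top-count neighbor. One erroneous pairing read can
therefore never fuse two molecules; rare ties are left unpaired rather than
guessed. Barcodes whose top two counts are within a factor of two are
reported as possible collisions.

**Per-group assembly** uses a single-k bidirected de Bruijn graph over
canonical 31-mers. k-mers seen fewer than 2 times are discarded (a lone
sequencing error produces count-1 k-mers at default coverage); dead-end
unitigs of at most 2k bases hanging off a junction are clipped; simple
parallel bubbles of at most 2k+10 bases are popped keeping the
higher-coverage path. Maximal unbranched paths become contigs, reported in
canonical orientation (lexicographic minimum of the two strands) and sorted
by length — assembly output is invariant to read order and worker count.
Contigs of at least 1 kb become synthetic reads; all are reported (a group
may legitimately yield more than one), with the longest flagged primary.
Groups of 10²–10⁴ short reads over ≤ 20 kb do not need multi-k iteration or
repeat resolution, so none is attempted; an external-assembler seam
(`AssemblyParams.external_assembler`, a command template mapping group
FASTQ to contig FASTA) exists for parity experiments with full assemblers.

**Truth alignment** is a banded global alignment with free end gaps on both
sequences (match +1, mismatch −4, gap open −6, extend −1; a gap of length g
costs 6+g), seeded on the modal diagonal of shared 31-mers and run against
both strands; absence of any shared 31-mer is reported as unalignable.
Mismatch rates are mismatches over aligned (match+mismatch) columns;
clipped query ends are excluded from the denominator and reported
separately. Positional profiles bin each aligned query position p of a
read of length L into floor(100·p/L).

**Mixture classification** aligns each synthetic read to two known parent
sequences with an affine-gap Smith–Waterman (match +1, mismatch −1, gap
open −10, extend −0.5, water-like) and computes 1 − identity over the
aligned span. The lower-rate parent is called only if its rate is at most
0.01 and the margin to the other parent is at least 0.01; everything else
is ambiguous — the signature expected of chimeras. These two thresholds are
this package's choice (the outcome, not the rule, is what the protocol's
analyses report) and are exposed as flags. For two long sequences the DP is
banded around the shared-k-mer diagonal (seed k = 21, falling back to k = 11,
then to full DP); the comparisons made here are near-collinear, where the
band is exact. Read strand is fixed once per read by shared-k-mer support
against both parents.

**Phasing** counts exact occurrences of short probe sequences (and their
reverse complements) in each group's unassembled reads and fits ordinary
least squares between probe pairs; R² is reported as undefined when the
response is constant. No mismatch tolerance is applied — probes are chosen
unique, and tolerance would require an error model the protocol does not
supply.

**N50** is defined over synthetic reads of at least `min_len` (default
1000) bases: the first length at which the descending cumulative sum
reaches half the total. "Longer than 1 kb" is implemented inclusively as
≥ 1000 to keep one convention at the boundary.

## Numerical notes

* Alignment DP runs in float32; every score used (+1, −1, −4, −6, −0.5, −1)
  is exactly representable, so the value-based traceback is exact.
* k-mers are 2-bit packed into one 64-bit word for k ≤ 31 (the default);
  larger odd k up to 63 fall back to arbitrary-precision integers.
* Ties are broken deterministically everywhere: lexicographically smaller
  barcode/sequence first, longer overlap first, higher coverage first.
* Degenerate inputs (empty groups, reads shorter than k, constant
  regression response, zero-length input to N50) return empty/zero/flagged
  values rather than raising.

## Problem sizes used in tests and the acceptance script

The accuracy experiment simulates 200 molecules of ~8 kb from a 1 Mb random
reference (≈75,000 read pairs) and aligns all synthetic reads ≥ 1.5 kb back
to their truth fragments. The mixture experiment simulates 600 molecules
from each of two 3-kb parents at 5% divergence (≈450,000 read pairs) and
classifies every cleaned synthetic read of 1.5–3.2 kb. Coverage-evenness
properties are evaluated on the first 40–60 molecules of the default
library, which is ample for proportions asserted at the 90–95% level.

## Known limitations

* With the default count-2 k-mer filter the assembler is more conservative
  than a full multi-k assembler: consensus errors require two reads to
  carry the same substitution at the same position, so realized mismatch
  rates on simulated libraries are far below the rates reported for real
  libraries, and positional error structure (end-enrichment of errors) is
  largely suppressed along with the errors themselves.
* The strict mutual-best pairing rule trades recall for precision: barcodes
  with genuinely ambiguous pairing evidence stay unpaired.
* Coverage placement in QC uses infix edit-distance alignment (edlib) and
  counts a read at its best placement only; reads spanning true repeats
  would be placed arbitrarily among equally good locations.
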