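# Methods

## The detection problem

In a stranded small-RNA library, a genuine Dicer-processed miRNA locus
leaves two signatures that no other small-RNA class reproduces together:
(i) a partner strand that base-pairs with it in an antiparallel duplex with
2-nt single-stranded 3′ overhangs at both ends, and (ii) strong abundance
asymmetry between the guide and star strands. dinomir operationalizes only
the structural criterion for detection and reports the abundance asymmetry
as supporting evidence, deliberately avoiding precursor-hairpin folding,
free-energy scoring and homology databases, which cannot be applied when a
lineage's miRNA pathway itself is in doubt.

All internal sequence space is DNA (input U normalized to T, everything
upper-cased), coordinates are 0-based half-open, and the alphabet is
{A,C,G,T,N} with N pairing to nothing.

## Duplex geometry test

For strands *a* and *b* the pairing regions are `a[:-2]` and `b[:-2]`: the
two 3′-terminal bases of each strand are the overhangs, unpaired by
definition and unconstrained in sequence. The pairing regions must align
globally — no terminal gaps, so the overhang length is exactly 2 on both
ends — under these rules:

* a position pairs iff it is Watson–Crick (A:T or G:C); G:T wobble and any
  position involving N count as mismatches;
* at most 3 mismatches;
* at most 1 single-base bulge, modelled as one internal gap in the shorter
  pairing region (equivalently one unpaired base on the longer strand);
  bulges at the first or last alignment column are disallowed because they
  would change an overhang length. Consequently the two strands may differ
  in length by at most 1 nt.

When both a bulged and (for equal lengths) an ungapped placement are
impossible to confuse — equal lengths admit only the ungapped alignment,
unequal lengths only bulged ones — the reported alignment is the
minimum-mismatch one, ties broken by the leftmost bulge column. Computing
this exactly costs O(L²) per pair in the worst case and L ≤ 24, so the
all-pairs search over a candidate set partitioned into length classes
(each class compared with itself and its +1 neighbour) is exact rather than
heuristic; correctness is preferred over speed at these problem sizes, and
the unit tests hold the search to equality with an independent brute-force
enumeration of every pair and every gap placement.

One consequence worth stating: a poly(A) strand and a poly(T) strand form a
perfect A:T duplex under these rules. Low-complexity pairs of this kind are
legitimate geometric hits; filtering them is a judgement about biology, not
geometry, and is left to the caller.

## Cleaning cascade

Stage order is fixed: adapter trimming, rRNA subtraction, tRNA subtraction,
poly(A) removal, size selection, a second rRNA/tRNA pass, organelle
subtraction. Choices that needed making:

* **Adapter trimming** removes the leftmost full internal occurrence of the
  3′ adapter, falling back to the longest adapter prefix (≥ 3 nt) anchored
  at the read's 3′ end; a read reduced to nothing is discarded. The default
  adapter is the TruSeq small-RNA 3′ adapter (`TGGAATTCTCGGGTGCCAAGG`),
  exposed as a required-style config value since library preps differ.
* **Poly(A) removal** drops a read containing any run of more than
  `polya_max_run` (default 6) consecutive A anywhere in the read, not only
  a 3′ tail — degradation products carry internal runs too.
* **Reference subtraction** declares a read contaminant if it occurs as a
  contiguous substring of any reference entry on either strand with at most
  `subtraction_max_mismatches` (default 0, configurable to approximate a
  lenient aligner) mismatches and no gaps. For ≤ 26-nt reads exact
  substring search is both faster and more reproducible than a heuristic
  external aligner. Per-sequence results are memoized because libraries are
  highly redundant.
* **The second rRNA/tRNA pass** re-runs subtraction after trimming and size
  selection, which can expose matches hidden by adapter sequence.
* **Percent accounting** is round-half-up to one decimal
  (`Decimal`-based, so 5.25% prints 5.3), matching how such cascade tables
  are conventionally printed; the initial row prints `100`.

Reads with N survive cleaning but cannot match references at a zero
mismatch budget.

## Collapsing and the minimum-copy filter

Collapsing is strand-literal (the library is directional, so a sequence and
its reverse complement are different species) and orders unique sequences
by descending count, ties lexicographic; ids follow the fastx-collapser
dialect `seq{rank}_x{count}`. The abundance filter removes species with
fewer than 5 copies (count ≥ 5 kept — the boundary is tested explicitly):
a duplex call built on singletons is indistinguishable from sequencing
noise.

## Contig filter

Assembly is greedy agglomeration on exact overlaps: repeatedly merge the
pair of units (reads or growing contigs) with the longest exact
suffix–prefix overlap or containment of length ≥ 14, considering both
orientations of one partner; ties are broken by the lexicographically
smallest merged sequence, making assembly deterministic. Only 100%-identity
overlaps merge — the filter exists to catch reads that tile a common
source, and near-matches would blur exactly the distinction it draws.

A contig is flagged when its length strictly exceeds the threshold
(default: the median multi-member contig length, overridable with an
integer since the appropriate value is a property of the library) *and*
all member reads share one orientation. Member reads of flagged contigs
are removed; singletons and members of bidirectional or short contigs are
retained. Singleton contigs are trivially unidirectional but are never
removed: they carry no length evidence beyond the read itself, and removing
them would empty the candidate pool. Note that a guide/star pair itself
assembles — the star contains the reverse complement of the guide's pairing
region — into a short *bidirectional* 2-member contig, which the filter
correctly retains; this is the structural reason the filter separates
degradation fragments from duplex-forming small RNAs rather than merely
shrinking the dataset.

## Transcript profiling

Mapping is exact contiguous substring matching on both strands (default;
configurable up to a small mismatch budget), reporting every occurrence.
Totals weight each collapsed species by its copy count by default
(unweighted mode counts species). Pattern classes: A requires literally
zero antisense reads; C requires an antisense fraction strictly above 20%;
B is everything between. The PFM aligns near-identical sequences gaplessly
by anchoring on their longest common substring; a full MSA buys nothing for
reads that differ by a handful of substitutions and ragged ends, and the
anchored consensus (majority base, ties alphabetical) is what a sequence
logo of such a set displays.

## Synthetic study conditions

The generator's defaults define the conditions every recovery test runs
under: 20 duplex loci, guide:star = 50:1 with 5 star reads per locus (the
star must survive the ≥ 5-copy filter for the pair to be observable at
all), 5000 transcript-tiling fragments (1000 per bundled transcript, tiled
every 4 nt so adjacent fragments overlap by ≥ 14 nt and assemble into long
unidirectional contigs), 20% contaminants split 8/5/4/3 percent among
rRNA/tRNA/organelle/poly(A) with largest-remainder rounding, locus lengths
drawn with a majority (40/70) at 22 nt and the remainder falling off toward
18 and 26, and a per-base star mutation rate of 0 (mutation-free duplexes;
the rate is configurable and capped at 3 mismatches so planted pairs always
remain valid).

Planted loci are rejection-sampled so that neither strand carries a >6-nt
A run or shares any 14-mer with the references, the transcripts or other
loci; without this a chance exact overlap would entangle a locus with the
contig filter, which is not the condition being emulated. The bundled
reference fixture (3 rRNA, 3 tRNA, 2 organelle entries; 5 transcripts, one
LBP-like with a declared 3′ UTR at offset 400) is synthetic sequence
generated once under the same constraints, shipped as plain FASTA so all
tests run offline.

What the generator does *not* emulate — sequencing errors, quality decay,
ligation bias, expression-level dispersion beyond the fixed guide/star
ratio, partial adapter truncation — bounds what passing recovery tests
show: they demonstrate that each pipeline stage removes exactly the class
it targets and that the duplex search is complete and sound under its
stated geometry, not that the pipeline is robust to platform noise.

## Problem sizes and numerics

Recovery runs use a ~12,600-read library (560 unique species after
cleaning), which exercises every stage while keeping the full pipeline
around five seconds; oracle-equivalence checks use 200 candidate sequences
against O(n²) brute force, and geometry invariants are sampled over 10,000
random pairs. All randomness flows from explicit seeds through
`numpy.random.default_rng`; the analysis stages themselves are fully
deterministic, including assembly tie-breaks. Degenerate inputs are
defined rather than accidental: an empty library yields a report of zeros
(percent 0.0), an empty candidate set yields no pairs, a profile with no
mapped reads refuses pattern classification, and recovery metrics on an
empty manifest are flagged undefined.

## Known limitations

* Greedy longest-overlap-first assembly is not guaranteed to find a
  globally optimal contig partition; for tiling fragments (the case the
  filter exists for) it converges to the full source interval, but unusual
  overlap structures could fragment differently under a different merge
  order.
* The subtraction and mapping steps are substring-exact by default; a
  contaminant diverged by indels from its reference entry will not be
  caught.
* Whether the contig-length threshold should be the median of contig or of
  read lengths is ambiguous in general; the median of multi-member contig
  lengths is the default, with an integer override.
* The duplex test scores G:T wobble as a mismatch (DNA-space convention).
  An RNA-thermodynamics reading would admit wobble pairs and find strictly
  more duplexes.
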