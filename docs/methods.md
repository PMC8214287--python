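# Methods

## Problem setting

Structural variants (SVs) — deletions, insertions, inversions, duplications
and translocations of ≥ 50 bp — are detected from long reads mainly through
split alignments: a read spanning a breakpoint is divided into a primary and
one or more supplementary records. Aligners differ sharply here. Fast
minimizer-chaining aligners map whole runs quickly but split conservatively
(and sometimes wrongly, notably across translocations); convex-gap aligners
split far more informatively but cost roughly an order of magnitude more
CPU. Only a small fraction of reads (well under 1%) end up split by the
sensitive aligner, so re-aligning everything wastes almost all of that cost.
This package's premise is that those reads are predictable from the fast
aligner's own output: an unsplit read that *should* have been split aligns
noisily, with long soft clips, long indel runs and clustered edits.

## Feature extraction

Each read is summarized by a 21-slot vector, frozen as schema `svfeat-1`,
computed from the primary alignment record only (supplementary and
secondary records inform split detection, not the vector):

| group | features |
|---|---|
| aligner tags | s1, s2, cm, NM, AS (missing tags → 0; NM falls back to ins+del+mismatch) |
| edit totals | inserted, deleted, mismatched bases |
| edit runs | longest run of each kind; same with one matched base allowed inside |
| clipping | left and right soft-clip lengths |
| binned edits | four largest per-bin edit totals, 100 bp bins over read coordinates |
| size | read length |

Conventions that the SAM format leaves open:

- **Runs are measured in bases** (summed op lengths), not op counts, since
  base counts scale with the footprint of the variant.
- **The one-match-gap variant** joins two runs separated by *exactly one*
  matched base; the gap base contributes nothing to the run value. Joins
  chain, so `D M D M D` counts all three deletion runs.
- **Bins are over read coordinates** (soft clips included in the
  coordinate system). Inserted and mismatched bases are charged to the bin
  of their read offset; a deletion run consumes no read bases and is
  charged in full to the bin containing the offset where it occurs. Bin
  totals pool all three edit kinds into one number per bin; the four
  largest are reported in descending order, zero-padded.
- **Mismatch positions** prefer `=`/`X` CIGAR operations, then the MD tag.
  With neither, positional mismatch features (runs, bins) are zero and only
  the mismatch total is recovered as max(0, NM − ins − del). The pipeline's
  fast-aligner adapter therefore requests MD emission (`--MD`).

No feature depends on position or contig, so a classifier trained on reads
from one region cannot overfit to location.

## Classifier

The network is fixed at five fully connected tanh hidden layers of
18, 30, 18, 11 and 5 units with a single sigmoid output. Inputs are
z-scored with parameters stored in the model (tanh saturates on raw base
counts; constant features get sd 1). Training, which the architecture does
not constrain, uses:

- weighted binary cross-entropy with inverse-class-frequency weights —
  positives are on the order of 1% of reads, and unweighted training
  collapses to the majority class;
- mini-batch Adam (default lr 3e-3, batch 128, ≤ 400 epochs, weak L2);
- a stratified 10% validation split driving early stopping (patience 40);
- fan-in-scaled symmetric uniform initialization from a seed, so identical
  data and seed give bit-identical weights.

The decision threshold defaults to 0.5 and is *inclusive* (p = threshold
classifies as informative): a missed informative read costs SV sensitivity,
a false positive only costs re-alignment time. Models serialize to a
versioned JSON layout (`svpipe-mlp/1`: layer dims, row-major weights,
normalization vectors, threshold); loading refuses other formats.

Training labels derive from a paired run of both aligners: split by the
fast aligner → excluded (re-aligned unconditionally, nothing to learn);
split only by the accurate aligner → 1; split by neither → 0.

## Unification and SV post-processing

The two aligners emit different optional-tag vocabularies, which breaks
SAM→BAM conversion of a naively concatenated stream. Merging therefore
keeps only an allow-list (NM, AS, SA, MD) — the standard tags both SV
callers consume — drops everything else, and adds a lower-case provenance
tag (`so`). Headers must agree exactly on (name, length) for every contig;
@PG chains are concatenated. Duplicate representation of a read aligned by
both aligners is deliberately preserved: it is resolved downstream by
unique-support counting, not at merge time.

Call-level redundancy is handled in three steps:

1. **Unique support**: the number of *distinct* supporting read names (a
   read present twice in the merged BAM would otherwise count twice).
   Callers that report only a count fall back to that count.
2. **Minimum support**: ⌈coverage/2⌉ by default — at least half the average
   depth must support a call. The ceiling for odd coverages is the
   conservative choice against false positives.
3. **Cross-caller merge** (window 50 bp): two calls unify when type and
   chromosome(s) match and *both* breakpoint coordinates differ by strictly
   less than the window; requiring both ends prevents merging nested or
   overlapping distinct events. Pairing is greedy in descending unique
   support, each call participating at most once; the better-supported
   member survives, carrying the union of read names and both caller ids.
   Ties prefer named support over count-only, then the lexicographically
   smaller caller, then the smaller position — determinism over optimality.
   Greedy pairing mirrors common SV-merging practice; an optimal bipartite
   matching could differ on pathological clusters of near-window calls.

Evaluation against a truth set matches greedily (best-supported call
first, nearest truth record of identical type within a strict < 10 bp
breakpoint distance), one-to-one. FDR of an empty call set is defined
as 0.

Coordinates follow the VCF anchor convention end to end: `pos` is the last
unaffected base before the event, `end` the last affected base, so
SVLEN = end − pos for deletions/inversions/duplications and htslib's
END = POS + SVLEN arithmetic is consistent with the records written.

## Synthetic data

The generator emulates every external product the pipeline consumes, at
desk scale (10^5-bp contigs, SVs of 60–2000 bp, coverages around 10×)
rather than the chromosome-scale, up-to-50-kbp setting the design targets;
the statistical structure is the same but runtimes are seconds, and all
generators are pure functions of their seeds.

- **References and SV injection.** I.i.d. sequences with a requested GC
  fraction; non-overlapping DEL/INS/INV/DUP placements with a minimum gap
  and end margins, plus reciprocal tail-swap translocations (one per contig
  pair — composing multiple swaps on one contig would make original-
  coordinate truth ambiguous). Truth records carry exact original-reference
  breakpoints and, for insertions, the inserted sequence, so applying the
  truth VCF to the original reference reconstructs the altered genome
  byte-exactly — a property the tests assert through the VCF round trip.
- **Reads.** Uniform starts, truncated-normal lengths, random strands,
  i.i.d. substitution/insertion/deletion errors at PacBio-like rates
  (defaults total 13%), read names encoding the true origin interval.
  Not modeled: quality-score structure, homopolymer bias, chimeras.
- **Alignment records.** Background reads get modest clips (< 120 bp
  total) and scattered small edits; informative reads (default 1%,
  Bernoulli) get a large one-sided soft clip (> 200 bp total), a long
  deletion run (> 40 bp), or both, so the stated generative rule holds
  exactly and labels are known by construction. CIGAR, MD, NM and read
  length are mutually consistent; s1/s2/cm/AS are plausible but synthetic.
  A configurable fraction of reads gets an SA tag plus supplementary
  record to emulate fast-aligner splits.
- **Caller VCF pairs.** Truth plus per-caller breakpoint jitter (pos and
  end shifted together), dropout, and supporting-read names drawn from a
  shared pool. The expected post-merge set is computed analytically from
  the construction, giving the merge stage an independent oracle.

What passing on this data does *not* show: robustness to real error
profiles, to aligner-specific clipping behavior, or to caller scoring
quirks — the generator's labels are clean by design, so classifier metrics
here are upper bounds on real-data performance.

## Pipeline orchestration

The six stages run under a working directory with stable output names;
existing stage outputs are reused unless `--force` (the accurate-alignment
stage is the bottleneck the whole design exists to minimize, so reruns
should not repeat it). External tools are wrapped in adapters with pinned
default argument templates (the fast aligner is asked for SAM + MD tags,
the callers for supporting read names); a missing binary raises a
capability error naming the tool, and any stage's product can be supplied
directly instead — the bespoke-only mode in which the entire pipeline runs
on synthetic inputs with zero external dependencies.

## Numerical and degenerate-input choices

- CIGAR `*` yields an empty operation list; unmapped records produce
  all-zero positional features with a warning rather than an error.
- MD walking tolerates the zero-length match runs MD uses around
  deletions and mismatches; any other disagreement with the CIGAR is a
  format error.
- `H` and `P` operations are ignored for features; `N` resets runs and
  contributes no edits.
- Training requires both classes and finite features; constant features
  standardize with sd 1.
- Merge and match windows are strict inequalities (< 50 bp, < 10 bp), per
  their definitions.

## Known limitations

- The classifier is trained and validated on the synthetic generative rule;
  transferring to real aligner output requires retraining on labels from a
  paired aligner run (the `label_reads` path).
- Breakend-to-TRA collapsing assumes mate pairs describe one reciprocal
  event; complex multi-break events are out of scope.
- No genotyping or re-genotyping of merged calls; caller genotype fields
  pass through opaquely.
- Translocation simulation is limited to reciprocal tail swaps between
  distinct contig pairs.
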