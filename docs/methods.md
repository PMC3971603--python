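# Methods

This note records the models, parameter choices and numerical conventions
behind `otuasm`, and what the synthetic-data tests do and do not establish.

## Identity conventions

All percent identities are matches / alignment columns × 100.  For global
alignments every column counts (including terminal gaps); for semi-global
and local alignments the unaligned reference flanks are excluded.  Pairwise
nucleotide identity uses a Needleman-Wunsch alignment with match +1,
mismatch −1, linear gap −2; read mapping uses affine gaps (open −2,
extend −1) with the read end-to-end and free gaps on the OTU; protein
frame-scoring uses local BLOSUM62 with gap open −11, extend −1 (BLASTX-like
conventions).  Coordinates are 0-based, half-open throughout.

## Community generator

A community is built from one random coding ancestor (no frame-0 stop
codons).  Each member applies a dose of point substitutions (stop-avoiding);
the maximum-identity pair is constructed by third-position changes at
fourfold-degenerate codons only, so its peptides are identical by
construction; the minimum-identity pair applies two independent doses *a*
solving (1−a)² + a²/3 = min/100 (the a²/3 term is the chance two
independent substitutions coincide).  A calibration loop measures realized
global-alignment identities and adds or reverts substitutions until the
designated pairs sit within ±0.5 points of their targets; a repair loop
then nudges any other pair that drifted outside the envelope, re-pinning
the designated pairs after each repair.  The documented tolerance on the
envelope is ±1 point — sequence length is finite, so identity is discrete
in steps of 100/L.

Defaults state the validation world: n = 20 members of 552 nt, envelope
60–96%, one synonymous pair.  Abundances follow a geometric series
(ratio 0.9) — a generic "uneven community" stand-in, since no empirical
abundance vector is part of the stated world — with one structural fact
honoured: the synonymous pair sits at abundance ranks 9 and 11, i.e.
mid-range and similar, the regime in which a de Bruijn assembler is most
tempted to merge the two.

## Read simulator

Reads come from the 5′ end (forward primer + template prefix) or the 3′ end
(reverse primer + reverse-complemented suffix), mirroring bidirectional
amplicon sequencing of a ~550-bp target.  Read length is Normal(400, 40)
clipped to [50, template length]: 400 nt is typical of the long-read
pyrosequencing era this protocol emulates, and it makes a 5′ and a 3′ read
overlap by ~250 nt ≥ the 100-bp minimum overlap — the geometric
precondition for recovering full-length OTUs from end-anchored reads.  Primers (degenerate IUPAC
strings, resolved per read) are attached *before* errors, so primer bases
are error-prone too.  Substitutions are i.i.d. per base (default 0.5%);
indels exist but default to 0 (the assembler comparisons are cleaner
without them, and homopolymer-specific error models are out of scope).
Chimeras join a prefix of one member to the suffix of another at a uniform
breakpoint in [0.25L, 0.75L], guaranteeing both 150-bp screen ends fall on
different parents.  Per-member read counts are multinomial draws; every
read carries its source label.

## OLC assembler

The overlap model is ungapped (dovetail or containment placements), exact
for the substitution-only error model and matching the all-offset
comparison oracle used in tests.  Reads are processed longest-first;
candidate drafts are short-listed by shared 15-mers and every candidate
placement re-scored exactly; the joining objective is score =
overlap length × identity with deterministic tie-breaks.  Two tiers:
placements at ≥ 98% identity (`strong_join_identity`) join immediately;
weaker placements wait for a second pass in which unclaimed reads may seed
their own draft first.  This emulates a global greedy edge ordering
(highest-identity overlaps first) at linear cost and is what separates a
96%-identical template pair at a 90% overlap threshold.  A final merge
phase joins drafts only at the strong band — merging repairs fragmentation
of one template; relating *distinct* near-identical templates is the
mapper's job.  Consensus is a per-column weighted majority (Phred weights
when qualities exist), ties to the lexicographically smallest base;
consensus ends supported by fewer than two reads are trimmed, so a single
read with an untrimmed primer cannot extend a consensus beyond the
amplicon (which would otherwise corrupt the translated peptide).  OTUs are
emitted in canonical orientation (lexicographic minimum of the two
strands), which makes strand-closure exact: reverse-complementing every
input read reproduces byte-identical consensuses.

## DBG assembler

Canonical k-mers (lexicographic min of k-mer and reverse complement),
k ∈ [10, 31]; counts below `min_kmer_count` (default 2) are dropped, which
removes isolated sequencing-error k-mers at typical depths.  Maximal
unbranched paths are compacted with sorted-key traversal (deterministic);
tips shorter than 2k dangling off junctions are clipped; simple two-path
bubbles whose branches align at ≥ `bubble_pop_identity` (default 98%) are
popped keeping the higher-coverage branch.  A single contig equal to the
template is guaranteed only when the template's canonical (k−1)-mers are
unique and none is a reverse-complement palindrome — repeated (k−1)-mers
create junctions even when all k-mers are unique, and palindromic stems
(possible for even k−1) fold the bidirected graph onto itself.  The engine
deliberately does no read tracking: distilling reads into k-mers forfeits
it, which is exactly why the mapping module exists.

## Read mapping

Candidates are short-listed by shared 11-mers; for each candidate the
best diagonal (k-mer-voted) ungapped placement is evaluated first, and
accepted when its identity clears 97% (`gapless_accept`) — for
substitution-only divergence the ungapped placement is score-optimal, so
this fast path is exact there.  All sub-band cases fall through to the
affine semi-global dynamic program (Biopython's PairwiseAligner), with
near-tied scores re-ranked by exact identity.  Assignment is best-hit by
(identity, aligned length, lexicographic OTU id, '+' strand); below 90%
identity or 50 aligned columns the read is unmapped.  When the OTU set has
≤ 8 members every OTU is aligned (no shortlist effect).  Tests compare the
default path against an independent affine DP oracle on random instances
drawn from the simulator's error model.

## Chimera screen (C3)

Both `end_len` = 150-bp ends of an OTU are matched by the identity screen;
all ties at an end's maximum identity are kept as a set, so near-identical
reference entries cannot force disjoint best-match sets.  Non-chimeric
requires a shared reference with consistent orientation: same strand and
the 5′ end strictly upstream of the 3′ end ('+') or strictly downstream
('−').  Ends with no match ≥ `min_end_identity` (default 60%, the bottom
of the community envelope) make the verdict *indeterminate*, never
chimeric — in novel environments weak matches must not inflate the
false-positive rate, and the screen as a whole is skippable
(`skip_chimera`).  Removed OTUs' reads move to the unmapped tally rather
than being remapped, preserving conservation.

## Identity screen

The watered-BLAST-style screen short-lists references by shared 8-mer
counts (top 20 candidates over both strands) and scores them by exact
Smith-Waterman.  Alignments shorter than half the query are ignored: the
identity of an optimal *local* alignment is otherwise dominated by tiny
perfect repeats (a 12-bp exact match at 100% would outrank a full-length
alignment at 99.3%), which produced false chimera orientation calls before
the gate existed.

## Translation and peptide collapse

Nucleotide dereplication merges byte-identical, reverse-complement-identical
and contained sequences (CD-hit-at-100% semantics); the representative is
the longest, ties by id.  Frames are chosen by the maximal six-frame local
protein score, ties in the order (+1, +2, +3, −1, −2, −3); below a raw
score floor of 50 the longest-ORF frame is the fallback.  Peptides equal
after stripping a terminal stop (or contained in a longer peptide) collapse
into one peptide OTU whose abundance is the sum of its members.  OTUs whose
best-frame translation has an internal stop are excluded from peptide space
by default (they stay in nucleotide space and are reported): frameshifted
pseudo-peptides would otherwise inflate peptide richness.  Counts are
conserved: excluded OTU counts move to the peptide table's unmapped tally.

## Profile evaluation

OTUs are matched to members by the identity screen's best hit; a member is
*recovered* when some OTU matches it at ≥ 97% (our calling threshold for
"an expected OTU").  Profile error is the total variation distance
½ Σ|p̂ − p| with p̂ over mapped reads only and p the realized multinomial
draw; the unmapped fraction is reported separately rather than folded into
the error.  "Total error" is not formally defined in the source material;
total variation distance is this package's normative choice — it is the
standard bounded [0, 1] compositional error.

## What the simulations establish — and what they do not

Green tests establish that the pipeline's logic is correct under the
stated world: substitution-only errors, uniform error rate, known primers,
single-region amplicons, communities whose members are full-length
homologues.  They do not establish robustness to homopolymer/flowgram
error structure, PCR abundance bias, partial-length references, or
paired-end protocols — none of which the stated world contains.  The DBG
under-resolution of the 96% pair is demonstrated as a trend (recovery
non-decreasing in k, never exceeding the OLC engine), not matched to any
external tool's exact output.

## Determinism

Every stochastic step consumes a caller-supplied seed (one RNG per
simulation call); assembly, mapping, screening and export are
deterministic functions of their inputs with explicit tie-breaks, verified
by byte-identical artifact checksums across reruns.  Test suites are
seeded; simulation sizes in the suite (2000-read shared fixture, 5 × 5000
reads for the five-seed experiment) are scaled to run on one CPU in
minutes while keeping the rarest member's coverage ≥ 25×.
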