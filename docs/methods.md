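# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `nor5s`. Coordinates are 0-based half-open internally and
1-based inclusive in GFF3 and in gene-position reporting (diagnostic sites,
ICR, structure pairs).

## Homology scan

Gene copies are located by seed-and-extend: exact k-mer seeds (default
k = 13) of the reference are found on both contig strands, chained when
their diagonals agree within a tolerance (32 nt) and their contig positions
lie within one reference length, and each chained cluster is extended by an
affine-gap Smith–Waterman alignment of the full reference against the
seeded contig window (margin 60 nt). Scoring defaults are match +2,
mismatch −3, gap open −5, gap extend −2, with a gap of length L costing
−(open + (L−1)·ext); hits need ≥ 70 % identity (matches over alignment
columns) and ≥ 50 % query coverage. Overlapping same-strand hits collapse
to the highest score. Aligning the whole reference against the window
rather than banding the extension keeps seed-and-extend scores exactly
equal to exhaustive local alignment on the window, which the test suite
verifies against an independent enumeration oracle.

Within one window, tandem copies are separated by masking: after the best
local alignment is taken, its contig span is masked and the window
re-aligned until nothing clears the thresholds. Because local alignment
clips mismatching gene ends (a diagnostic substitution at position 2 of a
119-nt gene trims the first two bases), every hit records the aligned
reference span so downstream consumers can pad hits back to full gene
length (`HomologyHit.full_gene_interval`).

45S units are maximal same-strand 18S → 5.8S → 28S triplets in
transcription order spanning ≤ 20 kb. The IGS of a unit runs from its 28S
3′ end to the next unit's 18S start on the same strand, or to the contig
end (flagged partial; partial units are reported, not discarded, because
WGS contigs truncate arrays). The candidate screen flags contigs with ≥ 1
28S hit and ≥ 1 5S hit lying outside every unit's transcribed span.

The DP kernels are numba-compiled (first call pays a few seconds of JIT);
traceback replays the recurrences in Python with a fixed tie-break order
(diagonal, then vertical, then horizontal), so alignments are
deterministic.

## IGS architecture

**Tandem repeats.** For each candidate period p (default 5–2000), the
sequence is compared with itself shifted by p. The binary match profile is
scored +1 for a match and −m/(1−m) for a mismatch (m = `min_match`, default
0.8) so that a segment has positive sum exactly when its match fraction
exceeds m, and maximal positive-sum runs are taken Kadane-style. A run
must cover at least (`min_copies` − 1)·p positions (default min_copies
2.5); the array interval adds one period to the run. Overlapping candidates
resolve to the smallest period whose array covers the region (a period-p
array also matches at 2p, 3p, …). The monomer consensus is the column-wise
majority over the array's p phases; an array whose consensus is a
homopolymer is reported with period 1. Array boundaries can extend by
flank bases that genuinely match at the period, so the recovery contract is
period exactness and boundaries within one period.

**polyA.** The longest A-run of ≥ 8 nt within a 30-nt window beyond the
gene's 3′ end, tolerating one non-A per ten positions of the run and always
ending on an A. "Short polyA linker" is not otherwise quantified, so the
run threshold and tolerance are package defaults, configurable at the call
site.

**Insert classification.** Orientation is `opposite` iff the 5S hit strand
differs from the unit strand, and is invariant under reverse-complementing
the contig. Distance to 28S is the IGS-local start of the (padded) gene
interval in unit orientation, i.e. the gap from the 28S 3′ end to the
nearer insert boundary. The upstream flank (default 40 nt) is reported
**gene-proximal-first**: position 1 is the base immediately 5′ of the gene
start in gene orientation. This anchors cross-sample conservation at the
gene boundary, so `conserved_prefix` — the longest prefix over which every
column agrees with its majority in ≥ 90 % of samples — directly measures
how far conservation extends away from the gene. The conserved length is
measured from data, never assumed.

**Segmentation.** The IGS is tiled by insert, polyA, repeat blocks
(truncated with a warning where they collide with the insert) and maximal
`unique` gaps; coverage and non-overlap are asserted on every annotation.
Cross-sample block-label harmonisation groups monomer consensuses at ≥ 80 %
rotation-invariant global identity; it reports similarity families, not
homology claims.

## Variant typing

Copies of each class are aligned by the center-star method (the copy with
the highest summed pairwise identity is the center; all others are globally
aligned to it and gap patterns merged). This is adequate for near-identical
gene copies and deliberately not a general aligner. The consensus takes the
per-column majority base, encodes ties as IUPAC ambiguity codes, and drops
columns gapped in more than half the rows.

Diagnostic sites come from a global end-to-end alignment of the two
consensuses: substitution columns with distinct, unambiguous bases, with
positions in 1-based NTS-5S coordinates. Indel columns and ambiguity
columns are listed separately and never become sites — an ambiguous
consensus column cannot discriminate reads, and indels are not modelled by
the read classifier. Swapping the inputs swaps base labels but not
positions.

The ICR is annotated at configurable canonical 5S coordinates (A-box
50–64, intermediate element 67–72, C-box 80–97, 1-based), which follow
standard 5S gene numbering; the variant comparison simply tests equality of
the three intervals' subsequences.

## Secondary structure

Thermodynamic folding is intentionally out of scope. The package provides
(a) Nussinov-style maximum-cardinality nested pairing under Watson–Crick +
G·U rules with hairpin loops ≥ 3 nt and a deterministic traceback, verified
against brute-force enumeration for short sequences; and (b) threading onto
a fixed canonical five-helix 5S template (helix I 3–9:113–119, II
14–22:60–68, III 26–33:49–56, IV 70–77:97–104, V 79–85:90–96 on a 119-nt
gene), scoring the number of template pairs the sequence can still form.
Threading answers the biologically relevant question — do the variant's
substitutions break conserved helices or fall into loops? — without an
energy model. The default synthetic gene is built to satisfy the template,
and the default diagnostic positions (2, 23, 112) are loop-positioned, so
the two variants thread identically by construction.

## Read classification and the maternal call

Reads are mapped semi-globally (full read against a gene substring, both
orientations, via edlib's infix mode) to each consensus. Acceptance
requires mismatches + gap columns ≤ floor(`max_error_rate` × read length) —
the strictest reading of a "1 % per read" policy, so a 100-nt read passes
with 1 error and fails with 2 — and ≥ 20 nt of the gene covered. Site
alleles are read off the accepted alignment with fewer errors (NTS frame on
ties, since site positions are NTS coordinates). A read is labelled
NOR/NTS only when it covers ≥ 1 diagnostic site and all covered sites show
that variant's allele; conflicts, off-allele bases and site-free reads are
`ambiguous`, unmappable reads `unassigned`, and the four labels always
partition the input. Reads are never split fractionally.

`pct_nor` is the NOR share of assigned (NOR + NTS) reads; the share over
all reads is also emitted since the right denominator is a reporting
choice. Reads matching one variant perfectly at a single covered site are
genuinely indistinguishable from that variant, so a small false-NOR rate
(≈ error_rate/3 per single-site read) is inherent at mixture fraction 0;
recovery is therefore checked with a Wald band — |p̂ − p| ≤ 3·√(p̂(1−p̂)/n)
on assigned reads — the standard confidence-interval form, which is exact
at p̂ = 0 and absorbs the residual misclassification at the design points
used.

The maternal-type call is a deliberate operationalisation of a qualitative
pattern: the NOR variant is maternal-type iff its share is ≥ 50 % in every
germline/embryo tissue and ≤ 5 % in every somatic tissue. Both thresholds
are reported next to the raw percentages so users can apply their own
cutoffs. Reports carry the caveat that rRNA depletion in standard RNA-seq
libraries underestimates absolute 5S abundance; the percentages compare
variants, they do not estimate expression levels.

## Synthetic data

The generator plants, with exact truth intervals: a contig of tandem 45S
units (defaults 18S 1800 nt, 5.8S 160 nt, 28S 4000 nt, ITS 300 nt — round
teleost-scale values that only need internal consistency; 5S 119 nt, the
span of a typical teleost 5S gene) whose IGS carries labelled monomer
arrays (defaults 37 nt × 8, 52 nt × 6 before the insert and 29 nt × 5
after, generically labelled — real monomer sequences are not modelled), a
24-nt conserved flank shared across simulated species, the 5S insert
(default reverse-oriented, gene start 960 nt from the 28S 3′ end) and a
12-nt polyA linker; and a second contig with eight clustered canonical
copies. Background sequence is i.i.d. uniform A/C/G/T, which makes
spurious homology maximally visible. Eight non-A guard bases follow the
planted polyA so its truth interval is maximal and therefore well-defined
against the tolerant run detector.

Reads are single-end, drawn from uniform windows of the variant chosen
Bernoulli(fraction_nor), with i.i.d. substitution errors only (no indels,
no quality model); the read-error budget in mapping still counts gaps, so
real indel-bearing reads would be rejected rather than misassigned. Copy
noise across gene copies is likewise substitution-only, keeping consensus
recovery oracle-exact. Passing tests therefore demonstrate correct
recovery under substitution noise and clean tandem architecture; they do
not exercise indel noise, diverged pseudo-copies, chimeric contigs or
coverage-dependent assembly artefacts of real WGS data.

## Problem sizes and determinism

Default test and acceptance runs use three 45S units (~25 kb contig), five
simulated species, ten gene copies per class at 1 % noise, 100 replicates
for site recovery, 100 oracle comparisons, and four tissues at depth 5000
with 0.3 % read error. All randomness flows from explicit integer seeds
(numpy `default_rng` / `random.Random`); pipeline outputs are a pure
function of inputs, config and seed, and reruns are byte-identical.

## Known limitations

- No E-value statistics; hit acceptance is identity/coverage thresholds.
- The center-star aligner assumes near-identical copies; diverged
  paralogues would need a real MSA tool.
- Repeat detection reports the smallest covering period and can misplace
  boundaries by up to one period; higher-order repeat structure is not
  inferred.
- The ICR is located positionally, not by motif search.
- The structure module maximises pair counts; it makes no free-energy or
  temperature claims.
- Accession-based reproduction (screening the original WGS contigs and SRA
  read sets) requires network access to NCBI and is supported by the same
  pipeline entry points but not exercised by the offline test suite.
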