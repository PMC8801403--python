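# Methods

## Setting

An intronic-selection-marker knock-in places the Cas9 double-strand break
(DSB) and the selection cassette inside an intron, leaving splicing and
coding sequence untouched, and relies on the gene-conversion tract of
homology-directed repair to copy exonic edits from the donor's homology
arms (HAs) into the genome. The computational questions are (i) which
exonic targets are reachable given a tract budget, (ii) where a guide may
cut without disturbing splice signals, (iii) which designed variants each
sequenced amplicon incorporated, and (iv) what tract-length distribution
explains the observed per-distance conversion frequencies.

## Annotation analysis

Exon and CDS rows of a GENCODE-dialect GFF3 are grouped per transcript;
coordinates become 0-based half-open at the parse boundary. An exon's
coding (UTR-excluded) length is its summed overlap with the transcript's
CDS intervals; fully untranslated exons are excluded from UTR-excluded
denominators because a coding-length statistic is undefined for them.
First/last flags follow transcription order (strand-aware). Where a
`transcript_type`/`transcript_biotype` tag is present, only
`protein_coding` transcripts are kept; untagged annotations pass through
unfiltered so minimal fixtures behave predictably.

Exons are counted per (transcript, exon) pair by default — the result of
a naive per-row scan of the annotation — with an optional `dedupe` flag
collapsing exons shared across transcripts at identical coordinates; both
conventions are defensible and the choice measurably shifts the tail
fractions, so it is exposed rather than hidden.

The editability fraction is `1 − fraction(length_coding > budget)` with a
default budget of 600 nt: because both flanking introns can host the cut,
an internal exon of length ℓ needs a tract of at most ⌈ℓ/2⌉ nt, so the
600 nt exon budget corresponds to a ~300 nt tract. Unstranded features
are rejected (first/last assignment needs strand), and an exon universe
that is empty after filtering raises rather than returning 0.

## Guide placement and donor assembly

Guides are SpCas9 sites: a 20-nt protospacer followed by NGG, blunt cut
3 nt 5′ of the PAM (between protospacer positions 17|18). Only the cut
position is constrained: it must fall strictly inside the host intron
minus a donor-side window (default 20 nt, protecting GT and donor-site
context) and an acceptor-side window (default 50 nt, covering branch
point, polypyrimidine tract and AG). The defaults are conservative,
literature-typical extents; both are configurable and must be ≥ 2 nt so
the boundary dinucleotides are always protected. Sites containing N are
never admissible. Candidates are ordered purely by distance of the cut to
the requested target — no activity or off-target scoring is attempted.

`nearest_intron` returns the flanking intron minimizing the distance from
an exonic target to the exon boundary; ties at the exact midpoint break
toward the left (5′-in-genome) intron, an arbitrary but fixed rule.

Donor assembly copies both HAs from the locus around an intronic cut,
applies the designed variants (substitution / insertion / deletion; the
reference allele is checked against the locus and mismatches are errors
naming the position), and records two safety results: whether the arms
reach 500 nt — the length below which recombination was empirically
inefficient — and the positions of poly(A)-signal motifs (AATAAA/ATTAAA)
over the whole donor in sense orientation. "Terminator" is interpreted
as the polyadenylation signal; bacterial rho-independent terminators and
transcriptional pause sites are out of scope, and the motif list is
deliberately small and explicit.

Tract distance is measured from the cut site (not the guide 5′ end) to
the variant's nearest edited base: the base immediately flanking the cut
is at distance 1, and an insertion exactly at the cut at distance 0.

## Amplicon calling

Each read is globally aligned (Needleman–Wunsch with affine gaps; match
+2, mismatch −3, gap open −5, gap extend −2, the first gap base costing
the open score) against the wild-type amplicon in both orientations, the
better score kept. Identity is matches over aligned columns with terminal
gap runs excluded, so truncated or over-long reads are penalized only for
internal disagreement; reads shorter than 50 nt or below 0.9 identity
fail QC. The alignment parameters and QC thresholds are package defaults
(Sanger colony sequencing typically needs nothing stricter) and are all
configurable.

Substitutions are called base-for-base through the alignment: converted
iff the aligned bases equal the alternate allele, unconverted iff the
reference, ambiguous otherwise (any gap, any non-designed base, any site
outside the read span — truncation is never counted as unconverted).
Indels are called by extracting the read segment between aligned anchor
columns flanking the site (3 nt each side) and comparing it to the
expected reference/alternate window; this makes the call invariant to
where the aligner places an equivalent gap, e.g. inside a homopolymer.

Ambiguous calls are excluded from both numerator and denominator of
conversion frequencies by default, so per-site denominators vary; a
fixed-total denominator (all QC-passing reads) is available as a flag for
comparison with fixed-denominator reporting conventions.

## Tract statistics

The conversion profile is the per-variant fraction of converted calls,
ordered by tract distance, with summary accessors for the minimum and the
pooled frequency below a distance cutoff (both are reported because
"efficiency below 300 nt" can be read per-site or pooled). A variant with
zero non-ambiguous calls has undefined (NaN) frequency, never 0.

Co-occurrence cell (i, j) is P(variant j converted | variant i
converted) over reads where both calls are non-ambiguous. Under a
per-molecule tract, conversion is nested — the incorporated set is
downward-closed in distance — so P(near | far) = 1 while P(far | near)
equals a conditional survival ratio; the matrix makes that asymmetry
visible.

The tract-length model is a geometric survival S(d) = p^d, the simplest
one-parameter monotone family on the nonnegative integers; the family is
named so alternatives can be added. Each read is collapsed to the
censoring interval [a, b) between its furthest converted and nearest
unconverted distance and contributes log(S(a) − S(b)); all-unconverted
reads give [0, d_min) and all-converted reads [d_max, ∞). Reads with a
non-nested pattern (a far conversion without a nearer one — template
switching or PCR chimerism in real data) are excluded from the fit and
counted, since they violate the single-tract assumption; the profile and
co-occurrence retain them. The MLE is found by bounded scalar
minimization to ~1e−12 in p (well past the 1e−8 log-likelihood change
the optimum needs), and the 95% CI is the profile-likelihood set at a
χ²(1) half-drop of 1.92. An optimum within 1e−6 of a boundary (e.g. a
single distance, all converted) is flagged non-identifiable.

Clone recombination rates are exact rational percentages rounded half-up
to one decimal (21/24 → 87.5, 10/24 → 41.7) with Clopper–Pearson 95%
intervals from the beta quantile form.

## Synthetic data

The generator's defaults are the study conditions the analysis assumes:
seven left-arm variants at 45, 90, 171, 386, 490, 596 and 696 nt from the
cut; one library of 624 amplicons; substitution sequencing error 1e−3
(Sanger-like; indel errors exist behind a rate flag, default 0);
geometric tract parameter p = 0.9989, calibrated so survival at ~400 nt
is ~65%, the conversion efficiency observed at that distance at the locus
this layout emulates; clone genotyping of 24 clones per donor type with
true-positive probabilities 0.875 (ssDNA donor) and 0.417 (dsDNA donor).
Simulated loci have canonical GT…AG introns, a branch-point adenine
20–40 nt upstream of each acceptor and a ≥10 nt polypyrimidine tract —
enough anatomy for the splice-safety windows to be meaningful.

Per-read tract lengths are drawn independently (L = Geom trials before
failure, so P(L ≥ d) = p^d exactly); real repair may correlate events
within a clone or between strands, which this deliberately ignores. A
configurable fraction of reads is pure wild type, modeling sorting false
positives (default 0). Reads are emitted in mixed orientation (half
reverse-complemented) to exercise orientation normalization. Everything
is deterministic under the config seed; read simulation and clone
simulation use fixed offsets from it so the stages are independently
reproducible.

`simulate_call_matrix` draws the same tract model directly at the call
matrix level (no sequences, no alignment); statistical experiments that
need thousands of replicates use it, while end-to-end correctness is
always established on fully simulated and re-aligned reads.

**What passing tests show — and don't.** The simulator produces exactly
the nested, geometric, iid world the estimator assumes, plus simple iid
base errors. Tests therefore demonstrate correctness of the machinery
(alignment, calling, censoring algebra, optimization, intervals) and
internal consistency, not that real conversion tracts are geometric, that
real errors are iid, or that real libraries are free of chimeric
amplicons — the non-nested-read counter is the first diagnostic to look
at on real data.

## Problem sizes and numerical choices

The test suite and the acceptance script run at sizes chosen to make the
statistics sharp while keeping a full run comfortably interactive:
alignment-level round trips at 120–624 reads on ~830 nt amplicons,
matrix-level experiments at 500–10 000 reads, 100-locus brute-force guide
sweeps, 200 alignment-oracle pairs up to 600 nt, and 200-replicate CI
coverage runs. Grid-search and DP oracles live in the test tree, written
independently of the implementation. Binomial-band checks use exact
(Clopper–Pearson / scipy `binom.interval`) bounds; calibration-style unit
tests count band escapes across replicates against the nominal rate
rather than demanding zero escapes, which would itself be a ~5%
false-alarm test at 7 sites × 99%.

## Known limitations

- No off-target or on-target guide scoring; ordering is by distance only.
- No chromatogram (.ab1) parsing; reads enter as FASTA.
- No NHEJ indel spectrum at the cut site; the non-HDR fraction is modeled
  as clean wild type.
- The editability statistic treats annotation rows at face value; it does
  not ask whether a specific intron admits a safe guide at a specific
  distance (the design module answers that per locus).
- The geometric family is a modeling convention; the fitted p is a
  summary of decay, not a mechanistic claim.
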