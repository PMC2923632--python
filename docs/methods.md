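# Methods

## Coordinate and sequence conventions

All intervals are 0-based half-open in memory and 1-based inclusive in
TSV/report output; conversion happens only at the file boundary. Genomes are
uppercase DNA over {A,C,G,T,N}; U is mapped to T on input. Translation uses
the bacterial genetic code (NCBI table 11), so the histidine codons are
exactly CAT and CAC. A CDS whose length is not divisible by three, or whose
translation contains an internal stop, is excluded from histidine statistics
and listed in a QC report rather than silently used; the statistics are
meant for curated annotations, and degenerate gene models would distort
them. Ambiguous codons translate to X where biopython cannot resolve them;
since the genome alphabet contains no ambiguity codes other than N, a
histidine can never arise from an ambiguous codon.

## Array extraction and orientation

The array is found by consensus-anchored search, not de novo repeat
discovery: the repeat consensus (21–47 bp) is an input, and every
forward-strand ungapped occurrence within `max_mm_per_copy` mismatches
(default 6) is located by a vectorized Hamming scan. Overlapping occurrences
are resolved greedily left to right, keeping the lower-mismatch copy. The
mismatch tolerance per copy is a guess exposed as a parameter — there is no
canonical value — and at the default synthetic mutation rate (2% per base,
~0.6 substitutions per 29-bp copy) any tolerance from 3 to 10 recovers the
same array.

Consecutive occurrences whose gaps fall inside the spacer band (default
21–47 bp, the same size range as the repeat) are chained; the longest chain
becomes the array and its gaps become the spacers. Fewer than two chainable
copies is a "no array" result, not an exception.

The leader is called as the flank (150-bp window beyond the terminal
repeats, truncated at contig edges) with the higher A+T fraction. When the
two fractions differ by less than 0.02 the orientation is reported
undetermined with a warning, since "AT-rich" is the only available
criterion. Spacers are numbered trailer-first — spacer #1 is farthest from
the leader, i.e. the oldest spacer, since new spacers are inserted at the
leader end — with a CLI flag for leader-first numbering.

Hairpin prediction enumerates all pairs of non-overlapping intervals within
the repeat where the downstream interval is the exact Watson–Crick reverse
complement of the upstream one (no G:T wobble, no N), separated by at least
`min_loop` bases, and returns the longest stem, breaking ties by smaller
loop and then leftmost arm. `min_loop` defaults to 2 because the reference
repeat itself folds with a 2-nt loop. The implementation is checked in the
tests against an exhaustive O(L⁴) enumerator. Full RNA secondary-structure
prediction is out of scope; the single perfect stem is the object of
interest here.

## Seeded spacer search

The search reproduces the sensitivity criterion of a BLASTN run at the
minimum word size: a hit is a full-length ungapped alignment of the spacer
with at most k mismatches (default 5, the "five or fewer mismatches out of
32 bases" rule) that contains at least one exact w-mer (default w = 7).
k is applied as an absolute count whatever the spacer length, since the
stated rule is for 32-bp spacers; it is a parameter. The exact-seed
requirement is part of the defined criterion, not an approximation to
Hamming-ball completeness: for L = 32, w = 7 every alignment with k ≤ 3
mismatches necessarily contains an exact 7-mer (pigeonhole), while for
k = 4, 5 a seedless alignment is deliberately invisible, exactly as it would
be to the seeded aligner. Both strands are searched by aligning the reverse
complement of the spacer to the forward strand; a minus-strand hit means the
proto-spacer is on the reverse strand of the reported interval.

Self-hits of a spacer to its own array position are reported (category
`inside_own_array`) rather than suppressed, so whole-genome accounting of
"hits with zero mismatches within the genome itself" is reproducible. A hit
contained in a *different* spacer's interval is `spacer_spacer`; a hit
overlapping a CDS outside the array is `proto_spacer_in_cds`; anything else
is `intergenic`.

The PAM is the `length` bases (default 3) immediately 3′ of the proto-spacer
on the proto-spacer's strand — for a minus-strand hit, the bases 5′ of the
interval on the forward strand, reverse-complemented — padded with N at
contig edges. The side is a parameter for reuse on systems with 5′ PAMs.

Bulge alignment (off by default) models a single-base insertion on either
side by trying every single-base deletion of the longer sequence and
keeping the leftmost minimum-mismatch placement. It exists to represent the
observation that a central single-base-pair duplication in a spacer does
not abolish interference; it is opt-in and not part of the significance
criterion.

## Histidine demand

For histidines at residue positions p₁ < … < p_h, distances are differences
of *consecutive* positions (adjacent histidines give d = 1), in residues.
The demand index is D = h / H with H the harmonic mean of those gaps. The
alternative all-pairs reading of "the distances between them" is provided
behind a flag (`mode="all_pairs"`) for sensitivity analysis; the consecutive
reading is the default because it targets runs of closely spaced histidines
and gives the clean identity D = h for a perfectly adjacent cluster.
Proteins with h < 2 have no defined H or D; they are excluded from the
demand curve but included in the histidine-count curve. Computing h on the
translated protein and counting CAT/CAC codons on the CDS agree by
construction; the equality is asserted in the tests.

His-codon frequency per thousand is 1000 × (CAT+CAC) / (non-stop codons)
over all CDS. Stop codons are excluded from the denominator by default
because the frequency describes coding positions; the decision is exposed as
a flag since codon-usage tools differ on this convention.

The high-demand cutoffs mirror their verbal definitions exactly: the count
criterion is inclusive (h ≥ 35, "35 or more") and the demand criterion is
exclusive (D > 5.0, "above 5.0").

## Family screen

Ortholog families are an input TSV (family_id, genome_id, gene_id), not
computed — family assignment rests on curation, and inferring orthology here
would launder a much harder problem through the screen. For each family with
at least one member above the cutoffs: if no non-focal member passes, the
family is `not_applicable`; otherwise an absent focal member means `lost`,
focal members that all fail the cutoffs mean `reduced`, and a passing focal
member is `retained` or `increased` according to whether the focal maximum D
exceeds the non-focal maximum D. "Reduced" is operationalized as "no longer
passes the criterion"; a focal gene with lower demand than its orthologs but
still above the cutoff classifies as `retained`, and the numeric columns
(max h and max D on both sides) let a user apply a softer reading.
Ancestrality is not inferred: deciding which families are "clearly
ancestral" is curation, so a curated count of ancestral losses is not an
automated output of this package.

## Synthetic data

The generator's defaults are the study conditions: 112 repeat copies of the
29-bp reference repeat separated by 111 spacers of 32 bp, per-copy
substitution probability 0.02, an AT-rich leader (AT fraction 0.75 over
150 bp) on the left, and the trailer-most spacer copied verbatim from inside
a planted CDS with CTT immediately 3′ of the proto-spacer. Background
sequence is i.i.d. with GC 0.55 (typical of the *Geobacteraceae*); because
the background has no repeat structure, a brute-force scan is an exact
oracle for the search. The planted CDS is kept frame-clean by repairing any
in-frame stop codon created by the random insert outside the protected
window (redrawing the proto-spacer when a stop falls entirely inside it).
Proto-spacer uniqueness in the genome is verified after assembly.

Synthetic proteomes draw background histidines i.i.d. per residue with
probability 0.0225 (so the expected codon frequency is ≈ 22.5 per thousand,
the focal genome's value); high-demand genes additionally carry
⌈35/c⌉ clusters of c histidines at residue gap g (defaults c = 6, g = 1), so
h ≥ 35 and D ≈ h/g. Family planting appends engineered members with single
clusters chosen to force each status under the default cutoffs: reference
members at (h = 36, g = 1) and focal members absent for `lost`, at
(8, 40) for `reduced`, (36, 2) for `retained`, and reference (36, 3) vs
focal (36, 1) for `increased`.

A single integer seed drives one `numpy` SeedSequence; per-component
substreams are spawned deterministically, and per-genome proteome streams
are keyed by a CRC of the genome id, so outputs are byte-identical across
runs and adding a generator does not shift the others.

What the generator does *not* emulate: realistic codon usage, genome-wide
repeat families, mobile elements, annotation errors, or evolutionary loss as
a process. Passing the planted-recovery tests therefore shows the pipeline's
bookkeeping and statistics are correct under clean conditions, not that the
search is robust to repeat-rich real genomes, where near-repeat background
can produce additional low-quality hits that the classification step must
absorb.

## Problem sizes and verification

The default test and acceptance runs use a 60-kb genome for the 112-repeat
array, a 100-kb genome and 200 random 32-mers for the search-oracle
comparison, 10,000 random proteins for the demand-index oracle, and
three 300-protein proteomes with 10 planted families for the screen — sizes
at which every brute-force oracle runs comfortably while exercising the
full default geometry. The acceptance script
(`python scripts/acceptance.py --seed N --out results/acceptance.json`)
recomputes every reported quantity from scratch at run time.

## Known limitations

- Desk validation is synthetic; validating spacer #1 against the public
  *P. carbinolicus* genome (locus Pcar_1041) requires downloading the
  assembly, and annotation-version drift can perturb codon-frequency
  decimals between annotation releases.
- The seeded search is ungapped (plus the opt-in single bulge); affine
  gapped alignment and E-value statistics are out of scope.
- De novo repeat discovery, cas-gene annotation, and repeat-cluster
  phylogenetic classification are out of scope; the consensus is an input.
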