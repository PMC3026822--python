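# Methods

This note documents the models, parameter choices and numerical
conventions behind each pipeline stage, what the synthetic data
generator does and does not emulate, and the known limitations.

## Preprocessing

Reads are dropped when they contain any ambiguous base or their mean
Phred quality falls below 20 (`min_mean_q`, configurable); "low quality"
is otherwise unspecified in this protocol family, so a hard mean-quality
rule was chosen. The 3′ adapter is located by the leftmost position
where a prefix of the adapter matches with at least 6 nt overlap and at
most one mismatch per 10 aligned bases; everything from that position on
is removed. Reads whose 5′ end matches the 5′ adapter under the same
rule are adapter-dimer artifacts and are discarded whole. Only 18–30 nt
inserts survive (the gel window extends to 16 nt, but the computational
floor is 18 nt). Collapsing ranks tags by descending count with
lexicographic tie-break so identifiers are deterministic; `F<rank>_x
<count>` encodes the count exactly. The retained-read fraction is
defined as 100 × clean/raw rounded to two decimals; note that the
widely quoted 70.30% for the 4,821,809/3,389,218 accounting is actually
70.29 at that precision — the package reports the arithmetic value.

## Annotation cascade

Classes are assigned in a fixed priority order (rRNA, tRNA, snRNA,
snoRNA, known miRNA, mRNA, piRNA, unknown); the first hit wins, which
makes the cascade monotone: growing a lower-priority catalog can never
change a higher-priority assignment. ncRNA and mRNA matching is exact
substring or k-mismatch windowed comparison with k = 2, implemented
in-repo with numpy sliding-window comparisons (catalogs at this scale
are small; no external aligner, fully deterministic). Known-miRNA
matching delegates to the homology rules below. piRNA candidacy is
restricted to 26–30 nt tags with perfect matches, and the mRNA class is
checked after miRNA so miRNAs residing in transcripts are not absorbed
as breakdown products.

## Folding backend

The built-in backend minimises a stacking-only nearest-neighbour free
energy: each adjacent pair of base pairs contributes a Turner-style
37 °C stacking increment (Watson–Crick and G:U wobble), hairpin loops
span at least 3 unpaired bases, and there are no loop, bulge or
multiloop penalties. Energies are integers in centi-kcal/mol
internally, so optima and ties are exact; the optimum is defined
lexicographically (minimum energy, then fewest pairs, so zero-energy
lone-pair decorations are dropped). The dynamic program covers all
pseudoknot-free structures, including multibranch ones — the model has
no multiloop penalty, so this is the natural closure — and is verified
in the tests against exhaustive enumeration for short sequences. The
backend is pluggable: anything returning `(dot_bracket, delta_g)` can
replace it. Because loops are free, absolute ΔG values are more
negative than full-thermodynamic folders would report, which the −17
kcal/mol threshold absorbs in practice for designed and planted
hairpins but which should be kept in mind for real genomes.

Shuffle significance follows the dinucleotide-preserving (Altschul–
Erikson) procedure: shuffles keep the exact dinucleotide count vector
(first and last bases fixed), and `p = (1 + #{ΔG_shuffle ≤ ΔG}) /
(n_shuffles + 1)` with n = 99 by default. Homopolymers shuffle to
themselves and give p = 1 by construction.

## Hairpin discovery

Tags map to the genome by exact string match on both strands; tags with
more than 5 placements are set aside as multi-mapping. Placements are
clustered per contig with a 30 nt gap, and the highest-count tag of a
cluster seeds two excision windows (tag + 70 nt flank 3′, and 5′),
matching ~75 nt precursors with room to spare. After a window passes
the preliminary structure checks it is trimmed to the stem–loop around
the mature (paired mature bases plus partners, ±5 nt margin) and
refolded; the shuffle test then compares the hairpin against shuffles
of itself rather than of unrelated flanking sequence, which is what
keeps the significance filter sharp.

Filter thresholds: ΔG < −17 kcal/mol, mature confined to one arm,
≥ 60% of mature bases paired, shuffle p ≤ 0.05. The arm test ignores
up to two base pairs formed within the mature itself (structural noise;
a Dicer duplex pairs mature with star) but treats more extensive
self-pairing, or any mature reaching past the terminal loop, as a
straddle; up to 4 nt of terminal fraying into the loop is tolerated.

The read-signature score is
`3·f_mature + 2·star_bonus + 2·h5 − 4·f_loop + 0.2·log2(total reads)`,
where `f_mature`/`f_loop` are read fractions on the mature arm and
loop, `star_bonus` indicates a star read whose 5′ end lies within 2 nt
of the position implied by a 2-nt 3′ overhang, and `h5` is the modal
5′-end fraction among mature-arm reads. Candidates below a score of
2.0 are dropped; loop-dominated signatures are strongly negative. The
weights are a documented re-derivation of biogenesis-signature scoring
with tunable constants, not a reproduction of any published tool's
likelihood parameters. The dominant arm is simply the half of the
precursor carrying more reads — star-dominated loci are reported as
such rather than discarded.

The genome homolog scan slides each known mature over both strands,
keeps ungapped hits with identity strictly above 95% (mismatches/mature
length), and subjects the excised context to the same fold/trim/filter
chain. Identity is computed over the full mature length, so a 22-mer
admits one mismatch (21/22 = 95.45%) but not two.

## Homology and merging

Tags are compared full-length against the known-mature catalog at
offsets within ±2 nt: terminal overhangs (≤ 2 nt per end) accumulate in
the signed length delta rather than the mismatch count, and up to two
internal mismatches define the variant class. Expect-value semantics
of BLAST-based matching are deliberately replaced by this explicit
counting — deterministic and dependency-free at catalog scale.
Cross-species synonyms collapse by base name (species prefix stripped;
`-5p`/`-3p` suffixes are never stripped within a catalog), represented
by the highest-count tag. Merging the three methods keys conserved
records by name and novel records by mature sequence; provenance is the
union, the seven Venn cells are reported, and a name bound to two
sequences differing by more than 2 nt yields a conflict with both
records kept under numeric suffixes.

## isomiRs

A tag is assigned to the precursor it aligns to best (no gaps) with the
5′ start within ±4 nt of the reference mature start, at most 2 body
mismatches, and the 3′ offset within ±4 nt. Sign convention: negative
offsets extend beyond the reference end, positive offsets trim. A
maximal run of terminal 3′ mismatches (≤ 3 nt) is classified as a
non-templated addition rather than substitutions — an internal
substitution at the very last templated position is therefore read as
NTA, a deliberate tie-break. Assignment cost orders by (body
mismatches, total |offset|, NTA length); ties across precursors assign
the tag to each, flagged ambiguous, and ambiguous counts are excluded
from conservation accounting. The classification is information-
preserving: (reference, offsets, substitutions, NTA) reconstructs the
tag exactly, which the tests assert on every simulated library. The
summary reports variant species both summed per miRNA and as globally
unique sequences, since the two conventions differ.

## Microarray stage

Triplicate spots collapse by median before anything else. Detection:
per array, positive means signal ≥ negative-control mean + 2 SD
(sample SD; zero-variance controls degrade the threshold to the bare
mean and are flagged); a probe is detected when positive on at least
two arrays. Background correction is the Normal + Exponential
convolution: the posterior signal given an observation is a normal
truncated to s > 0, with mean `m + σ·φ(m/σ)/Φ(m/σ)`, `m = x − μ −
σ²/α`, computed in log space; μ and σ come from the negative controls,
α from the mean signal excess. Quantile normalization maps each column
to the row-sorted mean profile at its within-column ranks, averaging
ties — the standard definition, idempotent, verified against the
Bioconductor implementation on small matrices.

Testing uses the pooled-variance two-sample t statistic on log2
signals (Welch available as an option) and the fold change is the
difference of group means on the log2 scale — the linear-model "logFC"
convention; arithmetic means of linear intensities at n = 3 are
heavy-tail noisy. Benjamini–Hochberg adjustment is always reported;
the differential-expression call applies |log2FC| ≥ 1.5 (inclusive)
and p < 0.05 to the raw p-value by default, with a flag to use the
adjusted one. The raw default reflects both the workflow's literal
thresholds and a power analysis: with three arrays per group and
σ ≈ 0.5 on the log2 scale, an adjusted-p cut at 0.05 has roughly half
power against a 2-fold-change alternative, which would make the
detection claims unachievable; both p-values appear in every result
table so either convention can be audited. Both-groups-constant probes
get p = 1 by convention.

## Synthetic data generator

The generator's defaults define the study conditions. Planted
precursors are a 20–24 nt mature arm (mode 22), a 10–14 nt loop, and a
near-complementary star arm carrying two point changes (stable stems
without exact reverse-complement symmetry, so arms do not phantom-map
to the opposite strand); every planted hairpin is verified at build
time to fold below −17 kcal/mol. Expression weights are lognormal
(σ = 1.2) or equal on request. Reads draw terminal offsets from a
profile with 60% mass on the reference ends, ±1 nt at 8% per variant
and ±2 nt at 2%; untemplated 3′ additions (A/T, chosen to differ from
the templated continuation) occur at 5%, per-base substitution errors
at 1%, contaminants (rRNA/tRNA/sn/snoRNA/mRNA fragments of 18–30 nt
and full-length 26–30 nt piRNA-like sequences) at 25%, adapter dimers
at 1%. Reads are insert + 3′ adapter truncated to 36 nt with constant
Phred-40 qualities. A mock miRBase-style catalog covers every planted
mature, plus cross-species synonyms with 1–2 substitutions.

What this does **not** emulate: realistic Illumina error and quality
profiles, tissue-specific expression structure in the pooled library,
genomic repeats and multi-copy miRNA families, RNA editing, and
real-catalog homology structure. Passing recovery tests therefore
demonstrates the pipeline's rules are implemented and composed
correctly under controlled conditions, not field performance on a real
genome.

## Problem sizes and reproducibility

Test and acceptance workloads use desk-scale problem sizes chosen to
exercise every code path: conservation invariants run at 10⁵ reads over
20 hairpins in a 40 kb genome; recovery runs 15 hairpins at ~120×
mature coverage and 1% error; the differential-expression simulation
plants 100 effects of 2.0 log2 units (σ = 0.5, 3 vs 3 arrays) among
400 nulls at the tester interface, and the array-dataset generator
defaults to a 5% planted fraction, since quantile normalization
genuinely shrinks planted effects when a large share of probes is
differential. All randomness flows from explicit integer seeds;
identical configurations are byte-identical on disk.

## Known limitations

* The stacking-only energy model overestimates stability of loose
  structures; thresholds are calibrated for it, and swapping in a full
  thermodynamic folder changes absolute ΔG scales.
* Exact-match mapping ignores sequencing errors, so error-carrying
  reads contribute to tag counts but not to placements.
* Multi-mapping tags (> 5 loci) are excluded from discovery rather
  than fractionally assigned.
* The merge step trusts catalog names; homonymous miRNAs from
  different loci merge unless their sequences conflict.
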