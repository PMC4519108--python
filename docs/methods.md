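# Methods

`ssrforge` implements in-silico discovery of polymorphic microsatellite
(SSR) markers between two related genome assemblies, together with the
auxiliary analyses that typically accompany such a marker resource: homology
keyword screening, VCF hard filtering with substitution spectra, and panel
summary arithmetic. This note records the models, parameter choices and
numerical conventions, and what the synthetic fixtures do and do not show.

## Repeat model

An SSR locus is a *perfect* tandem repetition of a primitive motif of
period 2–7 bp whose full-copy span reaches `min_tract_len` (default 20 bp).
"Primitive" means the motif is not itself a whole-number repetition of a
shorter unit, so an (AT)n tract is reported once, at period 2, never as
ATAT at period 4; mononucleotide runs are excluded entirely. Imperfect and
compound repeats are out of scope: adjacent tracts of different motifs are
reported separately, and a mismatch terminates a tract.

Detection uses, per period p, the boolean profile `seq[i+p] == seq[i]`; a
maximal run of length m corresponds to a repeat region of raw span m + p.
The tract is anchored at the leftmost base of the run and only whole copies
count: `copies = (m + p) // p`, with any trailing partial copy reported as
`trailing_bp` but never added to `copies` (copy-number arithmetic across
genotypes stays integral). A consequence of leftmost anchoring is that a
flank base completing a motif rotation shifts the reported start by up to
period − 1 bp; motif class and copy number are unaffected, and the
brute-force oracle in the test suite uses the same convention. A final pass
suppresses any locus contained within a locus of smaller period. Motifs are
reported rotation-canonically (lexicographically smallest rotation); the
minus-strand canonical form additionally reverse-complements first, and an
orientation-free form (minimum of the two) is used whenever the relative
strand of two sequences is unknown.

## Contig enrichment

Assemblies enter as plain multi-FASTA over {A,C,G,T,N}; other ambiguity
codes are rejected so the repeat domain stays well-defined. N50 is the
largest contig length L such that contigs of length ≥ L contain at least
half the assembled bases. Enrichment keeps contigs *strictly* longer than
the N50 (an `≥` variant is available by flag); AT/GC composition excludes N
bases from the denominator while lengths include them.

## Primer selection

For each locus, forward candidates are enumerated over the left flank and
reverse candidates over the right flank, within the amplicon window, and
filtered on length 18–24 bp, nearest-neighbor melting temperature 55–62 °C
(Biopython's unified thermodynamic parameters; the Wallace 2+4 rule is
available for quick estimates), GC fraction 0.40–0.60, and homopolymer runs
of at most 4. The winning pair minimizes |Tm_fwd − Tm_rev|, then product
length (100–400 bp, tract contained), then position — deterministic for a
fixed input. When the two filtered candidate lists are large, each side is
truncated to the 120 candidates closest to the Tm-window midpoint before
pairing; this bounds the quadratic pairing step and cannot change the
result when the optimum lies near the Tm midpoint, which is where the
scoring drives it. Returning no pair is an expected outcome (short or
low-complexity flanks), tracked as a failure count rather than an error.

A marker is retained only if both primers are unique: each primer (and its
reverse complement) may occur at most once as an exact substring across the
whole enriched contig set of its genotype. Exact-match uniqueness was
chosen over k-mismatch definitions, which are under-specified and an order
of magnitude costlier. The tailed genotyping chemistry (universal 19-nt
5′ tail on the forward primer, GTTT "pigtail" on the reverse) is available
as verbatim extra report columns only; tails take no part in design.

## Cross-genotype comparison

Matching between genotype contig sets either ingests a 12-column tabular
alignment file (query, subject, %identity, length, mismatches, gap opens,
q/s coordinates, E-value, bitscore), discarding rows above the E-value
ceiling (default 1e-9), or uses the built-in matcher so the pipeline has no
external dependency. The internal matcher is exact-seed (21-mers) and
ungapped: seeds vote for diagonals per (query, subject, strand), the most
supported diagonal is extended with an x-drop rule (+1 match, −2 mismatch,
drop 20), and a hit is emitted when identity ≥ 90% over ≥ 100 aligned bp.
Two guards confine matching to informative sequence: seeds that are
themselves perfect tandem repetitions are masked (the seed-level analogue
of low-complexity filtering), and an alignment must cover ≥ 100 bp of
non-repetitive query sequence — otherwise two unrelated contigs sharing
the same repeat motif can satisfy the length threshold through the tract
alone. Internal hits carry E-value 0.0 as a sentinel. Minus-strand hits
are reported with subject start > end, following the tabular convention.

Each query SSR receives exactly one verdict. Its contig's best hit
(smallest E-value, ties by identity then lexicographic subject id) selects
the partner contig; a subject SSR corresponds if the canonical motifs agree
after orientation adjustment and the query tract midpoint, mapped through
the alignment diagonal, lies within `flank_tol` (default 10 bp) of the
subject tract midpoint. Midpoint-within-tolerance was chosen over exact
coordinate mapping to tolerate small indels and the midpoint shift a
copy-number difference itself induces (half the tract-length delta under
flank-anchored ungapped mapping — the default simulation keeps deltas at
1–2 copies so the worst shift, 7 bp, stays inside the tolerance). The
verdict is *polymorphic* when the tract lengths differ by at least one
period (in perfect tracts lengths differ by whole periods, so this is the
smallest observable difference), *monomorphic* when equal or sub-period,
and *no_match* otherwise. The final panel is the intersection of the
polymorphic calls from both directions, keyed on contig pair and
orientation-free motif; per-direction count tables are kept because
asymmetric best-hits make the two directions genuinely differ.

## Homology screening and positional categories

Keyword exclusion removes sequences whose protein-homology descriptor
contains a blacklist term at or below an E-value ceiling. Matching is
case-insensitive substring matching after stripping non-alphanumeric
characters, so "Retro-Element" ≡ "retroelement". Two presets exist:
transcript panels (ribosomal, retro-element, gag protein, chloroplast,
mitochondria; E ≤ 0.001) and genomic panels (chloroplast, mitochondria,
retroelement, gag protein; E ≤ 1e-9). Each SSR is also categorized against
its sequence's best hit (smallest E-value, lexicographic descriptor
tie-break) as before / after / within the homology region, or no_homology;
*any* overlap counts as within, since partial overlap has no other natural
reading, and a strict-containment variant is one flag away. Panel
reporting folds before/after into a single "outside homology" bin.

## Variant filtering and spectra

Records pass the hard filter when INFO/DP ≥ 10 and INFO/MQ ≥ 30 (inclusive,
site-level annotations as written by samtools/bcftools); records missing
either annotation are dropped and counted. Surviving records are
classified exactly once: biallelic single-base records are SNVs and
increment one of 12 directed substitution cells (strands reported
separately, not collapsed); sites with more than one ALT allele are counted
as multiallelic and excluded from the spectrum; every other biallelic
record (length-changing, and the never-simulated equal-length multi-base
case) lands in the indel bucket. The Ti/Tv ratio is transitions (A↔G,
C↔T) over transversions within the biallelic SNV set.

## Summary arithmetic

Panel rates deliberately use two denominators: percent polymorphic is
computed over markers that amplified (polymorphic + monomorphic), a
property of working markers, while percent failure is computed over all
markers tested. This pairing is the only reading under which the published
marker-panel rate pairs (42/84 polymorphic, 10/2 failure) are simultaneously
consistent, and it is asserted in the tests. Machine output carries two
decimals; display rounding to integers is available separately.

## Synthetic fixtures

The generator emulates two related assemblies with planted truth. Defaults
are 200 planted loci on 800–1200 bp contigs; per locus the verdict is drawn
(no_match 0.1, else polymorphic 0.4, else monomorphic), polymorphic loci
get a copy-number delta of 1–2 in genotype 2, and no_match loci delete the
partner contig. Planted tracts are exactly maximal: flank bases adjacent
to a tract are constrained not to extend it, and each contig is re-sampled
until the detector reports exactly the planted locus — so noise-free
fixtures carry a zero-accidental-SSR guarantee. SSR-free filler contigs of
400–600 bp supply more than half of each assembly's bases, which pins the
N50 below the shortest planted contig and makes enrichment provably retain
every planted locus. Organellar decoys (800–1200 bp, polymorphic tract,
blacklist descriptor at E = 1e-40) exercise the keyword stage, and about a
third of planted contigs get benign annotation hits. An optional per-base
flank substitution rate (0.005 in the noisy suite) models genotype
divergence; mutated contigs are re-verified so the planted tract itself
survives. A companion VCF simulator draws DP from 1–30 and MQ from 10–60
(straddling the filter thresholds), substitution types from a
transition-dominated 12-cell distribution, and omits DP or MQ from a small
fraction of records.

What the fixtures do *not* model: real assemblies contain imperfect and
compound repeats, indel-bearing flanks, paralogy and repetitive families,
and assembly artifacts. Passing the planted-recovery suite therefore shows
the pipeline's logic is correct under its own model, not that real-data
verdict accuracy would be 100%; the published validation rates are the
realistic anchor there.

## Problem sizes and determinism

All randomness flows from explicit integer seeds (numpy `default_rng`);
the simulate CLI requires `--seed` and records it in its output directory.
The standard verification runs use 200 planted loci per genotype pair,
1,000 random 2-kb sequences for detector/oracle agreement (200 in the
acceptance script, which also runs two full pipelines), 1,000 length
multisets for N50, and 1,000-record VCFs — sizes at which every check is
exact rather than sampled-down approximations of itself.

## Known limitations

* Ungapped internal matching: a large indel in a flank truncates the
  alignment at the x-drop boundary; the midpoint rule still pairs tracts
  via the anchored flank, but heavily diverged pairs should be matched with
  an external aligner and ingested as tabular hits.
* No primer thermodynamics beyond Tm/GC/homopolymer: hairpins, dimers and
  multiplex compatibility are out of scope.
* E-values are never computed internally; the 0.0 sentinel means ranking
  among internal hits falls back to identity and deterministic tie-breaks.
* The EST-resource positional categories depend on a single best hit per
  sequence; multi-domain proteins with several distinct homology regions
  are summarized by one region only.
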