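# Methods

This note documents the models, parameter choices and numerical decisions
behind `organedit`, and what the synthetic-data based tests do and do not
demonstrate about real data.

## Read simulation

Reads are drawn from the transcription units of an annotated toy genome
(the top-level, non-intergenic features; introns are sub-features of their
unit). Each read pair comes from an **independent transcript copy**:

1. every configured editing site on the unit is converted C→U with its
   per-site probability (written as T on the transcript sense; in
   plus-strand projection a minus-strand edit is G→A);
2. each intron is excised with probability `spliced_fraction`;
3. with probability `antisense_fraction` the copy is transcribed from the
   opposite strand instead (antisense copies are neither edited nor
   spliced);
4. a fragment of Normal(`insert_mean` = 250, `insert_sd` = 25) nt is placed
   uniformly on the transcript; mate 1 is its first `read_length` = 150 nt
   on the transcript sense, mate 2 the reverse complement of its last
   150 nt;
5. independent per-base substitution errors are applied after editing.

Because copies are independent, the T/(T+C) fraction observed at a site at
coverage *n* is exactly Binomial(*n*, f)/n — the oracle used throughout the
stochastic tests (3-SE acceptance bands). Defaults mirror the library
design the workflow targets: 2 × 150 nt strand-specific pairs with ~250 bp
inserts; base qualities are constant high (quality modelling is not the
subject, and no downstream filter uses qualities); coverage is uniform
along the transcript (no 3′ bias) because every discovery filter is
coverage-threshold based, not shape based. The error-rate default in the
simulation-based tests is 0.002/base, a round value in the range of
post-filter Illumina substitution error.

What the simulator deliberately omits — PCR duplicates, GC bias, indel
errors, rRNA contamination, coverage heterogeneity — means that passing
tests demonstrate the *logic* of the filters (thresholds, strand handling,
wild-type subtraction, masking) and their statistical calibration, not
robustness to real library artefacts.

A separate junction-read generator (`quantify.simulate_junction_reads`)
draws each read from an independent transcript copy (spliced with the given
probability; unspliced copies contribute one of their two borders,
uniformly) and places it so that it always spans the junction. This makes
the spliced fraction among junction reads a plain binomial sample of the
transcript-level fraction. The general read simulator does **not** have
this property: unspliced precursors are longer and carry two borders, so
their junction-read yield per copy differs from spliced copies, which is a
read-sampling fact rather than a bug.

## Reference preparation

Known editing sites are masked to IUPAC `Y` (plus strand) / `R` (minus
strand); the aligner scores a masked base as matching either constituent,
so edited and unedited reads align with identical scores. Masking is
idempotent and invertible given the site list. Inverted-repeat collapse
removes the interior of one IR copy, keeping a 75-nt flank at each border;
features downstream shift left, features straddling a border are truncated
and flagged (`truncated=true` in GFF3), features inside the removed block
are dropped. Which IR copy to remove is the caller's choice — the interval
is an explicit input.

Coordinates are 1-based inclusive in all files and reports; internal
computation is 0-based half-open, with conversion confined to the I/O
layer.

## Alignment

The built-in aligner is a k-mer seed (k = 15, reference indexed at every
position; query k-mers sampled every 5 nt on both strands) plus ungapped
extension. Substitution-only alignment is sufficient because C-to-U editing
is a pure substitution signal, and it keeps the aligner exactly equal to an
exhaustive sliding-window mismatch count — the brute-force oracle asserted
in the tests for reads with ≤ 5 substitutions (a clean 19-nt window is then
guaranteed by pigeonhole for 150-nt reads, so a seed is always found).
Identity = matches / aligned length; aligned fraction = aligned length /
read length; ties in match count break to the leftmost start, then the plus
strand, and reads with more than one best locus are excluded from pileups
(IR collapse removes the dominant source of such ambiguity). Circular
references are indexed over their doubled sequence with positions reported
modulo length.

The strand-specific convention is mate 1 = transcript sense; a fragment's
transcript strand is therefore mate 1's alignment strand (or the opposite
of mate 2's). Pileups key base counts by this transcript strand, with bases
always projected onto the reference plus strand.

Pair selection keeps a pair iff both mates are strictly longer than 100 nt
and at least one mate aligns at ≥ 85 % identity over more than 50 % of its
length; only mates individually meeting those thresholds contribute to
pileups.

## Discovery

SNPs are called per (position, transcript strand) where the most frequent
non-reference base reaches 5 % (inclusive) of the strand coverage, with a
coverage floor of 20 reads (a conventional minimum for a 5 % threshold to
be meaningful; configurable). Two denominators are distinguished and both
reported: the SNP **rate** (alt / full strand coverage), used for the 5 %
filter, and the editing **efficiency** 100·T/(T+C) (equivalently A/(A+G)
for minus-strand transcripts), which is the quantity tabulated per site —
an efficiency of 100 % at fully edited sites is only possible under the
two-allele ratio, which fixes its interpretation. The 5 % cutoff is applied
to both readings, the stricter of the two possible conventions.

Candidates are restricted to C→T (plus-strand transcripts) and G→A
(minus-strand transcripts) — both C→U on the transcript — and positions at
known editing sites or inside tRNA/rRNA features are excluded (those RNAs
are hypermodified by unrelated enzymes). Location classes come from
same-strand feature overlap (CDS > intron > UTR); a site overlapping only
opposite-strand genes is `antisense`, only an annotated intergenic interval
`intergenic_antisense`, nothing `intergenic`.

An off-target site must be edited at ≥ 5 % in at least one
factor-expressing library while the wild type shows < 1 % efficiency. The
wild-type cutoff is 1 % rather than an exact zero because sequencing error
makes exact zero fragile at depth; the wild-type SNP pass runs at a
permissive rate (0.1 %) so sub-threshold wild-type editing can still veto a
candidate. Efficiencies are quantified on uncollapsed reads; duplicate
collapsing (discovery mode) is available separately, because collapsing
identical reads at deep uniform coverage distorts allele fractions.

High-affinity sites are those edited ≥ 5 % in at least one
moderate-expression library; low-affinity sites appear only under
overexpression.

Codon impact is computed on the spliced, strand-oriented CDS sequence:
`X->Y` for an amino-acid change, `STOP` for stop codons, `synonymous` when
the edit is silent, `-` for non-coding positions.

## PPR-code scoring

Binding preference per motif is a pure table lookup on (motif class, key
amino acids), most-specific first (exact class before wildcard). The
packaged default table holds the core two-amino-acid rules
(TN→A, TD→G, SN→A, SD→G, ND→U, NS→C, NN→C/U, VN→A/U); it is configuration,
not hard-coded truth — users supply their own TSV for other codes,
including three-amino-acid variants keyed additionally on position 2. The
two-amino-acid pass is the default headline score; a three-amino-acid pass
is an independent second scoring run.

A cis-element spans −20..+5 with the edited C at 0. The last motif anchors
at −4 and motif *k* of *n* maps to −4−(n−k), so a 15-motif array covers
−18..−4; positions outside the footprint are "unaligned" and positions with
no prediction are "n.p." — neither ever counts toward mismatch totals.
Scorecard row totals equal the sum of per-motif mismatch verdicts by
construction, and this marginal consistency is asserted as a property test.

The degenerate consensus takes, per position, the IUPAC code of all bases
whose frequency reaches `include_threshold` (default 0.25 — the uniform
frequency, so a base must be at least as common as chance to enter the
code); the threshold is exposed because no single value is canonical, and
the edit position is fixed to C.

## Context similarity

Windows of −50..+50 (101 nt) anchored at the edited C are compared by mean
pairwise identity within a sliding 14-nt window, step 1, reported at the
window's left-edge offset (a centered-reporting option would only shift the
x-axis). Excluded positions (0 for [C], −1..+1 for [nCn]) are removed from
numerator and denominator alike. Ambiguity codes never count as identical
(conservative). Removing positions that are identical across all sequences
can only lower the mean — asserted on constructed inputs; when the excluded
positions are variable the inequality need not hold.

## Quantification

Junction classification requires an alignment at ≥ 85 % identity crossing
the junction point with ≥ 10 nt (`min_overhang`) on both sides; 10 nt makes
a chance cross-junction match (4^-10) negligible while keeping most reads
informative. A read matching a spliced and an unspliced reference is
assigned to the higher-identity hit; exact ties are discarded, and a read
spanning both unspliced borders counts once. The splice ratio is
normalised-spliced / normalised-unspliced; fraction and ratio satisfy
ratio = f/(1−f) whenever both are defined, and the ratio is flagged
undefined (NaN) at zero unspliced counts.

RPKM is 10⁹ · reads / (length · library total). ΔΔCt uses replicate-mean
Ct values, ΔCt = Ct(target) − Ct(reference gene), folds = 2^(−ΔΔCt) against
an explicit calibrator or, by default, the sample with the highest ΔCt
(lowest expression), which normalises the minimum fold change to 1.

## Allele scanning

Genotyping is exact 31-mer matching (site base ± 15 nt) of the C and T
variants on both strands. Exactness is a design decision: it replaces
relaxed-threshold database alignment with a primitive whose every call can
be verified by independent substring search; diverged orthologs therefore
return `no_match` rather than a low-confidence call. A sequence containing
both variants is `ambiguous`, never silently resolved; a species with mixed
C and T sequences likewise. The 6-frame peptide scan translates all frames
with the standard code and reports exact peptide occurrences. Editotype
statuses combine the genomic call with transcript-level editing
observations: genomic T (pre-edited), edited C, unedited C, C with unknown
editing status, or no data.

## Problem sizes in the test suite

The simulation-based acceptance checks run at the smallest sizes at which
their statistical claims are meaningful: ≥ 2000× site coverage for
efficiency recovery (3-SE band of ±1.8 points at 92 % editing, ±3.3 points
at 47 %), five libraries over two toy genomes (~34 k read pairs total), and
≥ 5000 junction reads for the spliced fraction (3-SE band of ±1.9 points at
72 %). Toy genomes are 700–900 nt with one CDS; this is sufficient because
every filter is local to a site and none depends on genome scale.

## Known limitations

- No gapped or spliced alignment: junction analysis requires explicit
  junction references, and the trans-spliced intron case of real plastomes
  is out of scope for discovery.
- Statistical testing of differential editing between libraries is not
  performed; the workflow applies plain thresholds by design.
- The default PPR code table is minimal; scoring quality is bounded by the
  code table supplied.
- Editing detection is limited to C-to-U (and its minus-strand projection);
  no indel or other editing types.
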