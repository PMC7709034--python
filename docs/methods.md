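# Methods

## The analysis problem

Forensic whole-mitochondrial-genome sequencing with tiled short-amplicon
panels produces, after alignment, a per-position table of stranded read
counts over the 16,569-nt circular mtGenome. From these counts the analysis
must (i) call a difference-coded haplotype against the rCRS, including point
heteroplasmies, insertions and deletions; (ii) quality-control amplicon
performance and coverage; (iii) assess background signal in negative
controls; (iv) quantify reproducibility across replicates; and (v) detect
and, where possible, deconvolve two-person mixtures. `mitoval` implements
each step as a library module with a thin CLI on top.

## Coordinate model

All positions are 1-based inclusive circular coordinates, the convention of
forensic mtDNA nomenclature. Origin-spanning alignment is modelled by an
extended reference in which the first `min(80, L)` nucleotides are repeated
after the end; `canonical_position` folds extended coordinates back onto the
circle (identity on `1..L`, bijection from `L+1..L+80` onto `1..80`).
Amplicons may wrap the origin (`end < start`). Panel mean length and mean
junction overlap are always recomputed from the amplicon spans; junction
overlap is measured at each circular adjacency separately, so a
two-amplicon panel with one overlapping and one abutting junction averages
the two.

## Variant calling

Calling is purely threshold-based on allele frequency — no quality
recalibration, no statistical noise model. The frequency of an allele (or
the pooled insertion-supporting reads) is its read count divided by total
depth at the position, where total depth sums A/C/G/T/deletion reads;
insertion-carrying reads are a subset of these and are never double-counted.

| parameter | default | meaning |
|---|---|---|
| `php_min` | 0.10 | minimum minor-allele frequency for a point heteroplasmy |
| `ins_min` | 0.30 | minimum pooled insertion-read frequency |
| `del_min` | 0.40 | minimum deletion-read frequency |
| `min_depth` | 20 reads | positions below this are masked, never called |
| `strand_bias_review` | 0.89 | bias above this flags the call for review |
| `mv_min_count` | 3 | mixed-variant sites needed to flag a mixture |

Every threshold is inclusive (`>=`). A consequence worth noting: when the
major allele sits exactly at `1 − php_min` (e.g. 90%) and the minor exactly
at `php_min`, the position is called as a heteroplasmy, not a substitution —
this is what makes the 9:1 mixture boundary detectable. Heteroplasmies are
reported as two-base IUPAC codes (`11562R`); sites with three states above
threshold report the top two plus a multi-allele note in the evidence field.

Strand bias is `1 − min(fwd, rev)/max(fwd, rev)`, computed per allele from
allele-supporting reads by default (a per-position variant pooling all
reads is available via a switch; per-allele is the stricter reading).
Calls exceeding the review bound are *flagged*, never dropped: automated
strand-bias suppression is known to discard true variants near homopolymers
that an analyst would rescue on inspection.

Indels are right-aligned (3'-aligned) within homopolymer tracts, so a
deletion anywhere in the 303–309 C-stretch is named `309del` and insertions
are anchored at the tract end (`309.1C`, `309.2C`, ... expanded from the
dominant inserted sequence, whose fraction is taken over insertion reads
only; ties break to the lexicographically smaller sequence with an explicit
flag). Deletions at poly-C tract ends (`309del`, `315del`, `16193del` by
default) are systematic platform artifacts; `apply_suspect_deletions`
suppresses them post hoc while keeping them in the audit trail, because no
computable rule separates them from genuine deletions — the default list is
configurable. Heteroplasmies whose *minor* allele matches a user-supplied
NUMT catalog are demoted to `posN` uncalled markers (the position cannot be
resolved); a catalogued allele that is the dominant state is left alone, as
near-fixation indicates a true variant rather than nuclear carry-in.

## QC and contamination

Amplicon balance is the amplicon's median depth divided by the median of
all amplicons' median depths (1.0 = balanced). "Median of all amplicons" is
interpreted at the amplicon level (median of per-amplicon medians), which
reproduces the standard worked example (100X/150X = 0.67); even-length
medians take the mean of the middle two values, and overlap positions
contribute to both adjacent amplicons (deconvolving shared reads would need
read-level data). Coverage breadth is the fraction of reference positions
at or above `min_depth`. Relative read depth for a negative control is
`100 × neg/pos` per position against a paired positive; positions where the
positive has zero depth are reported as undefined (NaN), never as 0 or
infinity. The contamination summary averages relative depth across
negatives (sample SD when n > 1), reports the fraction of defined positions
below a configurable bound (default 10%), and flags contiguous above-bound
spans with their overlapping amplicons — localized spans point to primer
artifacts in amplicon overlaps rather than genuine carry-over.

## Concordance

Haplotype comparison excludes positions masked in either source, then
categorises each discordant call with a first-match rule ladder:
`suspect_deletion`, `dominant_variant_differs` (both sources insert at the
same position with different dominant sequences), `threshold_miss` (the
partner pileup carries the state below threshold — requires pileups),
`homopolymer_indel` (indel in or adjacent to a reference tract of >= 4
identical bases — requires the reference), `php_only_one_source`, `other`.
The ladder is ordered so that the known artifact deletions are recognised
as such even though they also sit in homopolymers; every discordance
receives exactly one category. Replicate spread per variant is the maximum
pairwise difference in frequency, computed as `100 × (max − min)`, which
equals the maximum over all pairs; for insertions the same statistic is
also computed on the dominant-variant fraction.

## Mixtures

A mixed variant site (MV) is a position with two or more base states, each
at frequency >= `php_min`, at adequate depth; indels are excluded
throughout the mixture machinery. Three or more MVs flag a mixture (fewer
can be personal heteroplasmies). Deconvolution assigns, per MV, the
higher-frequency state to the major contributor; per-site assignments can
only flip phase when a minor frequency crosses 50%, which falls inside the
near-1:1 indistinguishability band (default: major and minor means within
10 percentage points) that is reported as unresolvable. MVs whose minor
frequency is more than 3 SD from the minor mean are audited as possible
stochastic variation or NUMT carry-in and excluded from the minor
haplotype. The minor haplotype combines the minor MV alleles with the
consensus substitutions shared by both contributors; the effective ratio is
the ratio of major to minor mean frequencies. The band, the SD multiplier
and the MV count are configuration, not biology — laboratories set their
own in validation.

Mixture bench design follows the constant-contributor convention: one
contributor fixed at 2 pg (the "1" side), the other at `2 × a/b` pg for a
target ratio `a:b`, so a 20:1 design totals 42 pg and a 1:10 design 2.2 pg.

## Synthetic data generator

The generator produces the inputs the analysis assumes, with seeded
bit-for-bit determinism:

- **Panel**: evenly spaced, jittered circular tiling with alternating
  pools; defaults of 109 amplicons × ~163 bp with ~11 bp junction overlaps
  tile the full circle. Feasibility requires
  `n × (mean_length + 1 − mean_overlap) >= L` (the +1 absorbs integer
  rounding of amplicon boundaries).
- **Depth**: per-amplicon depth = target median × balance multiplier ×
  log-normal dispersion (σ = 0.25); per-position counts are Poisson around
  the summed depth of covering amplicons, so overlaps run deeper.
- **Alleles**: multinomial over A/C/G/T/del per position; substitution
  miscalls at 0.002 per read-base spread uniformly over the other bases;
  strands split binomially (0.5).
- **Homopolymer indel noise**: at the 3' end of each tract of >= 2 identical
  bases, indel probability `0.005 × tract_length`, split evenly between
  insertion and deletion reads. The rates are calibrated only to reproduce
  the qualitative structure (indels far noisier than substitutions, noise
  growing with tract length); no public quantitative per-tract error rates
  exist for this chemistry.
- **NUMTs**: a fixed absolute read count at catalogued positions,
  independent of mitochondrial depth — nuclear copy number does not dilute
  with mtDNA — so NUMT allele frequencies rise mechanically through a
  dilution series (`25/(25+1280) ≈ 2%` at full input, `25/(25+40) ≈ 38%`
  five halvings later).
- **Mixtures**: each read drawn from the minor contributor with probability
  `mixture_minor_fraction`.
- **Negatives**: Poisson background at a configurable percentage of the
  paired positive's depth, plus hotspot spans with their own relative
  depth, all reads reference-matching.
- **Noiseless mode** (`stochastic=False`): every draw replaced by rounding
  its expectation, giving exact allele frequencies. This is what makes
  threshold-boundary statements sharp: a 9:1 mixture puts the minor at
  exactly 10.0% (called, inclusively) and a 10:1 mixture at 9.09% (not).

What the generator does **not** emulate: read-level artifacts (no read
lengths, no spanning-vs-short-read classification of negatives),
flowgram-level homopolymer signal, alignment/mapping error, primer-binding
SNP dropout (approximated by balance multipliers or deleted spans),
degraded-DNA fragment-length effects, and real NUMT sequence homology
(reduced to a position → allele catalog). Passing tests therefore
demonstrate the *analysis logic* under the stated statistical model, not
platform performance on real libraries.

The shipped reference is synthetic: a seeded random circle of rCRS length
with the canonical poly-C tracts planted at positions 303–309/311–315,
16,184–16,193 and 568–573, which exercises the homopolymer naming and noise
machinery at the familiar coordinates. Real casework uses a user-supplied
rCRS FASTA.

## Numerical choices and degenerate inputs

- Frequencies at zero-depth positions raise `UndefinedFrequencyError`
  rather than returning 0 — absence of evidence is not evidence of absence.
- Even-count medians use the mean of the middle two values.
- Dominant-insertion ties break lexicographically with an explicit flag.
- An empty pileup yields a fully masked haplotype with zero calls; a
  zero-scale negative yields an empty pileup; all-zero amplicon medians
  make balance an error rather than a division by zero.
- Problem sizes in the test suite: full-genome scenarios run at 100–1280X
  median depth with 8–30 injected variants, mixtures at 1000X with 20–25
  differing positions, and a 1,200-nt circle stands in where full length
  adds nothing; these sizes keep the whole suite in seconds while leaving
  every statistical assertion comfortably powered.

## Known limitations

- Deconvolution is frequency-only; it cannot separate near-1:1 mixtures and
  does not use phase, phylogeny, or probabilistic genotyping.
- Strand-bias handling reflects one reading of an underdocumented vendor
  statistic; both per-allele and per-position variants are exposed.
- The suspect-deletion list is a knowledge-based filter, not an inference.
- VCF export is minimal VCF 4.2 (single-sample, site-level INFO only);
  origin-spanning indels are right-anchored at position 1.
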