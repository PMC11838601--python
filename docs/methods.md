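# Methods

`paraloscope` analyses a high-identity, multicopy gene family across phased
haplotype assemblies. Because real pangenome assemblies are far beyond desk
scale, every analysis is exercised against a synthetic-data generator with a
machine-readable truth set; the generator is first-class, tested code, and its
defaults define the study conditions used throughout the test suite. This note
records the models, the parameters that matter, the numerical choices, and
what the synthetic experiments do and do not establish.

## The synthetic family

The generator (`synthdata`) builds diploid samples whose haplotypes carry a
~20 kbp duplicon in 1 to several copies, arranged along a locus template of
paralog and unique marker-gene tokens separated by 35 kbp of unique spacer
sequence.

* **Divergence structure.** A random ancestral locus is mutated into
  subfamily consensuses (0.8% substitutions), then paralog consensuses (1%
  private substitutions each, giving ~2% inter-paralog divergence, inside the
  0.3–5% range typical of recent segmental duplications), then per-copy
  sequences (0.1% copy-private substitutions). Mutations are substitutions
  only, so copies stay colinear with the ancestor and paralogous sequence
  variants (PSVs) can be tracked exactly; the only length changes are the
  VNTR insertions recorded per copy.
* **Gene model.** Four exons (total 4.5 kbp, lengths divisible by three) are
  overwritten with a stop-free CDS starting ATG. Substitutions inside the CDS
  re-draw the base whenever the new codon would be a stop, so open reading
  frames survive the mutation process; the first four codons encode a
  paralog-specific start class (MFCC/MVKL/MRVR/MRLR).
* **IGC.** Per haplotype, Poisson(1) interlocus gene-conversion events pick a
  random acceptor copy and a donor paralog from the same subfamily, and
  replace a tract (exponential length, mean 3 kbp, minimum 500 bp, snapped
  outward to codon boundaries inside the CDS) with the donor consensus.
* **Inversions.** One polymorphic inversion (allele frequency 0.4) reverse-
  complements the token interval between two flanking markers, flipping the
  embedded copies to the reverse strand.
* **VNTR.** Copies of one paralog (B3) receive an in-frame repeat array:
  a SADD-frame run of 7–15 units (19- and 23-residue unit types alternating),
  a 25-residue MIISR-frame run of 6–14 units, and a second SADD run of 5–11
  units, inserted at a codon boundary in the final exon.
* **Random streams** are namespaced per component (ancestor, paralogs,
  copies, IGC, inversion, VNTR, spacers, reads, coalescent), so enabling one
  feature never perturbs another's draws, and a fixed config is byte-
  reproducible.

Default scale: 20 samples (40 haplotypes) from two labelled populations, six
paralogs in two subfamilies, ~270 copies overall. These problem sizes keep
the full simulate–discover–classify round trip comfortably within an
interactive session while leaving every statistic enough data to be
calibrated.

**What the generator does not emulate:** assembly errors and gaps, indel
mutation, GC- and mappability-biased read depth, recombination within
windows, base-quality structure, and library-preparation biases. Passing
tests therefore demonstrate the correctness of the implementations under the
stated generative model, not performance on real assemblies.

## Copy discovery and validation

Homology search is shared-k-mer anchor chaining (k = 21, every third position
probed) against the ancestral query. Anchors are clustered along the
haplotype with gaps under 5 kbp merged (so a VNTR insertion does not split a
copy), cluster extents are extrapolated to full query boundaries, and hits
are kept when the anchored query span reaches 15 kbp and the estimated
identity is at least 80%. Identity is estimated as f^(1/k) from the matched
k-mer fraction f, which is unbiased under uniform substitution divergence;
the approach is adequate below ~10% divergence, where k-mer anchors remain
dense. A locus passes validation when the contig provides 30 kbp of copy-free
flank on both sides.

Read-depth copy number follows the segment-matching design: reads are cut
into non-overlapping 36 bp pieces, placed at every reference position within
Hamming distance 2 (found exactly by pigeonhole seeding with 12-mers), with
multi-mapping pieces contributing fractional weight 1/sites — this preserves
depth linearity inside duplications. Window copy number is scaled so
designated copy-number-2 control windows average 2; the gene-level value is
the median over non-excluded windows. The collapse flagger marks clusters
(two or more within 500 bp) of pileup positions whose second allele reaches
five reads and 10% frequency.

## Paralog assignment

Distances are p or Jukes–Cantor distances over ancestral-coordinate
projections of each copy (anchor runs transfer whole segments so
substitution columns between anchors are preserved; unanchored bases are `N`
and excluded pairwise). Neighbor joining is implemented in-package so that
tie-breaking is deterministic (lexicographic on clade leaf labels; Q-matrix
evaluated on the upper triangle only because floating summation order can
differ across the diagonal by one ulp); negative branch lengths are clamped
to zero and trees are midpoint-rooted. Support is the bootstrap proportion of
column-resampled NJ replicates containing the same bipartition (100
replicates), used as the clade-confidence surrogate; clades with support
above 75 containing exactly one anchored reference copy inherit its label.
Anchors whose tight clades interleave, or that sit closer than the merge
distance (default: three times the median intra-clade distance of the
anchors' tightest supported clades), merge into joint "X/Y" labels; supported
anchorless clades take the nearest anchor's label with an "L" suffix,
numbered by descending clade size. Strict-clock dating assigns each node the
age `root_age × height/root_height`, with heights the mean distance to
descendant leaves and the tree rooted at the outgroup attachment point; ages
are clamped to be monotone root-to-leaf. This proportional rule is exact for
ultrametric trees and is validated on clock simulations only — it is not a
substitute for rate-relaxed dating.

## Structural configurations and DCJ-indel distance

A haplotype's configuration is its ordered, signed string of paralog and
marker tokens (features ≥ 1 kbp), flipped so the distal marker leads.
Distances between configurations use the double-cut-and-join (DCJ) model with
indels: DCJ operations (through circular intermediates) and insertions or
deletions of contiguous runs of tokens private to one string each cost one.
Duplicate token names are disambiguated positionally (k-th occurrence to k-th
occurrence; leftovers become indel runs) — exact matching of arbitrary
multiplicities would require integer programming, and positional matching is
always cross-checked against the exhaustive oracle in the tests. The closed
form is the adjacency-graph formula `d = N − C − I/2` plus an indel potential
of ⌈(λ+1)/2⌉ per component, where λ counts maximal same-genome private runs
met along the component (empty adjacencies skipped, cyclic merge on cycles).
Path components can in principle recombine runs across components; those
corrections are not implemented because marker-anchored configurations —
the only kind this package encodes — keep runs off the telomere paths. The
independent reference is a bidirectional breadth-first search over
adjacency-set genome states with the same move set, feasible for instances up
to ~8 tokens. Inversion calls compare only tokens unique in every encodable
configuration (in practice the marker genes), so copy-number variation cannot
destabilise the interval keys.

## Selection statistics

Assembly-versus-reference SNP calling keeps biallelic substitution columns,
polarized by an outgroup allele when it matches one of the two alleles.
Tajima's D uses the standard constants and is reported as missing (never
zero) for windows without segregating sites, so percentile tails are not
diluted. Windows are non-overlapping 30 kbp tiles, which keeps the
percentile null independent across windows.

nS_L follows the haplotype-homozygosity definition: for each polarized site,
SL_A (SL_D) is the mean, over ancestral- (derived-) carrying haplotype pairs,
of the number of consecutive segregating sites in the maximal interval of
pairwise identity containing the site; the unstandardized score is
ln(SL_A/SL_D), so sweeps on the derived background give negative scores (the
standard sign convention). Scores are standardized to zero mean and unit
variance within derived-allele-frequency bins (up to 100; identical
frequencies share a bin). The standardization reference matters: a selection
scan normalizes against the chromosome-wide, predominantly neutral
background, so `nsl_scan` accepts an explicit normalization set; fitting the
bins on an evaluation set that is half sweeps would normalize the sweep
signal away. The window statistic is the fraction of scored sites with
|standardized score| > 2, computed for windows with at least 10 scored sites.

The neutral null is a hand-rolled Kingman coalescent without recombination
under the infinite-sites model, with mutations Poisson(θ/2 × total branch
length) so that E[π] = θ and E[S] = θ·a₁ (both verified in tests). The sweep
null ("star" mode) models an ongoing hard sweep: a carrier fraction (default
0.75) coalesces simultaneously with 0.01-unit terminal branches, and the
carrier-clade root joins the remaining lineages in a neutral coalescent.
The default fraction was chosen because a literal complete star leaves every
variant a singleton — informative for Tajima's D but with no derived-carrying
pairs for nS_L to score; 3/4 keeps the site-frequency spectrum strongly
skewed (mean D ≈ −1.2 at n = 20, θ = 10) while leaving nS_L enough scorable
sites. `sweep_freq=1.0` recovers the literal star.

## Transcripts and the VNTR

Long-read assignment is exact-seed (13-mers), diagonal-chained spliced
alignment with diagonal gaps of at least 30 bp treated as free introns; split
points between adjacent diagonals are chosen to minimise mismatches. A read
is uniquely assigned when the best locus beats the second best by at least
one mismatch; ties are ambiguous, and reads covering under half their length
are unaligned. This assumes indel-free reads with clean junctions, which the
generator provides; it is not a general spliced aligner. Gene models require
five supporting molecules and at least two exons, ranked by abundance then
length. ORF calling scans the three forward frames (full-length cDNA is
orientation-resolved), returns the longest ATG-initiated ORF (open ORFs run
to the last complete codon), breaks ties 5′-most, and floors at 50 codons —
the family's proteins are all longer.

Protein VNTR segmentation anchors unit starts at "SADD" (S frame) and at
"ISR" two residues into the MIISR-frame unit, requires tandem contiguity
(next start = current start + unit length, at most 60 aa), and reports the
unit counts (a, b, c) of the first SADD run, the MIISR run and the second
SADD run of the longest tandem segment. DNA-level arrays are found by offset
self-matching: the longest span where seq[i] = seq[i+p] for at least 90% of
positions, over periods of 40–300 bp, edge-trimmed (the average criterion
would otherwise absorb short random flanks) and filtered to fundamental
periods of at least 40 bp so that, e.g., a 30 bp unit matching at offset 60
is not reported.

## Expression quantification

Gene-model 31-mers absent from the background genome are indexed in
canonical (strand-collapsed) form and annotated with the set of paralogs
containing them. Paralog groups are merged iteratively — most deficient
group first, joined to the group sharing most of its k-mers, ties
lexicographic — until every group has at least five uniquely identifying
k-mer positions. A read is assigned to a group when it contains a k-mer
unique to that group and none unique to any other; reads with unique k-mers
of two groups, or only shared family k-mers, count as family-ambiguous
(never double-counted), preserving classified ≤ total. Shares are computed
against family-classified totals; enrichment z-scores compare a group's
share in one sample against its cross-sample mean, with one-sided normal
p-values and UPGMA (correlation-distance) clustering. By default the
quantification transcript pool excludes the repeat array itself: tandem
repeats are internally multi-copy, so their k-mers occupy many transcript
positions and would make the VNTR-bearing paralog disproportionately
classifiable, biasing its share upward (group-constant biases cancel in
z-scores but not in shares).

## Numerical and degenerate-input choices

* Coordinates are 0-based half-open everywhere; GFF3 I/O converts to 1-based
  closed.
* JC69 distances raise at p ≥ 0.75; gap/N columns are excluded pairwise.
* NJ on fewer than three labels raises; configuration trees on fewer than
  three configurations return a trivial star.
* Empty-versus-nonempty configuration distance equals the nonempty side's
  run count (one deletion per contiguous private run).
* Windows with S = 0 yield missing Tajima's D; sites where one allele class
  has no pairs, or either mean SL is zero, are skipped by nS_L; zero-variance
  bins yield missing z-scores.
* Rank-sum population comparisons use the normal approximation
  (`scipy.stats.ranksums`); groups of size one are legal but powerless.

## Known limitations

The discovery stage cannot separate tandem copies closer than the anchor
merge gap (5 kbp) and is blind above ~10% divergence. The DCJ closed form is
exact only for anchored configurations. The aligner does not model indels
within exons. The coalescent null lacks recombination, so nS_L here measures
mutation-interrupted identity rather than recombination-limited haplotype
length; its calibration on real, recombining data is not claimed. Dating
assumes a strict clock.
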