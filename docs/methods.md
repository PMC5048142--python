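# Methods

## The exon model

The analysis treats the zinc-finger-domain exon as two parts: a
conserved 5' region and a 3' array of tandem 84-bp C2H2 repeat units.
A canonical repeat encodes 28 residues with zinc ligands C1/C2/H1/H2 at
residues 1/4/17/21 (template `C-x2-C-x12-H-x3-H`). Recognized departures
from the canon are: a substituted ligand (`DEGENERATE_LIGAND`), codons
falling in a shifted reading frame (`FORMER_FRAMESHIFTED`, a flag owned
by the indel analysis), a 25-residue array-leading fragment that lacks
the first cysteine codon (`TRUNC_5PRIME`, 9 bp shorter than canonical),
and an array-terminal fragment cut by a stop codon that still retains
C1, C2 and at least H1 (`TRUNC_3PRIME`).

**Helix coordinates.** The recognition helix is placed so that H1 sits
at helix position +7; the helix therefore starts at residue 11 and the
numbering skips zero, as usual for C2H2 fingers: residue 10 is −1 and
residues 1..28 map to −10..−1, 1..18. The DNA-contacting triplet is
(−1, 3, 6) = residues 10/13/16; the quadruplet adds position 2
(residue 12). Reports emit both the raw residue index and the helix
coordinate. These offsets are a documented convention (module constants)
— the operational content is only that the same four codons are used
everywhere (masking, fingerprints, selection labels).

**Segmentation** translates frame 0, scans greedily left-to-right for
28-residue windows whose four ligand positions match the template
(windows with exactly one substituted ligand are reported too, so
degenerate fingers are seen; the scan resumes at a window's end after a
match). The C2H2 array starts at the first canonical finger of the
contiguous run containing the most canonical fingers; everything
upstream is the 5' region. Frame excursions are never guessed here —
the exon's frame 0 is taken as annotated.

## Indels and the A/a/α allele scheme

Queries are globally aligned to the reference (affine gaps: match +1,
mismatch −1, open −4, extend −1 — fixed so indel coordinates are
reproducible; the aligner's first optimal alignment is taken, which
prefers mismatches over gaps and places gaps leftmost among ties).
Maximal gap runs become indel events with `shift = length mod 3`.
Compensatory pairing is strictly two-member and greedy: a frameshifting
event pairs with the nearest downstream frameshifting event that returns
the cumulative shift to zero; anything else is residual (multi-event
restorations are flagged, not guessed). Allele labels follow from the
events alone: no frameshifting indels → wild-type **A**; an unpaired
frameshifting indel → disrupted **a**; all frameshifting indels absorbed
in ≥1 pair → restored **α** (with a check that translation downstream of
the pair matches the reference). Genotype fertility: A/A and α/α
functional, a/a sterile, every heterozygote subfertile.

## Alleles and fingerprints

Alleles are defined on the amino-acid level and restricted to the C2H2
array: two sequences carry the same allele iff their concatenated array
peptides are identical, so synonymous changes collapse. Ligand-degenerate
fingers inside the array (e.g. a terminal H→N finger) are excluded from
the C2H2 count but retained in the binding-triplet fingerprint with a
degenerate flag. Fingerprint rows also flag fingers whose non-binding
residues differ from the modal peptide of that triplet (the "dot"
semantics of substitutions away from the shown binding residues).

## Phylogenies

Finger rows are deduplicated within groups (identical sequences in
different genera stay separate), codon-aligned to the 28-codon frame
(75-nt 5'-truncated fingers are right-aligned with three leading gap
codons, shorter 3' fragments padded on the right), and the four binding
codons are excised — 12 nt, leaving 72 columns for a canonical finger
(63 informative nt for a 75-nt finger). Distances are Kimura (1980)
two-parameter, `d = −½·ln((1−2P−Q)·√(1−2Q))`, with transition/
transversion proportions over pairwise complete sites (gap/N columns
pairwise-deleted). Saturated pairs (preconditions violated) raise an
error, or take a configurable ceiling (5.0 during bootstrap). Trees are
canonical Saitou–Nei neighbor joining; ties on the Q-criterion break to
the lowest (row, col) index pair and negative branch lengths clamp to
zero. Bootstrap resamples columns with replacement; the support of an
internal edge is the fraction of replicate trees containing its leaf-set
bipartition; nodes below 0.5 (default) collapse into polytomies. K80+NJ
with bootstrap is this package's desk-scale inference choice — the
support semantics (collapse < 0.5) are preserved, maximum-likelihood
inference is not attempted.

## Sitewise selection scan

Per codon column, synonymous/nonsynonymous sites and substitutions are
counted by the Nei–Gojobori (1986) pathway method: site fractions from
the standard code with mutations to stops excluded; multi-step codon
differences averaged over stop-free shortest mutational paths (all-stop
path sets fall back to including them). Proportions are Jukes–Cantor
corrected (`d = −¾·ln(1−4p/3)`); ω = dN/dS, flagged infinite when
dS = 0 < dN. Neutrality is tested per site with a two-sided exact
binomial test of the (rounded) nonsynonymous substitution count against
the neutral expectation `N/(S+N)`; p-values are Benjamini–Hochberg
corrected across the 28 sites. POSITIVE requires ω > 1 and q < 0.01,
NEGATIVE ω < 1 and q < 0.05 (both configurable).

**Comparison set.** By default each sequence is compared to the
codon-wise consensus of its column — the edge set of a star tree centred
on the consensus — so each substitution is counted approximately once
and the binomial test is calibrated (measured neutral type-I ≈ 3–5% at
nominal 5%). Accumulating over all sequence pairs instead counts every
substitution once per pair that contains it (≈ n−1 times), which
inflates the test's nominal sample size and pushes the neutral
false-positive rate to ~70%; the `pairs` mode is retained for
exploration with that caveat written into the output header. Pairwise
or consensus counting also overweights shared ancestry on structured
samples, which is why the validation simulations are star-shaped.

**Power and the simulated divergence.** The recovery simulations evolve
each sequence independently from a common ancestor, per codon, with
single-nucleotide changes at rate 1 (synonymous) or ω (nonsynonymous),
scaled to an expected 0.5 substitution events per codon per edge — a
divergence at which binding-site signal is not yet erased by multiple
hits. A power analysis shapes the design: histidine ligand codons offer
almost no synonymous mutations (expected nonsynonymous fraction ≈ 0.89
vs. ≈ 0.72 under ω = 0.1), so a reliable per-site deficit call needs on
the order of 70 observed substitutions, while binding sites (4× the
neutral substitution rate at ω = 5) saturate beyond ~1–2 events per
codon per edge. No single divergence makes a 40-edge design work; at
300 sequences and 0.5 subs/codon the scan recovers POSITIVE at exactly
the three binding sites and NEGATIVE at the ligands in ≥ 90% of seeds.
The property tests and the acceptance script therefore use the powered
300-sequence design (the acceptance script also reports the 40-sequence
rates, which are near zero — a measured limitation of the counting
statistic, not a tuning target).

## The synthetic-data generator

`make_reference_exon` builds a leader (cysteine/histidine-free, so it
cannot seed spurious finger windows), one ligand-degenerate finger
(C1→S), a 12-nt spacer, k ∈ [3, 12] canonical repeats with randomized
binding residues, and a terminal stop. The spacer is engineered to
contain a stop codon in **every** shifted reading frame but none in
frame 0, which makes premature-stop detection in disrupted alleles
deterministic. `evolve_allele_pool` applies per-replication-round repeat
duplication (0.08) and loss (0.05) as in-register whole-unit events, and
point substitutions at 0.002/site/round with a 5× multiplier at the
binding codons (ligand codons held fixed, stop-introducing changes
rejected); every allele carries an event log that replays byte-exactly
to its sequence. Defaults mirror the study system: arrays of 3–12
repeats whose alleles differ mainly in repeat number and little in
sequence, with elevated nonsynonymous change at the binding triplet.
All generators are pure functions of (config, seed).

What the simulations do not emulate: unequal crossing-over (duplication
is whole-unit only), shared genealogy within populations (star-shaped
histories), sequencing/phasing error (inputs are resolved allele
sequences, as after cloning), and selection acting on repeat number.
Passing tests therefore demonstrate correctness of the operations on
data with the assumed structure, not robustness to tree-shaped
dependence or alignment ambiguity in real data.

## Numerical choices and degenerate inputs

- Coordinates: 0-based half-open internally, 1-based inclusive in all
  user-facing tables.
- Translation: standard code; stops are data (`*`), codons containing N
  give `X`; non-IUPAC characters are input errors.
- K80 preconditions `1−2P−Q > 0`, `1−2Q > 0` raise a saturation error by
  default; bootstrap substitutes a ceiling of 5.0 substitutions/site.
- Binomial test counts are rounded to integers; a site with zero
  substitutions, or zero sites, is UNDETERMINED with p = 1.
- BH adjustment uses the standard step-up with monotonicity enforcement.
- Allele IDs are species-prefix + first-seen ordinal; the partition of
  sequences into alleles is invariant under input permutation, the IDs
  are not.
- Problem sizes in the test suite and acceptance script: 200 seeded
  exons for the segmentation round trip, 100 seeded indel pairs, 50
  random 5–8-leaf additive trees, 100 bootstrap replicates, 100
  selection seeds at 40 and 300 sequences.

## Known limitations

- The indel caller reports the aligner's leftmost-equivalent placement;
  homopolymer-adjacent indels can legitimately shift by a few bases
  relative to the mutational event.
- Compensatory pairing is two-member only; three or more jointly
  restoring events are flagged residual.
- The selection scan is tree-free; on phylogenetically structured
  samples its counts overweight shared branches, and its per-site power
  at small sample sizes is limited (see above).
- The published genotype table ships without sequences (none are
  packaged), so analyses that need nucleotides run on simulated data.
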