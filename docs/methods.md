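# Methods

## The SD/aSD pairing model

Bacterial translation initiation is guided by base pairing between the
Shine-Dalgarno (SD) sequence upstream of the start codon and the free 3'
end of the small-subunit rRNA (the 3'TAIL).  A tail is represented 3'->5'
(`AUUCCUCCACUAG` for *E. coli*; `UCUUUCCUCCACUAG` or `AUCUUUCCUCCACUAG`
for *B. subtilis*, depending on how far 3'->5' exonucleolytic maturation
has trimmed the end).  Pairing is strict Watson-Crick (A-U, G-C); G·U
wobble is excluded because every species-specific motif in the published
inventories is a perfect complement.  The set of SDs a tail can bind is
exactly the set of substrings, length >= 4, of the tail's complement
string read 5'->3'.

**Species-specific inventories.**  A motif is specific to one tail when
it is a substring of that tail's complement string and not of the
other's.  For the Ec-13 / Bs-UCU-15 pair this partitions motifs into one
*E. coli* series (UAAG-led) and three *B. subtilis* series (AGAA, GAAA,
AAAG); the 16-nt AUCU tail adds a UAGA series and changes no shared
motif.  The shipped canonical inventories (7 SD_Ec, 25 SD_Bs motifs)
realise the published tables as per-series maximum-length caps on the
pure enumeration (Ec: UAAG <= 10 nt; Bs-UCU: AGAA <= 11, GAAA <= 12,
AAAG <= 11; Bs-AUCU adds UAGA <= 12).  The published inventories are
internally inconsistent about these caps (6 vs 7 *E. coli* motifs, 36 vs
25 *B. subtilis* motifs, depending on which table one reads); we ship the
sets used for the count tables and leave the caps configurable.

## D_toStart

For a match spanning tail positions `s .. s+L-1` (1-based from the 3'
terminus) with `g` bases between its 3' end and the start codon,

    D_toStart = g + L + s

is the distance from the first start-codon base to the mRNA position
opposite the tail's 3' terminus under rigid projection of the full tail.
Unlike `g`, it measures where the ribosome is positioned regardless of
which part of the tail the SD engages.  The formula is calibrated by two
facts: extending the *B. subtilis* tail from 15 to 16 nt shifts every
D_toStart by exactly +1, and detected genomic values concentrate in the
published optimal windows.  Defaults: 10-22 (Ec-13), 12-23 (Bs-UCU-15),
13-24 (Bs-AUCU-16); these windows are equivalent under the +-1 shift and
are configurable (a published phage table used 10-21 / 15-25, also
expressible as a `WindowSpec`).

**Detection.**  All maximal common substrings (length >= 4) between the
30-nt upstream window and the complement string are enumerated per
(window position, tail position) diagonal; embedded sub-matches of a
longer run are not emitted separately.  Matches may not overlap the
start codon (`g >= 0`), and pairings extending 5' of the window are
truncated at the window edge.

**Per-gene call.**  One gene contributes at most one count: the longest
in-window match, ties broken by smaller D_toStart, then by the more
start-codon-proximal placement.  A secondary, non-overlapping match is
reported only in the phage report (genes can carry a species-specific
and a shared SD side by side).  Proportions are counts divided by the
number of included (non-pseudogene) CDSs, printed to 4 decimal places.

## Genome input

GenBank coordinates are 1-based inclusive; the upstream window is the 30
bases strictly 5' of the start codon, reverse-complemented for
minus-strand genes, transcribed to RNA on read.  Circular topology
(LOCUS line) wraps the window across the origin; linear contigs truncate
it.  Compound (join) locations use the 5'-most segment's start in gene
orientation.  Pseudogenes are parsed but excluded from all counting.
The *E. coli* annotation-derived gene inventory is reported ambiguously
in the source material (4139 vs 4143 vs 4144 included genes); the
package always reports its own count and uses 4144 / 4175 as the
published-statistic defaults, which reproduce the published CDS-weighted
chi-square exactly.

## Chi-square nulls

Three nested df=1 Pearson goodness-of-fit tests compare a motif class's
hit counts between species, with no continuity correction (the published
equal-split and CDS-weighted values, 48.9529 and 50.3648 on the SD_Ec
counts, reproduce exactly only without Yates correction):

1. equal — expected 50:50;
2. CDS-weighted — expected proportional to included CDS counts;
3. composition-weighted — expected proportional to
   `N_CDS,s * sum_m prod_{base in m} P_base,s`, the CDS count times the
   total i.i.d.-composition probability of the motif set.  Window length
   and positional availability are deliberately ignored; the null is a
   pure product-of-frequencies model.

With the published 4-decimal base frequencies this third statistic
evaluates to 102.96 on the SD_Ec counts (the acceptance script computes
it at run time); the published value 103.07 evidently came from
unrounded genome frequencies, which cannot be recovered from the printed
inputs.  A sweep over the plausible variants (alternative inventory
caps, alternative CDS totals, placement-count or occurrence-probability
weighting) moves the statistic by at most ~0.1 and none lands on 103.07
exactly.

## Cochran-Armitage trend test

For a 2 x k table of strata over ordered SD-length bins with scores
`s_j` (default: the bin's SD length), the statistic is the classic
asymptotic form used by R's `prop.trend.test` (variance with an `N`
denominator, no continuity correction).  Implementations that use the
permutation variance (`N-1` denominator, as the `coin` package) differ
by a factor `N/(N-1)` — negligible at genomic table sizes.  Tests
cross-check the statistic against the identity `X^2 = N r^2` (Pearson
correlation between score and row membership over individual
observations) and against a seeded permutation null; the permutation
comparison uses mid-p because the permutation distribution has large
discrete atoms on small tables.

## I_TE

The index of translation elongation is a codon-adaptation index that
corrects for background mutation bias.  Relative adaptiveness within
each synonymous (sub)family — sixfold families split into fourfold and
twofold subfamilies — is the codon's observed frequency in a
highly-expressed reference set divided by its expected frequency under
the genomic base composition at the third position, rescaled to max 1;
zero counts are floored at 0.5 observations.  A gene's I_TE is the
geometric mean (accumulated in log space) of `w` over its codons,
excluding start/stop codons and the single-codon families Met and Trp.
The exact weighting scheme behind the published scores is defined only
by its software implementation; the ratio-to-background scheme above is
this package's explicit operationalisation, and externally supplied
`CodonWeights` can replace it.

## Expression strata

HEG/LEG: top and bottom 10% of genes ranked by protein abundance or
I_TE, tie-broken by gene id on a single ranking (so boundary ties can
never land in both strata).  The published wording is ambiguous about
whether the strata required both metrics simultaneously; the default
stratifies per metric.

HTE/LTE: ordinary least squares of log10(protein) on log10(mRNA) —
log scale because abundances span orders of magnitude — with the 200
most positive / most negative residuals labelled HTE / LTE.  Genes
missing either measurement are excluded, not zero-filled.  In the
noiseless limit recovery of the true efficiency ranking is exact up to
the O(sigma_e / (sigma_mRNA * sqrt(n))) finite-sample error of the
fitted slope, which can swap genes immediately at the rank boundary.

## Synthetic data

The generator emulates the study inputs with full ground truth:

* **Genomes** — `n_genes` CDS cassettes (spacer | 30-nt upstream window
  | ATG | body | TAA) on random strands, windows i.i.d. from a
  configurable base composition with motifs planted at exact (motif, g)
  positions; written as GenBank plus a TSV truth table.  Chance
  background hits are not suppressed; the truth table flags plantings
  that a chance hit outranks.  A single integer seed drives one RNG
  stream, so outputs are byte-identical across runs.
* **Expression** — log10 mRNA ~ Normal(1.5, 0.6) on the RPKM scale; a
  per-gene efficiency multiplier either i.i.d. (log10 sigma = 1.0,
  matching the ~3-4 orders of magnitude spread of protein-per-mRNA
  ratios observed in *E. coli*; narrower spreads are not separable at a
  top-200 cut under 10% measurement noise) or tied to SD length
  (log10 efficiency = 0.1 * (L - mean L)); protein = mRNA * efficiency *
  mean-one lognormal noise with CV 0.10.

What the synthetic data does **not** emulate: real intergenic
architecture (operons, overlapping genes, leaderless mRNAs), realistic
codon usage beyond a configurable skew sampler, secondary structure
around the TIR, and the shared evolutionary history that couples SD
usage to expression in real genomes.  Passing tests therefore
demonstrate correctness of the machinery and calibration of the tests
under the stated generative model, not biological conclusions about real
genomes — those require the annotated genome and abundance inputs.

## Problem sizes and numerical choices

The analysis scripts use 1500-gene genomes and 5% strata; the simulation
studies in the test suite use 1000 random windows per tail for the
brute-force equivalence, 500 null replicates at n=2000 for the trend
test's type-I error, 100 replicates at n=4000 for its power under the
planted SD-length effect, and 5 replicates at n=4000 for HTE recovery.
Ties everywhere are broken deterministically (gene id order); RNG
streams are numpy `default_rng` seeded explicitly.  Degenerate inputs
raise: empty sequences, zero-total counts, zero row margins or
zero-variance scores in trend tables, SDs overlapping the start codon.

## Known limitations

* The composition-weighted null cannot reproduce the published 103.07
  from printed-precision inputs (see above); the package reports 102.96.
* Leaderless mRNAs and SDs 5' of the 30-nt window are out of scope.
* The phage "nonhypothetical" filter is a configurable product-keyword
  list, since no formal definition is published.
* I_TE weights depend on the chosen reference set; shipped defaults are
  synthetic demonstrations, not organism reference files.
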