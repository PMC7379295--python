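# Methods

`bilmap` analyzes backcross inbred line (BIL) populations: collections of
lines that each carry a handful of homozygous wild-species (donor) segments
in a cultivated (recurrent) background, produced by backcrossing an
interspecific F1 to the recurrent parent and then selfing to
near-homozygosity. This note records the models, conventions and numerical
choices behind each stage, and what the simulation-based tests do and do not
establish.

## Genotype model and coordinates

Genotypes are categorical calls per line and SNP marker: `A` (homozygous
recurrent), `B` (homozygous donor), `H` (heterozygous), `U` (missing).
Markers are anchored to a physical map (chromosome, 1-based bp); all
intervals are closed `[start, end]`. Source files with other encodings are
translated through an explicit recoding map at read time, never silently.

## Introgression calling

A donor segment is a maximal run of donor-informative calls (`B` or `H`)
along a chromosome. Missing calls are transparent: they neither break nor
extend a run, and borders are computed from informative calls only. This is
the least-assumption treatment of sparse no-calls; it implies a segment can
silently span a long run of missing markers, which is the price of not
modelling genotyping error.

Borders use the half-way convention: an interior border lies at the floor of
the midpoint between the outermost donor-informative marker and the nearest
flanking recurrent marker. The start side of a segment takes the base pair
*after* that midpoint — a deterministic 1-bp convention chosen so that
segment intervals and mapping-bin intervals (below) share exactly the same
boundaries and tile without overlap; at megabase scale the choice is
irrelevant but it must be fixed. A run that reaches the first or last
informative marker of a chromosome extends to the chromosome tip (position 1
or the chromosome length).

Zygosity is `homozygous` (all `B`), `heterozygous` (all `H`) or `mixed`.
Heterozygous calls are donor-informative for segmentation so that a
homozygous BIL and its hybrid (the same line crossed back to the recurrent
parent, rendering every segment heterozygous) yield identical segment
coordinates.

Population summaries follow the convention that per-line means and medians
are taken over lines carrying at least one segment; lines with none are
counted separately. Genome coverage is the union of all segments across
lines divided by the summed chromosome lengths.

## Mapping bins

Adjacent markers whose genotype columns show no recombination event in any
line merge into one bin. A missing call is a wildcard (it matches anything);
because the wildcard relation is not transitive, merging is a greedy
left-to-right scan anchored on the running consensus column: a marker joins
the current bin iff, for every line, its call equals the consensus or one of
the two is missing, and the consensus absorbs non-missing calls as it goes.
Equivalently, a bin is a maximal run in which no line has two different
non-missing calls — the form used by the set-based test oracle. Bin bp
intervals tile each chromosome with the same midpoint/tip rules as segment
borders, so QTL intervals can be reported in physical coordinates.

## Genetic map

The recombination fraction between two bins is estimated as the fraction of
doubly non-missing lines whose donor state differs, with `H` collapsing to
the donor state, capped at 1/2. Distances use the Haldane map function by
default (`d = -50 ln(1 - 2r)` cM); Kosambi is selectable. A new linkage
group starts wherever adjacent bins share no donor coverage — no line
carries the donor state at both bins — or the estimate reaches 1/2. Regions
never touched by an introgression therefore form their own zero-length
groups that are meaningful only on the physical scale, mirroring how sparse
BIL coverage fragments a chromosome into disconnected blocks of linkage
information.

**Map contraction and the design correction.** In finished BIL material the
observed discordance fraction between tight loci is *not* the meiotic
recombination fraction: backcrossing dilutes donor material and selfing can
fix residual segments back to the recurrent allele, so only a fraction of
meiotic junctions survive in the final carrier pattern (about 0.62 per
meiotic Morgan for three backcrosses and ten selfings — the opposite
direction from the classic two-fold selfed-RIL map expansion). The default
map therefore reports observed breakpoint-density distances, which is what a
co-segregation analysis of the lines actually measures. An opt-in
`design` correction inverts an exact two-locus recursion through the
breeding scheme (tracking the diploid two-locus genotype distribution
through each backcross and selfing generation) to recover meiotic distances;
its selfing-only limit reproduces the Haldane–Waddington relation
`R = 2r/(1+2r)` exactly, which the tests verify. On simulated populations
the corrected total map length recovers the true cM span of the linked
regions to within a few percent, whereas the uncorrected map is ~40%
shorter — a property worth remembering when comparing published BIL map
lengths with meiotic maps.

## Metabolite normalization

Relative responses are averaged over available replicates per line (missing
replicates dropped, never imputed), and divided per trait by the
recurrent-parent control mean. Zero raw responses are treated as
non-detects (missing) so the log2 transform stays defined; traits with a
missing or non-positive control mean are dropped with a log entry. The
population fold-change range is taken over line means, control excluded.

## QTL scanning

Replicates are collapsed to line means. Genotype classes collapse to
donor-vs-recurrent (residual `H` groups with the donor class in homozygous
material; hybrid experiments are `A` vs `H`), so the single-bin test is a
two-class one-way ANOVA, computed as a regression on the 0/1 donor
indicator with

    LOD = (n/2) * log10(RSS0 / RSS1),

p-values from the exact F(1, n-2) distribution, and the effect size as the
donor-minus-recurrent difference of class means (reported relative to the
wild allele). Bins with fewer than two lines in either class are skipped.

Haley–Knott regression scans each linkage group on a cM grid (bin positions
plus interior points, default 1 cM). At each position the expected donor
dosage per line is the two-point Markov posterior given the nearest
informative flanking bins: with transition probability `r` for a state
change across recombination fraction `r`,
`P(donor | L, R) ∝ P(L→donor; r1) P(donor→R; r2)`. Lines missing both
flanks are excluded at that position; a single flank conditions on it alone.
At a bin position with an observed call the dosage reduces to the call
itself, so the HK LOD equals the ANOVA LOD there — an exact identity the
tests assert. A single-bin group degenerates to the plain ANOVA.

Significance uses trait-wise permutation thresholds by default: the
(1 - α) quantile of the genome-wide maximum LOD over shuffled line labels
(1000 permutations, α = 0.05, seed-reproducible). Bonferroni and raw
nominal modes are available; the nominal mode exists for calibration
studies. Support intervals are the maximal contiguous region around a peak
within `lod_drop` (default 1.0) of the peak LOD, reported in bp via the bin
coordinates; a strictly flat curve returns the whole extent with a warning.
Contiguous significant bins on a chromosome are grouped into one QTL at
their LOD maximum.

Conserved QTLs across experiments are same-trait QTLs on the same
chromosome whose support intervals intersect, grouped by chained overlap; a
group is conserved iff it spans at least two experiments.

## Breeding-scheme simulator

The generator forward-simulates the construction of the population:
F1 (donor × recurrent) → 3 backcrosses to the recurrent parent → 10
single-seed-descent selfings, optionally followed by a final cross to the
recurrent parent that produces the heterozygous hybrid set. Meiosis is the
Haldane model: per chromosome, crossover count ~ Poisson(length in Morgans),
breakpoints uniform on the cM axis, fair starting phase, no interference, no
selection, no selfing failure. Haplotypes are piecewise-constant ancestry
functions on the cM axis, so marker genotypes and recorded truth segments
are exact rather than grid-discretized. cM→bp conversion is linear per
chromosome.

Defaults mirror the population the package targets: 12 chromosomes × 100 cM
× 65 Mbp, 260 evenly spaced markers each (3120 genome-anchored SNPs), 141
lines, 3 replicates, Gaussian replicate noise with unit SD around a baseline
of 100 (so planted additive effects are in noise-SD units and responses stay
positive). Lines are simulated as independent lineages; this reproduces the
per-line segment statistics (≈4.5 introgressions per line, ≈6.25% donor
genome) but, unlike a real program where lines share backcross ancestors,
every breakpoint is private to one line. Simulated populations therefore
partition into more, smaller bins (~900 at 3120 markers) than a same-sized
real population with shared pedigree, and near-complete genome coverage.
Passing tests on these populations establish the correctness and
calibration of the machinery, not the mapping resolution of any particular
real population.

Phenotypes are additive: line value = baseline + Σ effect × donor dosage at
each planted QTL (dosage 0 / 0.5 / 1, optional dominance deviation for
heterozygotes) + independent N(0, noise_sd) per replicate; the control line
carries no donor allele.

## Calibration studies and what they show

* **Type-I error**: 1000 pure-noise traits on one simulated population
  (107 lines, 3 replicates); the raw nominal-α rejection rate is measured
  on one designated bin per trait (cycled over bins) so the draws are
  independent and exact binomial bounds apply. The pooled rate over all
  trait × bin pairs is reported alongside.
* **Power and interval coverage**: 100 simulated populations with one
  planted 1-SD QTL at the middle of chromosome 5 (n = 107, 3 replicates).
  Four statistics are reported: localization power (genome-wide LOD argmax
  within ±1 bin of the true bin), unconditional 1-LOD interval coverage of
  the planted position, genome-wide Bonferroni significance power, and
  interval coverage among significant detections. At this design the donor
  carrier frequency per locus is (1/2)⁴ ≈ 6.7 lines of 107, which puts the
  expected standardized class difference near the genome-wide significance
  reference; localization and detection power for a 1-SD effect land around
  55–70%, and only effects well above 1 SD are reliably detected. This is a
  property of the BIL design at this sample size, not of the
  implementation, and it is consistent with such populations being used to
  map large-effect metabolite QTLs.
* **Breeding expectations**: mean donor-genome fraction after three
  backcrosses vs the Mendelian (1/2)⁴ = 6.25% (200 lines), and residual
  per-marker heterozygosity after ten selfings vs (1/2)³ × (1/2)¹⁰
  (500 lines; the larger n tames the heavy-tailed per-line distribution),
  each within three empirical standard errors.
* **Oracle agreement**: the segment caller matches an independent
  brute-force implementation on all 4⁵ five-marker vectors and 10⁴ random
  twelve-marker vectors; HK dosages match explicit gamete-path enumeration
  to 1e-12.
* **Determinism**: an end-to-end pipeline run is byte-identical across
  reruns with the same seed for every output except the run manifest, which
  records wall times.

## Numerical details and degenerate inputs

* Perfect fits (zero residual) clamp RSS1 to the smallest positive float so
  the LOD is large and finite and p stays in (0, 1].
* Midpoint borders use integer floor division; the segment-start side adds
  1 bp (see above).
* A chromosome with no informative calls yields no segments plus a
  warning; an empty bin list is an error for summaries.
* rf estimates with no doubly informative line are flagged as linkage gaps
  (NaN) rather than zero.
* Contradictory HK flanks at zero distance (impossible under a consistent
  map) return dosage 0.5.
* All simulation randomness flows from one `numpy` Generator per run; the
  identical-homolog shortcut in meiosis skips RNG draws, which changes the
  stream but not the distribution, and reproducibility is defined by the
  seed.

## Known limitations

* No genotyping-error model or HMM smoothing: a single miscalled `B` in a
  recurrent region becomes a (short) segment and its own bin.
* The scan drops lines with a missing trait mean for *any* scanned trait in
  a batch; scan traits with heavily disjoint line sets separately.
* The rf estimator measures the inbred material's breakpoint density;
  meiotic distances require the design correction, whose crossing history
  must be supplied.
* The simulator does not emulate shared pedigree between lines, marker
  ascertainment, or non-uniform recombination along chromosomes.
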