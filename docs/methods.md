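# Methods

## Scope and model

`nickscope` implements the computational side of a plasmid endonuclease
workflow: ligation-capture (GLOE-seq-style) mapping of single-strand
incisions on circular DNA, the densitometric arithmetic of agarose-gel
nicking and exonuclease assays, and the construction of species-paired
multiple sequence alignments for heterodimer structure prediction. It
deliberately excludes the neighbouring steps that are either wet-lab
work or the province of dedicated tools: image densitometry (band
intensities are inputs), homology search and progressive realignment
(aligned homolog sets are inputs), and structure prediction itself.

## Read model and registration convention

A nick leaves a free 3′-OH on the incised strand. Capture ligates an
adapter to that terminus and the library reads out the sequence of the
*complementary* strand, so a read mapping to the top strand reports a
bottom-strand cut and vice versa. Two conventions close the remaining
degrees of freedom:

* **Registration.** The read's 5′-terminal mapped base coincides exactly
  with the top-strand coordinate of the 3′-OH. No off-by-one is applied
  on either side, so simulation → mapping → calling round-trips exactly.
  This is a package convention, not a claim about the ligation
  chemistry; any fixed offset would cancel in the round trip.
* **Coordinates.** 0-based everywhere; exported intervals (BED-like TSV,
  bedGraph) are 0-based half-open; `+` denotes the top strand.

The simulator emulates: non-uniform site preference (a weighted
multinomial over all 2·L (strand, position) sites, by default a uniform
background with a configurable number of strongly enriched hotspot
sites), single-end reads of fixed length (default 120 nt), and i.i.d.
substitution errors. It does **not** emulate: fragmentation/sonication
(each nick yields exactly one read, so depth per site is exact rather
than a nuisance-scaled count), PCR duplicates, adapter read-through,
indels, or base-quality variation (qualities are constant Q30 and are
never consulted). Passing tests therefore demonstrate coordinate and
strand bookkeeping correctness, not robustness to library artefacts of
real sequencing data.

## Circular mapping

The reference top strand is concatenated three times; a read no longer
than the circle then occurs linearly wherever it occurs circularly. The
mapper is an exhaustive mismatch-count scan: every circular start
position is evaluated for the read and its reverse complement via a
vectorised comparison against a sliding-window view of the triplicated
sequence. Placements are folded modulo L and collapsed before ambiguity
assessment; a read is `unique` if exactly one folded (strand, start)
achieves the minimal mismatch count within the budget, `ambiguous` on
ties, `unmapped` otherwise. The reported start is the top-strand
coordinate of the read's 5′-terminal base (for a minus-strand placement,
the right edge of the matched window).

Numerical/algorithmic choices:

* **Mismatch budget.** Default 3 for 120-nt reads — it tolerates the
  simulator's error model at ~1 % on most reads and is exposed as a
  parameter. At 1 % error a 120-nt read carries Poisson(λ≈1.2)
  substitutions and exceeds 3 in ≈3.4 % of reads, so analyses that must
  recover essentially every noisy read should raise the budget (the
  round-trip tests use 6); random placements on a 5.5-kb circle remain
  far above any such threshold, so specificity is unaffected.
* **No gapped alignment.** Matches the substitution-only error model;
  indel tolerance is out of scope.
* **Ambiguous reads** are excluded from cut calling by default — the
  conservative convention for nucleotide-resolution maps. A fractional
  mode spreads each ambiguous read as weight 1/k over its k co-optimal
  placements; weights then sum to the number of contributing reads.
* **Ties** everywhere resolve to the lexicographically smallest
  (strand, start) pair, making outputs order-independent.

The scan is validated against an independent exhaustive oracle that
tries all 2·L circular placements by direct string comparison, and by a
rotation-equivariance property: rotating the reference origin by r
shifts every mapped start by −r mod L.

## Cleavage profiles, polar export, hotspots

Called cuts aggregate into per-position, per-strand count vectors over
the circle. The polar table maps position to angle θ = 2π·position/L
with radius equal to the raw count (default) or the count normalised by
the grand total (flag) — both are provided because either normalisation
is defensible for circular cleavage plots. The hotspot report lists
sites whose count exceeds mean + k·SD (default k = 3) of the pooled
per-position counts of both strands. This is a descriptive
operationalisation of "some sites are cut more efficiently than
others", labelled as such; it is not a calibrated peak caller, has no
statistical null, and on skewed profiles will include background sites
alongside planted hotspots.

## Gel quantification

Percent nicked is 100·nicked/(supercoiled + nicked + linear); the
linear band participates in the denominator whenever present (the total
DNA of the lane includes all topoisomers) and absent columns count as
zero. Background correction subtracts the no-protein control lane's
percent and clamps at zero — the subtraction is defined on percents,
not raw intensities, and clamping keeps corrected values interpretable
as percentages. Fold stimulation is the ratio of corrected percents; a
zero baseline yields NaN (not-computable), never infinity. Replicate
summaries use the sample SD (ddof = 1)/√n for the SEM, defined as 0 for
n = 1; group comparisons use the two-tailed t-test with no
multiple-testing correction. Exonuclease gels reuse the same
fraction-of-signal arithmetic as product/(substrate + product).

## Paired MSA construction

Identity is computed over mutually aligned (both non-gap) columns;
coverage is the fraction of the query's residues aligned to a hit
residue. Both denominators are package conventions — the 25 %/50 %
defaults are only meaningful jointly with them — and the thresholds keep
boundary values (the filter removes hits strictly below a threshold).
One hit per species is retained by maximal identity, ties broken by
lexicographically smallest hit id for determinism. Delimitation keeps
alignment columns whose 1-based query residue index falls in the given
range; rows that become all-gap are retained so species bookkeeping is
unchanged. Concatenation places the two queries first, pairs each
shared species row-wise, and pads species unique to one chain with gaps
in the partner block; rows without a parsable species tag (grammar:
`OX=`/`TaxID=` tokens, else a UniProt-style `_MNEMONIC` suffix) are
never paired. Delimitation bounds are always caller-supplied — the
appropriate region depends on the complex under study.

## Problem sizes and test design

Simulated conditions mirror the study substrate: a 5 500-bp circle,
120-nt single-end reads, 2 000 capture events under a 20-hotspot model
for the end-to-end check; 10⁵ events for the sampling-convergence check
(run on a 100-bp circle, since total-variation convergence at fixed
depth degrades with site count); 500 random small references (≤300 bp,
reads ≤30 nt) for oracle equivalence; 100 random rotations on a 1-kb
circle for equivariance. These sizes make the full suite and the
acceptance script complete in well under a minute each while keeping
every check at the scale its property is about. Property tests are
seeded (or hypothesis-derandomised) for reproducibility.

## Known limitations

* The mapper is O(L·R) per read — appropriate for plasmids, not for
  genome-scale references or multi-contig assemblies.
* The hotspot filter is descriptive (no FDR control).
* The gel arithmetic assumes densitometry has already linearised and
  background-corrected band intensities at the image level.
* The paired-MSA module trusts the input alignments; it does not
  realign, and its identity/coverage definitions may differ from those
  of upstream search tools.
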