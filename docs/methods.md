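# Methods

This package implements an analysis chain for environmental-DNA (eDNA)
metabarcoding of riverine fish across a main drainage divide (MDD): quality
filtering of denoised amplicon sequence variants (ASVs), basin-level community
statistics, genetic-distance-weighted phylogenetic beta diversity (betaMPD),
conductance-based landscape distances, and generalized dissimilarity models
(GDMs) testing isolation by distance (IBD). A synthetic riverscape/haplotype
generator with exact ground truth makes every stage testable without external
sequencing data.

## Synthetic data generator

**What it emulates.** A planar grid riverscape with a north–south ridge (the
MDD) separating "ligurian" basins draining west from "adriatic" basins
draining east; one river per basin from a headwater near the ridge to the sea
margin on its own side; elevation maximal on the ridge and sloping linearly to
sea level at each margin. Basins form a stepping-stone graph: an alongshore
chain per side plus a low-weight cross-divide edge at the northern pair
(weight 0.25 vs 1.0 for chain edges), emulating limited mixing across the
divide at one end of the study region while the rest of the two sides stay
separated.

Fish species share one random in-frame marker ancestor (~420 bp, the length of
the cytochrome-*b* amplicon) from which each species' ancestral haplotype
diverges by ~8% substitutions — all amplicons are homologous, as they would be
for one primer pair. Haplotypes then evolve over the basin graph by a
stepping-stone model: a breadth-first tree from the root basin applies
Poisson(λ·w) substitutions per edge of weight w (default λ = 2 per chain
step), and a basin retains its parent's haplotype with probability 0.25
(shared haplotypes between neighbours). Substitutions never create an in-frame
stop codon under the vertebrate mitochondrial code, because real functional
mitochondrial haplotypes are stop-free. Expected pairwise mismatch therefore
grows with graph distance — the IBD signal the downstream models test.

Default community: 6 species over 10 basins (5 per side) — four widespread
(every basin), one range-restricted to alongshore prefixes of both chains, one
confined to a single basin (excluded from intraspecific analysis by the
two-basin rule). Every basin hosts several species, so all pairwise community
comparisons are defined. Two samples per basin (years alternating), eight
negative controls. Read counts per occupied sample are negative-binomial
(mean 5000, dispersion 2, floored at one read so occupancy means detection);
they are overdispersed as in real metabarcoding but irrelevant downstream
because all analyses are occurrence-based.

**Planted artefacts** (each fails exactly one filter, by construction):

- *NUMTs* (20): copies of true haplotypes with ~2% substitutions plus one
  stop codon at a random in-frame position at or beyond codon 10 — within the
  translated region after the 15-bp trim, detectable but still assignable.
- *Singletons* (15): divergent marker variants (~15% substitutions) in exactly
  one sample.
- *Low-read ASVs* (10): in 2–3 samples with fewer than 10 reads overall.
- *Contaminants* (5): present in negative controls at totals (200–600 reads)
  exceeding every field-sample count, so per-ASV subtraction zeroes them.
- *Marine taxa* (5): labelled with one of the nine excluded marine families.

All artefact sequences are divergent variants of the marker ancestor, stop-free
in the reference frame, so the alignment-based NUMT screen finds their true
frame and does not misflag them. The generator is deterministic per seed, and
`GroundTruth` lists every planted identity plus the exact expected survivor
set.

**What it does not emulate:** PCR/sequencing error and chimeras (the pipeline
consumes post-denoising ASVs), tag jumping, abundance biases, recombination,
indel variation within species, taxonomic misassignment, and real hydrographic
geometry. Passing round-trip tests therefore demonstrates correctness of the
filter logic, not robustness to denoising failures upstream.

## ASV quality filtering

Filters run in a fixed order — taxonomic class retention → negative-control
subtraction → occurrence/read thresholds → NUMT screen → marine-family
exclusion → basin pooling — and the stage is idempotent. Key choices:

- **Contamination subtraction** is per-ASV: the reads observed in negative
  controls (summed across controls; a per-control maximum is available via
  `combine="max"`) are subtracted from every field sample for that ASV,
  clipping at zero — counts are non-negative and contamination implies
  removal, not debt.
- **Thresholds** (defaults: ≥ 2 samples, ≥ 10 reads overall) are evaluated
  *after* subtraction, since subtraction changes occurrence; both are
  configurable.
- **NUMT screen**: a sequence is flagged iff its translation under the
  vertebrate mitochondrial code (stops TAA, TAG, AGA, AGG) contains a stop
  codon. The default `alignment-frame` mode derives the codon phase from a
  global alignment (free end gaps) to an in-frame reference CDS and translates
  from the first complete codon; `fixed-trim-15` instead removes the first 15
  bases and translates in frame 0, which presumes a fixed amplicon start — the
  two agree whenever the amplicon starts 15 bases into a frame-0 reference.
  Codons containing IUPAC ambiguity codes are left untranslated and never
  count as stops; trailing partial codons are truncated; sequences under 18 bp
  are flagged unscreenable and treated as removed.
- **Marine exclusion** matches the family rank case-insensitively against the
  nine-family list (Clupeidae, Mugilidae, Sparidae, Moronidae, Engraulidae,
  Scombridae, Xiphiidae, Carangidae, Istiophoridae).
- **Pooling** collapses samples to basins by any-nonzero presence; read counts
  do not propagate past this point (occurrence-only contract).

## Intraspecific analyses

Species with ASVs in at least two basins are analysed. Sequences are aligned
progressively (UPGMA guide tree over quick pairwise mismatch distances;
pairwise steps scored match +1, mismatch −1, gap open −5, gap extend −1; the
guide tree uses average linkage, the standard progressive-MSA choice, rather
than a literal nearest-neighbour join — for the indel-free sequences the
generator produces, any guide tree yields the same gap-free alignment).
Pairwise genetic distance is the raw base-pair mismatch count with *pairwise
deletion*: only columns where both rows carry unambiguous bases are compared
(proportions per comparable site are emitted alongside).

**betaMPD** between basins b₁, b₂ is the mean of D[i, j] over all cross pairs
i ∈ ASVs(b₁), j ∈ ASVs(b₂), presence/absence weighted. It is symmetric and
≥ 0; the diagonal is fixed at 0 (the distance-matrix contract; the analogous
within-basin MPD quantity is not used downstream). Basins lacking the species
yield missing pairs, which are dropped from downstream model tables.

**Whole-community betaMPD** pools species-level ASVs of all species. Genetic
distances are meaningful only within species; cross-species ASV pairs receive
the global maximum observed intraspecific distance (a cap bounding their
influence), configurable to exclusion instead. With one species the result
reduces exactly to that species' betaMPD.

**Haplotype network**: identical (optionally overlap-trimmed) sequences
collapse into haplotypes with frequencies; edges are pairwise mismatch counts
(infinite-sites reading: one mismatch = one mutational step); the main network
is a Kruskal minimum spanning tree with deterministic lexicographic
tie-breaks, and every non-tree edge whose length equals the bottleneck of the
tree path it shortcuts is reported as an alternative configuration. External
reference haplotypes may be added, in which case all sequences are trimmed to
their common gap-free overlap first.

## Community statistics

Jaccard dissimilarity on basin presence sets (at ASV level or collapsed to the
highest assigned taxon, kept only at family level or deeper); classical PCoA
(double-centred −D²/2, positive-eigenvalue axes scaled by √λ, signs fixed by
the largest-magnitude loading; negative eigenvalues reported, no
Lingoes/Cailliez correction — the use-case is visualisation); ANOSIM with
midranks; Mantel with Pearson correlation of upper triangles, one-sided
(greater). Both permutation tests default to 999 seeded permutations and use
p = (1 + #{perm ≥ observed}) / (1 + N); the identity permutation is never
drawn as a null sample. The richness comparison between the two sides uses the
two-sided Wilcoxon rank-sum test (exact for small untied samples, normal
approximation with tie and continuity correction otherwise).

## Landscape distances

Conductance rasters follow two independent schemes: *river-following* (water
50 000, land 0.0001, sea 150 — land an almost impenetrable barrier, sea
intermediate) and *elevation-weighted* (bands [0, 100) m → 10⁶, [100, 500) →
10⁵, [500, 1500) → 10³, [1500, 2000) → 10², ≥ 2000 m → 0.001). The two schemes
are separate rasters, not overlays; all values are configurable but default to
the ones above.

Least-cost paths run over the 8-neighbour cell graph with edge cost
d/mean(c_i, c_j) (d the centre-to-centre distance, diagonals × √2) and
all-pairs Dijkstra between centroid cells. The 8-neighbour discretisation
overestimates off-axis straight-line costs by at most ~8.2%
(sec(π/8)·cos(π/8 − θ) bound). Cost distances are expressed in kilometres by
multiplying by a reference conductance (default: the water value), so a path
running entirely through water reads as its along-path river length; the
transformation is monotone and order-preserving, and the anchor is
configurable. Cell distances are planar from the cell size (the synthetic
grids are planar); Euclidean basin distances are great-circle (haversine,
mean Earth radius 6371.0088 km) on centroid lon/lat.

## GDM isolation-by-distance models

The model is d = 1 − exp(−η), η = β₀ + Σₖ βₖ·Iₖ(distance) with all
coefficients ≥ 0, so predicted dissimilarity is monotone non-decreasing in
distance and bounded in [0, 1). Responses are betaMPD values scaled by their
maximum to [0, 1]. The default basis is three order-2 I-splines (integrated
M-splines) with knots at the 0th/50th/100th percentiles of the distances,
built from B-splines via Iᵢ(x) = Σ_{j≥i} Bⱼ(x); each basis function is 0 at
the minimum, 1 at the maximum, monotone in between. One predictor (one
distance scheme) per model is the default.

Fitting minimises squared error on the response scale (the quantity reported
is explained variance, so the objective matches the metric): a non-negative
least-squares pass on the linearised link η = −log(1 − d) seeds a bounded
trust-region Gauss–Newton refinement; there is no random initialisation, so
fits are deterministic. Percent deviance explained is
100·(1 − RSS_model/RSS_null) with the intercept-only null, clipped to
[0, 100] against numerical slack; a constant response yields all βₖ = 0 and
0% by construction. Predictions outside the fitted distance range are clamped
to the boundary (I-splines are constant there) and flagged.

## Numerical and testing choices

- All randomness flows from explicit seeds (`numpy.random.default_rng`);
  pipeline stages derive independent seeds by hashing the global seed with the
  stage name, so stage order cannot change draws.
- Problem sizes in the test-suite experiments: betaMPD oracle instances up to
  10 basins × 60 ASVs; Dijkstra oracle rasters up to 50 × 50; permutation-test
  calibration 1000 replicates of 10 labels × 999 permutations; GDM recovery
  45 site pairs, 100 noise seeds; IBD sweeps on 8-basin chains, 50 seeds per
  mutation-rate level; end-to-end checks 50 seeds of the default 10-basin
  scenario.
- Independent oracles used in tests: brute-force double loops (betaMPD,
  subtraction, ranks), Biopython's vertebrate-mitochondrial translation,
  R `picante::comdist`, scikit-bio's ANOSIM/Mantel statistics, scipy's
  minimum spanning tree, a textbook binary-heap Dijkstra, and closed-form
  haversine/Poisson expectations.

## Known limitations

- The whole-community betaMPD cap for cross-species pairs is one defensible
  convention; results at community level depend on it (per-species analyses do
  not).
- The cost→km anchoring is a linear convention, not a calibration against
  measured river lengths.
- The progressive aligner targets substitution-dominated amplicon variation;
  it is not a general-purpose MSA tool for long indels or many ragged ends.
- GDM explained deviance is data-dependent; synthetic values are not
  comparable to any particular empirical dataset.
- The generator's negative-binomial read model ignores compositionality
  (fixed sequencing depth per sample), which is harmless here because nothing
  downstream of pooling uses abundances.
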