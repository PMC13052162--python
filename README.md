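# edna-divide

Inter- and intraspecific diversity of riverine fish from eDNA metabarcoding,
across a main drainage divide (MDD).

Environmental DNA sampled from rivers and amplified with a single
cytochrome-*b* primer pair yields amplicon sequence variants (ASVs) that carry
two kinds of signal at once: *which species* are present (interspecific
diversity) and *which haplotypes* of each species are present (intraspecific
diversity). This package, aimed at molecular ecologists and population
geneticists working with metabarcoding data, turns a denoised ASV table into
both signals and tests whether the intraspecific one is spatially structured:

1. **Quality filtering** (`asv_filtering`) — retain the target class
   (ray-finned fishes), subtract negative-control contamination per ASV,
   apply occurrence (≥ 2 samples) and read (≥ 10 total) thresholds, flag NUMTs
   (nuclear mitochondrial pseudogenes) by in-frame stop codons under the
   vertebrate mitochondrial code, exclude marine families, and pool samples to
   basin-level presence/absence.
2. **Community statistics** (`community_stats`) — richness, Jaccard
   dissimilarity J(A,B) = 1 − |A∩B|/|A∪B|, PCoA ordination, ANOSIM between the
   two sides of the divide, Mantel correlations.
3. **Intraspecific analyses** (`intraspecific`) — per-species alignment,
   pairwise base-pair mismatch distances D, and phylogenetic beta diversity
   betaMPD(b₁,b₂) = mean{ D[i,j] : i ∈ ASVs(b₁), j ∈ ASVs(b₂) }
   between basins, plus minimum-spanning-tree haplotype networks.
4. **Landscape distances** (`landscape`) — conductance rasters (river-following
   and elevation-weighted schemes) and least-cost-path distances between basin
   centroids, alongside great-circle distances.
5. **Isolation by distance** (`gdm_ibd`) — generalized dissimilarity models
   d = 1 − exp(−β₀ − Σₖ βₖ Iₖ(distance)), βₖ ≥ 0, with monotone I-spline basis
   functions, reporting percent deviance explained per distance scheme.

A first-class synthetic generator (`synthetic_data`) builds a two-sided
riverscape with basin-structured haplotype variation and planted artefacts
(NUMTs, singletons, low-read noise, contaminants, marine taxa) with exact
ground truth, so the whole chain is testable without external sequencing data.
See `docs/methods.md` for models, assumptions and parameter choices.

## Worked example

```python
from edna_divide.pipeline import PipelineConfig, run_pipeline

result = run_pipeline(PipelineConfig(seed=1), outdir="run1")
print(result.summary)
```

prints (abridged):

```
n_surviving_asvs: 40            # of 95 input ASVs; equals the planted truth
anosim_R_asv: 0.268             # ASV-composition separation between sides
anosim_R_betampd: 0.518         # genetic-distance-weighted separation
anosim_p_betampd: 0.011         #   ... significant at alpha = 0.05
mantel_r_jaccard_vs_betampd: 0.566   (p = 0.001)
gdm_community:
  euclidean:   27.8% deviance explained
  topographic: 19.8%
  elevation:   19.8%
```

Reading: the 55 planted artefacts were all removed (survivors equal the
generator's ground truth exactly); community betaMPD separates the two sides
of the divide more sharply than raw ASV identity; identity-based and
genetic-distance-weighted dissimilarity are correlated but not redundant; and
scaled betaMPD increases with geographic distance (isolation by distance),
with around a fifth to a quarter of its deviance explained by each distance
scheme on this synthetic landscape.

The same stages are available from the shell:

```sh
edna-divide simulate --out sim --seed 1
edna-divide filter --table sim/asv_table.tsv --fasta sim/asv_sequences.fasta \
    --tax sim/taxonomy.tsv --meta sim/metadata.tsv \
    --reference sim/reference_cds.fasta --out filt
edna-divide all --out run1 --seed 1
```

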