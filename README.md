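# ishquant

Quantification, clustering and transition statistics for spatial gene
expression patterns from in situ hybridization (ISH) images of
*Nematostella vectensis* embryos.

## The problem

Developmental biologists describe where a gene is expressed by staining
fixed embryos (ISH) and annotating named expression domains — central domain
(`Cd`), central ring (`Cr`), endoderm (`En`), oral ectoderm (`OrEc`) and so
on — at each of seven ordered stages from blastula to late planula.  Two
questions follow:

1. **Which genes share a spatial expression domain at a given stage?**
   Answered by quantifying each image into a standardized 1D profile along
   the oral–aboral body axis and clustering the profiles.
2. **How do expression domains move between stages?**  Answered by
   classifying each gene's change between consecutive available stages
   against three coarse *major regions* — R1 central domain/endoderm,
   R2 central ring + external ring/oral ectoderm, R3 vegetal
   hemisphere/aboral ectoderm — and tallying the outcomes.

`ishquant` implements both analyses as a tested, reusable library with a
thin CLI, plus a synthetic-data generator that produces embryo-like images,
profile sets and domain tables with known ground truth, so the entire
pipeline is verifiable without any external database.

## Methods in brief

**Profile extraction.** The embryo's cell layer is delimited by two
index-paired boundary polylines.  The layer is decomposed into quadrilateral
segments; pixel intensities are averaged per segment and plotted against the
normalized midline arc length *t* ∈ [0, 1] (0 = animal/oral pole).  After
masking artifacts (linear interpolation over recorded intervals), the
profile is interpolated at 100 equidistant points and scaled so
max *f*(*t*) = 1.

**Clustering.** Profiles within one stage are compared by the Pearson
correlation distance *d* = 1 − *r* ∈ [0, 2] and merged by unweighted
average linkage (UPGMA): the distance between clusters is the arithmetic
mean of all inter-member leaf distances.  Dendrograms are cut at
stage-specific thresholds (0.7, 1.3, 1.1, 0.6, 0.9, 0.9, 0.9 for the seven
stages; mean 0.9), or by the main-cluster rule: two main clusters, or three
if the second-highest merge subdivides the larger root branch.

**Transition statistics.** For every gene with described expression at ≥ 2
stages, each pair of consecutive available stages is classified as
*minor* (same major-region set), *major* (region set changed), *appeared*,
*vanished* or *none*.  Pairs are tallied into (initial × final stage) count
matrices; a pair spanning stages *i* → *f* is credited to every
consecutive-stage period between them when matrices are aggregated into
per-period sums and integer percentages.  A two-tail Fisher's exact test
(exact hypergeometric enumeration) compares change rates between periods.

## Worked example

```python
import numpy as np
from ishquant import (ArchetypeSpec, ShapeParams, Stage, STAGE_CUTOFFS,
                      aggregate_periods, cut_dendrogram, extract_profile,
                      generate_embryo_image, generate_profile_set,
                      pearson_distance_matrix, upgma_linkage)
from ishquant.reference import central_domain_pairwise_counts

# 1. quantify a synthetic blastula stained in the central domain
arch = ArchetypeSpec([("Cd", 0.0, 0.3)], stage=Stage.BLASTULA)
scene = generate_embryo_image(ShapeParams(), arch, noise_sd=0.02, seed=0)
profile = extract_profile(scene.image, scene.true_morphology)
print("profile head:", np.round(profile.values[:6], 3))

# 2. cluster a planted two-archetype profile set at the blastula cutoff
archetypes = [
    ArchetypeSpec([("Cd", 0.0, 0.25)], stage=Stage.BLASTULA),
    ArchetypeSpec([("Er", 0.35, 0.55)], stage=Stage.BLASTULA),
]
profiles, truth = generate_profile_set(archetypes, 6, noise_sd=0.05, seed=1)
dend = upgma_linkage(pearson_distance_matrix(profiles))
cut = cut_dendrogram(dend, STAGE_CUTOFFS[Stage.BLASTULA])
print("clusters:", cut.n_clusters, "sizes:", cut.sizes())

# 3. period summary of the published central-domain transition counts
summary = aggregate_periods(central_domain_pairwise_counts())
for p in summary.periods()[:2]:
    print(f"{p[0].label} -> {p[1].label}: counts {summary.counts[p]} "
          f"percentages {summary.percentages[p]}")
```

prints

```
profile head: [0.01  0.107 0.351 0.645 0.893 0.985]
clusters: 2 sizes: [6, 6]
blastula -> early gastrula: counts (22, 2, 1) percentages (88, 8, 4)
early gastrula -> mid gastrula: counts (9, 4, 0) percentages (69, 31, 0)
```

The profile rises from the oral pole into the stained window; the two
planted archetypes separate into two clusters of six profiles each; and the
central-domain summary says that 88 % of genes expressed only in the
blastula central domain are next seen only in the endoderm, while 31 % of
the entries spanning the early→mid gastrula period changed region there.

The same steps are available from a shell:

```sh
ishquant simulate-profiles --seed 1 --out profiles.csv
ishquant cluster --profiles profiles.csv --stage blastula --out-dir clusters/
ishquant simulate-domains --n-genes 200 --seed 1 --out table.csv
ishquant transitions --table table.csv --out-dir transitions/
```

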