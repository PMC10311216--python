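# glycometa

Glycan-related gene (CAZyme) profiling of gut metagenomes.

The human gut microbiome carries most of the carbohydrate-active enzymes
(CAZymes) that degrade dietary polysaccharides and mucins and that build
glycans — the human genome itself encodes only a handful of
carbohydrate-degrading enzymes.  `glycometa` identifies CAZyme-derived reads
in shotgun metagenomes, turns them into per-sample functional profiles, and
characterises the cohort structure those profiles imply: how abundant
glycan-related genes are per individual, how degradation
(GH/CE/PL) and synthesis (GT) functions are distributed, which sample
clusters exist, and which substrate origins (Plant, Animal, Mucin, Fungal,
Peptidoglycan, Sucrose, Starch) distinguish them.

## What it computes

1. **Host-read exclusion** — reads matching a host reference (canonical
   31-mer membership, configurable fraction rule) are removed before any
   annotation.
2. **Glycan-gene identification** — each read is translated in six frames
   and aligned against an annotated CAZyme protein catalogue (dbCAN/CAZy
   style: family, class, enzyme functions, substrate classes, taxon per
   entry).  A read is *glycan-related* when its best ungapped alignment has

   > identity ≥ 90 % **and** alignment length ≥ 25 aa

   and it inherits the annotation of its best-matching entry
   (score, then identity, then length, then smallest `ref_id`).
3. **Profiles** — per sample: the glycan fraction (% of post-filter reads
   assigned), class composition over GH/GT/CE/PL/CBM (AA is excluded),
   family→enzyme-function distribution (read mass split over an entry's
   weighted functions), degradation vs synthesis role tables, and taxon
   profiles at phylum/family/genus.
4. **Cohort analysis** — Shannon diversity `H' = −Σ Pᵢ log₂ Pᵢ`, Euclidean
   hierarchical clustering, a seeded 2-D t-SNE embedding of the
   degradation-function matrix, k-means cluster calling (labels ordered by
   ascending mean glycan fraction), Wilcoxon rank-sum tests with
   Benjamini–Hochberg q-values between clusters, top-20 differential
   enzymes per pair, and apportionment of their abundance across the seven
   substrate classes.
5. **Synthetic cohorts** — seeded generators plant reads from catalogue
   entries at controlled amino-acid identity, with background and host
   contamination, per-regime glycan fractions, substrate/role/taxon mixes
   and cluster labels, plus a per-read truth table — so every stage can be
   scored against known ground truth.

## Worked example

```python
from glycometa.pipeline import run_default_cohort

res = run_default_cohort(seed=1)
print("ARI vs planted labels:", round(res.ari, 3))
print({c: round(m, 2) for c, m in res.cluster_mean_fraction("called").items()})
plant = res.substrate_shares[((1, 3), 3)]["Plant"]
other = res.substrate_shares[((1, 3), 1)]["Plant"]
print("Plant share, cluster 3 vs cluster 1:", round(plant, 2), "vs", round(other, 2))
```

prints (cohort of 3 regimes × 10 samples × 20 000 reads, planted glycan
fractions 1.8/2.4/3.6 %):

```
ARI vs planted labels: 1.0
{1: 1.82, 2: 2.42, 3: 3.67}
Plant share, cluster 3 vs cluster 1: 0.45 vs 0.2
```

The called clusters reproduce the planted ones exactly (adjusted Rand
index 1.0), the recovered per-cluster glycan fractions sit within 0.1
points of the planted values, and the enzymes enriched in the
glycan-richest cluster are dominated by plant-substrate degraders while the
poorest cluster leans towards animal/mucin/peptidoglycan/fungal substrates.

## Command line

```bash
glycometa --config config.yaml run-all        # simulate → annotate → profile → analyze
glycometa --config config.yaml --seed 7 simulate
```

Every output TSV starts with `# glycometa <version> config=<hash>
seed=<seed>`; reruns with the same config are byte-identical.

### Catalogue format

A protein FASTA plus a tab-separated annotation table with columns
`ref_id  family  class  functions  substrates  taxonomy`.  Multi-values are
semicolon-separated with an optional `:weight` suffix
(`3.2.1.1:2;3.2.1.41`); taxonomy is `rank=name` pairs
(`phylum=Bacteroidota;genus=Bacteroides`).  Hit tables from external
translated-search tools are accepted in the common 12-column tabular
dialect (query, subject, %identity, length, …); column 11 carries the
reading frame in files this package writes itself.

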