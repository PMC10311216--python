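# Methods

## Problem setting

Stool shotgun metagenomes mix reads from hundreds of gut taxa with host
DNA.  A small but informative slice of those reads derives from
carbohydrate-active enzymes (CAZymes): glycoside hydrolases (GH),
carbohydrate esterases (CE) and polysaccharide lyases (PL) that break
glycosidic or ester bonds ("degradation"), glycosyltransferases (GT) that
form them ("synthesis"), carbohydrate-binding modules (CBM, non-catalytic)
and auxiliary activities (AA, redox; excluded from all analyses here
because it contributes essentially no reads in gut data).  The package
quantifies, per sample, how much of the metagenome is glycan-related and
what those genes do, then compares samples at cohort level.

## Read identification

Reads are nucleotide; the catalogue is protein.  Each read is translated
in all six frames, translations are split at stop codons, and fragments of
at least 8 aa are searched against the catalogue.  The aligner is an exact
seed-and-verify scheme:

* **Seeds** — exact amino-acid 4-mers shared between a fragment and a
  catalogue entry, found through a hash of all entry 4-mers.  The query is
  stepped by 2: any ungapped alignment with ≥ 90 % identity over ≥ 25 aa
  contains a run of ≥ 5 consecutive identities and therefore a 4-mer
  starting at an even query offset, so no acceptable alignment can be
  missed.
* **Verification** — for every seeded diagonal the maximal-scoring ungapped
  segment is computed exactly (vectorised maximum-subarray on BLOSUM62
  scores).  Among equal-score segments the higher-identity, then longer,
  then left-most one is kept.  Diagonals whose best segment scores below
  3.2 × 25 = 80 are discarded early: an acceptable segment has at least
  90 % of columns scoring ≥ +4 and at most 10 % scoring ≥ −4, so its score
  is at least 3.2 per column, and nothing below the bound can change an
  accept/reject decision.
* **Acceptance rule** — a hit is accepted iff identity ≥ 90 % (matches /
  aligned columns) **and** aligned length ≥ 25 aa, both bounds inclusive.
* **Assignment** — among accepted hits over all frames and entries exactly
  one is kept, ordered by score, identity, length, then lexicographically
  smallest `ref_id` (fully deterministic).  Fragments shorter than 25 aa
  are skipped during search since they cannot host an acceptable segment.

Ungapped alignment is a deliberate choice: the rule is purely
identity/length based, the synthetic reads contain substitutions only, and
ungapped segments admit an exhaustive, independently implemented oracle
(enumeration of every segment on every diagonal) against which the seeded
search is tested pair-by-pair.  Gapped or frameshift-aware refinements and
e-value statistics are out of scope; external translated-search tools can
be substituted through 12-column hit tables, to which the same acceptance
and best-hit rules are applied.

## Host filtering

A desk-scale surrogate for read mapping: the host reference is indexed as
canonical (strand-collapsed) 31-mers and a read is removed when at least
half of its 31-mers are index members (both parameters configurable).
Verbatim host substrings of length ≥ 31 are always removed; 150-bp
uniform-random reads essentially never are (the chance of a single 31-mer
collision against a 20-kb host is < 10⁻⁶).  A pre-computed removal list
can be supplied to honour an external mapper instead.

## Profiles

All within-glycan quantities use the count of non-AA assigned reads
(`n_glycan`) as denominator; the glycan fraction uses all post-filter
reads.  Each GH/GT/CE/PL read distributes its 1/`n_glycan` mass over the
weighted enzyme functions of its assigned entry; entries lacking function
annotation fall back to the family-wide function table (weights
proportional to the number of entries per function), and families with no
annotation anywhere book the mass to `<family>:unknown` so mass is
conserved exactly at every stage (tested to 1e-9).  Degradation tables
collect GH/CE/PL contributions, synthesis tables GT; CBM is counted in the
class composition but carries no role.  Per-hit annotations are the
primary route and the family table only a fallback, because the catalogue
schema carries function weights per entry.

For heatmap display, relative abundances are log10-transformed with zeros
floored at log10 of half the smallest nonzero cell, keeping them visually
below every observed value.

## Cohort statistics

* **Diversity** — Shannon index in bits, `H' = −Σ Pᵢ log₂ Pᵢ`, computed on
  three bases per sample: degradation functions, synthesis functions, and
  organisms (genus-level taxon profile).
* **Ordering/heatmaps** — complete-linkage hierarchical clustering on exact
  Euclidean distances (average/ward available).
* **Embedding** — 2-D Barnes–Hut t-SNE of the degradation matrix with the
  R-default parameters (perplexity 30, θ = 0.5, 1000 iterations,
  exaggeration 12, η = 200, 50-component PCA preprocessing when wider).
  Perplexity is lowered to ⌊(n−1)/3⌋ with a warning when the cohort is
  small.  t-SNE is stochastic, so the seed is a required, logged parameter
  and all downstream checks are invariance-based (cluster recovery), never
  exact coordinates.
* **Cluster calling** — the sample groups visible in such embeddings are
  formalised as seeded k-means (k·10 restarts) on the embedding, with
  labels renumbered by ascending cluster-mean glycan fraction so the
  highest label is always the most glycan-rich cluster.  Because a single
  t-SNE restart can nudge one borderline sample across a cluster boundary,
  the pipeline majority-votes the k-means labels over five independently
  seeded embedding restarts (aligned to the first restart by Hungarian
  assignment on the label contingency table); the first restart's
  embedding is the one displayed.  The procedure remains a pure function
  of the root seed.
* **Differential enzymes** — per cluster pair, a two-sided Wilcoxon
  rank-sum test per enzyme function (exact enumeration when min(n) ≤ 8
  without ties, otherwise the tie- and continuity-corrected normal
  approximation), Benjamini–Hochberg q-values computed within the pair
  (the BH family is all functions tested for that pair), and the 20
  smallest q-values selected (ties broken by p, then function id).
  Sidedness and the BH family are design choices; two-sided and per-pair
  respectively.
* **Substrate apportionment** — each selected enzyme's mean abundance in
  the cluster it is higher in is split across its substrate classes
  proportionally to catalogue substrate weights, pooled, and normalised
  over the seven classes (Plant, Animal, Mucin, Fungal, Peptidoglycan,
  Sucrose, Starch).  Functions without substrate annotation are booked to
  a separate unannotated mass and excluded from the normalisation.

## Synthetic data

The generators emulate the study conditions rather than sequencing
physics.  A toy catalogue (default 10 families × 4 entries, classes
round-robin over GH/GT/CE/PL/CBM; AA omitted) cycles six gut genera
(Bacteroides, Phocaeicola, Ruminococcus, Bifidobacterium, Blautia,
Faecalibacterium) with consistent lineages, the seven substrate classes,
and pairwise-shared enzyme functions.  The host surrogate is an i.i.d.
nucleotide sequence at human-like GC (41 %).

Samples draw read origins i.i.d. per read: glycan reads are
reverse-translated windows (uniform synonymous codons, no indels) of
catalogue entries with substitutions planted to hit a per-regime identity
band (default 92–99 %), on a random strand and frame; background reads are
uniform-random nucleotides (maximally separated from the catalogue, so
false-positive measurements are meaningful); host reads are verbatim host
substrings; host contamination defaults to 2 %.  Default read length
150 bp encodes 48–49 aa, comfortably above the 25-aa rule.

The default cohort has three regimes at glycan fractions 1.8 / 2.4 /
3.6 % — lowest, intermediate, and highest glycan content — with regime 1
leaning to animal/mucin/peptidoglycan/fungal substrates carried by
Bacillota/Actinomycetota genera, and regimes 2–3 leaning to plant
substrates, regime 3 dominated by Bacteroidota.  Entry sampling is
hierarchical — genus from the taxon mix, then entries weighted by the
substrate and role mixes — so the planted genus marginal is exact.

What the generator does **not** model: sequencing error profiles,
paired-end structure, gene-length effects, indels, within-genus sequence
homology (entries are independent random proteins, so cross-assignment
between entries is essentially impossible).  Passing tests therefore
demonstrate the correctness of the decision rule, the accounting, and the
statistical machinery under controlled truth — not robustness to real
sequencing artefacts or to homologous gene families.

## Problem sizes and numerical choices

The cohort-level checks run the full pipeline on 3 regimes × 10 samples ×
20 000 reads (the default study conditions) across five cohort seeds;
smaller fixtures (hundreds to thousands of reads) cover the per-module
behaviour.  All randomness flows from explicit seeds; per-sample seeds are
spawned from the cohort seed via `numpy.random.SeedSequence`.  Mass
conservation is asserted at 1e-9, substrate-share normalisation at 1e-12.
Degenerate inputs fail loudly: constant matrices for t-SNE, all-zero
abundance vectors for the Shannon index, NaN cells in clustering, k = 1
cluster calls.  Samples excluded by the read-QC gate (minimum read length
100 bp; minimum read count, scaled to fixture size via config) are listed
with reasons rather than silently dropped.

## Known limitations

* The k-mer host filter is exact-membership, not alignment; diverged host
  regions (or host microsatellites) are out of scope.
* One best assignment per read; multi-mapping reads are not fractionally
  split (a `count_mode="all"` option exists for sensitivity analyses).
* No gene-length or copy-number normalisation (raw read proportions).
* Cluster calling assumes the embedding separates groups; k is a
  parameter (default 3), not inferred.
* The exact and asymptotic rank-sum branches differ by up to 0.0109 in
  two-sided p at the crossover size n = 8/8 — an intrinsic property of the
  continuity-corrected normal approximation, relevant only in the
  uninformative centre of the null distribution.
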