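"""Diversity, clustering and between-cluster differential statistics.

Implements the analysis layer over cohort matrices: Shannon diversity in
bits (H' = -sum P_i * log2 P_i), Euclidean hierarchical clustering for
heatmap ordering, a 2-D stochastic-neighbour (t-SNE) embedding of the
degradation-function profiles, seeded k-means cluster calling with an
abundance-based label ordering, Wilcoxon rank-sum tests with
Benjamini-Hochberg q-values, top-k differential enzyme selection, and the
apportionment of the selected enzymes' abundance across the seven substrate
origin classes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from scipy.stats import mannwhitneyu
from sklearn.cluster import KMeans
from sklearn.manifold import TSNE
from statsmodels.stats.multitest import multipletests

from .profile import SampleProfile
from .refdb import SUBSTRATE_CLASSES, ReferenceCatalogue


@dataclass
class DiversityResult:
    sample_id: str
    basis: str  # degradation_genes | synthesis_genes | organisms
    H_prime: float
    S: int


def shannon_index(rel_abundances) -> float:
    """Shannon index in bits over a relative-abundance vector.

    Zero entries are ignored; the vector is renormalised when its sum
    deviates from 1 by more than 1e-9.  An all-zero vector is an error.
    """
    p = np.asarray(list(rel_abundances), dtype=float)
    if p.size == 0 or np.any(p < 0):
        raise ValueError("abundances must be non-negative and non-empty")
    p = p[p > 0]
    if p.size == 0:
        raise ValueError("empty distribution")
    total = p.sum()
    if abs(total - 1.0) > 1e-9:
        p = p / total
    return float(-(p * np.log2(p)).sum())


def hierarchical_order(matrix: pd.DataFrame, metric: str = "euclidean",
                       linkage: str = "complete"):
    """Leaf order and linkage tree for heatmap display.

    Deterministic given the input row order; exact pairwise distances.
    """
    values = matrix.to_numpy(dtype=float)
    if values.shape[0] < 2:
        raise ValueError("need at least 2 rows")
    if np.isnan(values).any():
        raise ValueError("matrix contains NaN")
    tree = hierarchy.linkage(pdist(values, metric=metric), method=linkage)
    order = hierarchy.leaves_list(tree)
    return [matrix.index[i] for i in order], tree


def tsne_embed(matrix: pd.DataFrame, seed: int, perplexity: float = 30.0,
               theta: float = 0.5, max_iter: int = 1000,
               initial_dims: int = 50) -> np.ndarray:
    """2-D t-SNE embedding (Barnes-Hut, exaggeration 12, eta 200 — the
    R Rtsne defaults).  Perplexity is auto-lowered to floor((n-1)/3) when
    the sample count cannot support it, with a warning."""
    x = matrix.to_numpy(dtype=float)
    n = x.shape[0]
    if np.allclose(x, x[0]):
        raise ValueError("degenerate input: constant matrix")
    max_perp = (n - 1) // 3
    if n <= 3 * perplexity:
        warnings.warn(f"perplexity lowered from {perplexity} to {max_perp} for n={n}")
        perplexity = max_perp
    if x.shape[1] > initial_dims:
        from sklearn.decomposition import PCA
        x = PCA(n_components=initial_dims, random_state=seed).fit_transform(x)
    tsne = TSNE(n_components=2, perplexity=perplexity, angle=theta,
                max_iter=max_iter, early_exaggeration=12.0, learning_rate=200.0,
                init="random", random_state=seed, method="barnes_hut")
    return tsne.fit_transform(x)


@dataclass
class ClusterAssignment:
    sample_id: str
    cluster_label: int
    embedding_xy: tuple[float, float]


def call_clusters(points, sample_ids, k: int = 3, seed: int = 0,
                  glycan_fractions: dict[str, float] | None = None,
                  ) -> list[ClusterAssignment]:
    """Seeded k-means on the embedding (or any feature matrix).

    Labels are renumbered 1..k by ascending cluster-mean glycan fraction
    when fractions are supplied, so the highest label is the most
    glycan-rich cluster; otherwise by first appearance.
    """
    x = np.asarray(points, dtype=float)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > x.shape[0]:
        raise ValueError("k exceeds the number of samples")
    km = KMeans(n_clusters=k, n_init=k * 10, random_state=seed)
    raw = km.fit_predict(x)
    relabel = _order_by_abundance(raw, sample_ids, k, glycan_fractions)
    return [ClusterAssignment(sid, relabel[r], (float(p[0]), float(p[1])) if x.shape[1] >= 2 else (float(p[0]), 0.0))
            for sid, r, p in zip(sample_ids, raw, x)]


def _order_by_abundance(raw_labels, sample_ids, k, glycan_fractions):
    """Map raw 0-based k-means labels to 1..k, ascending mean glycan
    fraction when fractions are supplied (the top label is then the most
    glycan-rich cluster), else by first appearance."""
    raw_labels = np.asarray(raw_labels)
    if glycan_fractions is not None:
        means = {c: np.mean([glycan_fractions[sid]
                             for sid, r in zip(sample_ids, raw_labels) if r == c])
                 for c in range(k)}
        order = sorted(means, key=lambda c: means[c])
    else:
        order = list(dict.fromkeys(raw_labels.tolist()))
    return {c: i + 1 for i, c in enumerate(order)}


def consensus_clusters(matrix: pd.DataFrame, sample_ids, k: int = 3, seed: int = 0,
                       n_restarts: int = 5, perplexity: float = 30.0,
                       glycan_fractions: dict[str, float] | None = None,
                       ) -> tuple[list[ClusterAssignment], np.ndarray]:
    """Majority-vote cluster calling over several seeded embedding restarts.

    t-SNE can nudge one borderline sample across a cluster boundary in a
    given restart; running `n_restarts` independently seeded embeddings,
    k-means on each, aligning labels to the first restart by maximum
    overlap (Hungarian assignment on the label contingency table) and
    taking each sample's majority label removes that single-restart noise
    while remaining a pure function of the root seed.  Returns the
    assignments (labelled via :func:`_order_by_abundance`) and the first
    restart's embedding, which serves as the display embedding.
    """
    from scipy.optimize import linear_sum_assignment

    seeds = [int(c.generate_state(1)[0] % (2**31))
             for c in np.random.SeedSequence(seed).spawn(n_restarts)]
    runs = []
    first_embedding = None
    for s in seeds:
        embedding = tsne_embed(matrix, seed=s, perplexity=perplexity)
        if first_embedding is None:
            first_embedding = embedding
        km = KMeans(n_clusters=k, n_init=k * 10, random_state=s)
        runs.append(km.fit_predict(embedding))

    reference = runs[0]
    aligned = [reference]
    for labels in runs[1:]:
        contingency = np.zeros((k, k), dtype=int)
        for r, c in zip(reference, labels):
            contingency[r, c] += 1
        rows, cols = linear_sum_assignment(-contingency)
        mapping = {int(c): int(r) for r, c in zip(rows, cols)}
        aligned.append(np.array([mapping[int(v)] for v in labels]))

    stacked = np.vstack(aligned)
    majority = np.empty(stacked.shape[1], dtype=int)
    for j in range(stacked.shape[1]):
        counts = np.bincount(stacked[:, j], minlength=k)
        best = np.flatnonzero(counts == counts.max())
        majority[j] = reference[j] if reference[j] in best else int(best[0])

    relabel = _order_by_abundance(majority, sample_ids, k, glycan_fractions)
    assignments = [ClusterAssignment(sid, relabel[int(m)],
                                     (float(p[0]), float(p[1])))
                   for sid, m, p in zip(sample_ids, majority, first_embedding)]
    return assignments, first_embedding


def rank_sum_test(values_a, values_b) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Exact enumeration when min(n_a, n_b) <= 8 and there are no ties, else
    the normal approximation with tie and continuity corrections.  Two
    identical groups give p = 1.
    """
    a = np.asarray(list(values_a), dtype=float)
    b = np.asarray(list(values_b), dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("each group needs >= 3 values")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return 1.0
    has_ties = len(np.unique(pooled)) < pooled.size
    if min(a.size, b.size) <= 8 and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = mannwhitneyu(a, b, alternative="two-sided", method=method,
                       use_continuity=True)
    return float(min(res.pvalue, 1.0))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in the original order."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class DifferentialResult:
    function_id: str
    cluster_pair: tuple[int, int]
    p_value: float
    q_value: float
    higher_in: int
    substrate_shares: dict[str, float] = field(default_factory=dict)


def top_k_differential(matrix: pd.DataFrame, labels, k: int = 20,
                       ) -> dict[tuple[int, int], list[DifferentialResult]]:
    """Per cluster pair: rank-sum per function column, BH across all
    functions tested for that pair, then the k smallest q-values (ties by p,
    then function id).  `higher_in` is the cluster with the larger median
    (mean breaks median ties)."""
    labels = np.asarray(list(labels))
    clusters = sorted(set(labels.tolist()))
    if len(clusters) < 2:
        raise ValueError("need >= 2 clusters")
    if k > matrix.shape[1]:
        warnings.warn(f"only {matrix.shape[1]} functions available for top-{k}")
    out: dict[tuple[int, int], list[DifferentialResult]] = {}
    for i, ca in enumerate(clusters):
        for cb in clusters[i + 1:]:
            xa = matrix.loc[labels == ca]
            xb = matrix.loc[labels == cb]
            if len(xa) < 3 or len(xb) < 3:
                warnings.warn(f"skipping pair ({ca},{cb}): fewer than 3 samples per group")
                continue
            pvals = [rank_sum_test(xa[fn].to_numpy(), xb[fn].to_numpy())
                     for fn in matrix.columns]
            qvals = bh_adjust(pvals)
            rows = sorted(zip(matrix.columns, pvals, qvals),
                          key=lambda r: (r[2], r[1], r[0]))[:k]
            results = []
            for fn, p, q in rows:
                med_a, med_b = float(xa[fn].median()), float(xb[fn].median())
                if med_a != med_b:
                    higher = ca if med_a > med_b else cb
                else:
                    higher = ca if xa[fn].mean() >= xb[fn].mean() else cb
                results.append(DifferentialResult(fn, (ca, cb), float(p), float(q), higher))
            out[(ca, cb)] = results
    return out


def substrate_apportion(function_ids, abundances, catalogue: ReferenceCatalogue,
                        ) -> tuple[dict[str, float], float]:
    """Pool selected enzymes' abundances over the seven substrate classes.

    Each function's abundance is split across its substrate classes
    proportionally to the catalogue's substrate weights, then pooled and
    normalised to sum to 1.  Functions with no substrate annotation are
    booked to an 'Unannotated' mass returned separately and excluded from
    the normalisation.
    """
    pooled = {s: 0.0 for s in SUBSTRATE_CLASSES}
    unannotated = 0.0
    for fid, ab in zip(function_ids, abundances):
        weights = catalogue.function_substrates(fid)
        weights = {s: w for s, w in weights.items() if s in SUBSTRATE_CLASSES and w > 0}
        total = sum(weights.values())
        if total <= 0:
            unannotated += ab
            continue
        for s, w in weights.items():
            pooled[s] += ab * w / total
    grand = sum(pooled.values())
    if grand > 0:
        pooled = {s: v / grand for s, v in pooled.items()}
    return pooled, unannotated


def plot_embedding(points, labels, path) -> None:
    """Scatter plot (PNG) of a 2-D embedding coloured by cluster label."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    x = np.asarray(points, dtype=float)
    labels = np.asarray(list(labels))
    fig, ax = plt.subplots(figsize=(5, 4))
    for lab in sorted(set(labels.tolist())):
        mask = labels == lab
        ax.scatter(x[mask, 0], x[mask, 1], s=18, label=f"cluster {lab}")
    ax.set_xlabel("t-SNE 1")
    ax.set_ylabel("t-SNE 2")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


@dataclass
class ClusterSummary:
    cluster_means: dict[int, float]
    pairwise_p: dict[tuple[int, int], float]
    diversity: list[DiversityResult]


def cluster_summary(profiles: list[SampleProfile], labels: dict[str, int],
                    ) -> ClusterSummary:
    """Per-cluster mean glycan fraction, pairwise rank-sum p-values on the
    per-sample fractions, and three Shannon indices per sample (degradation
    genes, synthesis genes, organisms at genus rank)."""
    by_cluster: dict[int, list[float]] = {}
    for p in profiles:
        by_cluster.setdefault(labels[p.sample_id], []).append(p.glycan_fraction_pct)
    means = {c: float(np.mean(v)) for c, v in sorted(by_cluster.items())}
    pairwise: dict[tuple[int, int], float] = {}
    clusters = sorted(by_cluster)
    for i, ca in enumerate(clusters):
        for cb in clusters[i + 1:]:
            if len(by_cluster[ca]) < 3 or len(by_cluster[cb]) < 3:
                warnings.warn(f"skipping pair ({ca},{cb}): cluster too small")
                continue
            pairwise[(ca, cb)] = rank_sum_test(by_cluster[ca], by_cluster[cb])

    diversity: list[DiversityResult] = []
    for p in profiles:
        for basis, table in (
            ("degradation_genes", p.role_tables["degradation"]),
            ("synthesis_genes", p.role_tables["synthesis"]),
            ("organisms", p.taxon_rel["genus"]),
        ):
            values = [v for v in table.values() if v > 0]
            if not values:
                continue
            diversity.append(DiversityResult(p.sample_id, basis,
                                             shannon_index(values), len(values)))
    return ClusterSummary(means, pairwise, diversity)
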