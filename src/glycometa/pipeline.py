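"""End-to-end cohort workflow: simulate -> host-filter -> annotate ->
profile -> embed/cluster -> differential + substrate apportionment.

This is the programmatic entry point the command-line interface, the test
suite and the acceptance script all share, so every consumer exercises the
same code path.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .annotate import AlignParams, annotate_sample
from .host_filter import build_host_index, filter_host_reads
from .profile import SampleProfile, build_profile, cohort_matrix
from .refdb import ReferenceCatalogue
from .stats import (ClusterSummary, cluster_summary, consensus_clusters,
                    substrate_apportion, top_k_differential)
from .synthetic import (CohortData, RegimeSpec, default_regimes,
                        generate_catalogue, generate_cohort, generate_host)

DEFAULT_N_SAMPLES = 10
DEFAULT_N_READS = 20_000
DEFAULT_READ_LEN = 150
DEFAULT_HOST_BP = 20_000


def default_catalogue(seed: int = 0) -> ReferenceCatalogue:
    """The study's default toy catalogue: 10 families x 4 entries over the
    five analysed classes, cycling the toy genera and substrate classes."""
    return generate_catalogue(10, 4, seed=seed)


@dataclass
class SampleResult:
    sample_id: str
    cluster_true: int
    n_reads_in: int
    n_host_removed: int
    profile: SampleProfile
    truth_glycan_pct: float


@dataclass
class CohortResult:
    samples: list[SampleResult]
    matrix_degradation: pd.DataFrame
    matrix_synthesis: pd.DataFrame
    embedding: np.ndarray
    labels_true: dict[str, int]
    labels_called: dict[str, int]
    ari: float
    summary: ClusterSummary
    differential: dict
    substrate_shares: dict = field(default_factory=dict)

    @property
    def profiles(self) -> list[SampleProfile]:
        return [s.profile for s in self.samples]

    def cluster_mean_fraction(self, by: str = "called") -> dict[int, float]:
        labels = self.labels_called if by == "called" else self.labels_true
        acc: dict[int, list[float]] = {}
        for s in self.samples:
            acc.setdefault(labels[s.sample_id], []).append(s.profile.glycan_fraction_pct)
        return {c: float(np.mean(v)) for c, v in sorted(acc.items())}


def analyze_cohort(cohort: CohortData, catalogue: ReferenceCatalogue, host: str,
                   params: AlignParams | None = None, host_k: int = 31,
                   host_kmer_frac: float = 0.5, k_clusters: int | None = None,
                   top_k: int = 20, seed: int = 0) -> CohortResult:
    """Run the full analysis on an in-memory cohort.

    The returned object carries per-sample profiles, the degradation and
    synthesis cohort matrices, the seeded 2-D embedding, called cluster
    labels (renumbered by ascending mean glycan fraction), the adjusted
    Rand index against the planted labels, cluster summaries, per-pair
    differential enzymes and their substrate apportionment.
    """
    params = params or AlignParams()
    host_index = build_host_index(host, k=host_k)
    if k_clusters is None:
        k_clusters = len(set(s.cluster for s in cohort.samples))

    samples: list[SampleResult] = []
    for s in cohort.samples:
        kept, freport = filter_host_reads(s.reads, host_index, host_kmer_frac)
        assignments, _areport = annotate_sample(kept, catalogue, params)
        profile = build_profile(s.sample_id, assignments, len(kept), catalogue)
        truth_glycan = float((s.truth["origin"] == "glycan").sum())
        truth_non_host = float((s.truth["origin"] != "host").sum())
        samples.append(SampleResult(
            sample_id=s.sample_id, cluster_true=s.cluster,
            n_reads_in=len(s.reads), n_host_removed=freport.n_removed_host,
            profile=profile,
            truth_glycan_pct=100.0 * truth_glycan / truth_non_host if truth_non_host else 0.0,
        ))

    profiles = [s.profile for s in samples]
    mat_deg = cohort_matrix(profiles, "degradation")
    mat_syn = cohort_matrix(profiles, "synthesis")

    fractions = {p.sample_id: p.glycan_fraction_pct for p in profiles}
    called, embedding = consensus_clusters(mat_deg, list(mat_deg.index),
                                           k=k_clusters, seed=seed,
                                           glycan_fractions=fractions)
    labels_called = {c.sample_id: c.cluster_label for c in called}
    labels_true = cohort.labels_true
    ids = list(mat_deg.index)
    ari = float(adjusted_rand_score([labels_true[i] for i in ids],
                                    [labels_called[i] for i in ids]))

    summary = cluster_summary(profiles, labels_called)
    diff = top_k_differential(mat_deg, [labels_called[i] for i in ids], k=top_k)

    shares: dict = {}
    for pair, results in diff.items():
        for side in pair:
            chosen = [r for r in results if r.higher_in == side]
            if not chosen:
                continue
            fids = [r.function_id for r in chosen]
            side_rows = mat_deg.loc[[i for i in ids if labels_called[i] == side]]
            means = [float(side_rows[f].mean()) for f in fids]
            pooled, unann = substrate_apportion(fids, means, catalogue)
            shares[(pair, side)] = pooled
            for r in chosen:
                r.substrate_shares = substrate_apportion([r.function_id], [1.0], catalogue)[0]

    return CohortResult(samples, mat_deg, mat_syn, embedding, labels_true,
                        labels_called, ari, summary, diff, shares)


def run_default_cohort(seed: int, n_samples_per_regime: int = DEFAULT_N_SAMPLES,
                       n_reads: int = DEFAULT_N_READS,
                       read_len_bp: int = DEFAULT_READ_LEN,
                       regimes: list[RegimeSpec] | None = None) -> CohortResult:
    """Generate and analyse the default three-regime cohort under `seed`."""
    regimes = regimes or default_regimes()
    catalogue = default_catalogue(seed=0)
    host = generate_host(DEFAULT_HOST_BP, seed=1)
    cohort = generate_cohort(catalogue, host,
                             [(r, n_samples_per_regime) for r in regimes],
                             n_reads=n_reads, read_len_bp=read_len_bp, seed=seed)
    return analyze_cohort(cohort, catalogue, host, seed=seed)
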