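"""Per-sample abundance profiles built from read assignments.

A sample profile carries, all relative to the post-host-filter read count or
to the glycan read count as appropriate: the glycan fraction (percentage of
reads assigned to CAZyme references), the class composition over
GH/GT/CE/PL/CBM (AA assignments are excluded before normalisation), family
counts, the family-to-enzyme-function distribution, the split of function
mass into degradation (GH/CE/PL) and synthesis (GT) roles, and taxon
profiles at phylum / family / genus rank.  Mass is conserved at every stage:
each counted read contributes exactly 1/n_glycan of abundance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .annotate import ReadAssignment
from .refdb import ReferenceCatalogue

ANALYSIS_CLASSES = ("GH", "GT", "CE", "PL", "CBM")
DEGRADATION_CLASSES = ("GH", "CE", "PL")
SYNTHESIS_CLASSES = ("GT",)
ROLE_CLASSES = DEGRADATION_CLASSES + SYNTHESIS_CLASSES


@dataclass
class SampleProfile:
    sample_id: str
    n_reads_total: int
    n_glycan: int
    class_rel: dict[str, float]
    family_counts: dict[str, int]
    function_rel: dict[str, float]
    function_class_mass: dict[tuple[str, str], float]
    role_tables: dict[str, dict[str, float]]
    taxon_rel: dict[str, dict[str, float]]
    empty: bool = False

    @property
    def glycan_fraction_pct(self) -> float:
        return 100.0 * self.n_glycan / self.n_reads_total if self.n_reads_total else 0.0


def class_composition(assignments: list[ReadAssignment], n_reads_total: int,
                      ) -> tuple[list[ReadAssignment], dict[str, float]]:
    """Drop AA assignments, then normalise class counts by the glycan read
    count.  Returns (kept assignments, class_rel)."""
    kept = [a for a in assignments if a.cazy_class in ANALYSIS_CLASSES]
    n = len(kept)
    counts = {c: 0 for c in ANALYSIS_CLASSES}
    for a in kept:
        counts[a.cazy_class] += 1
    rel = {c: (counts[c] / n if n else 0.0) for c in ANALYSIS_CLASSES}
    return kept, rel


def distribute_family_to_function(assignments: list[ReadAssignment],
                                  catalogue: ReferenceCatalogue,
                                  n_glycan: int) -> dict[tuple[str, str], float]:
    """Distribute each GH/GT/CE/PL read's mass (1/n_glycan) over the enzyme
    functions of its assigned entry, proportionally to function weights.

    Entries without function annotation fall back to the catalogue-wide
    function table of their family (weights proportional to the number of
    entries per function); a family with no annotated functions anywhere
    books the mass to ``<family>:unknown``.  Keys are (function, class) so
    the role split can keep degradation and synthesis masses apart.
    """
    mass: dict[tuple[str, str], float] = {}
    if n_glycan == 0:
        return mass
    unit = 1.0 / n_glycan
    family_tables: dict[str, dict[str, float]] = {}
    for a in assignments:
        if a.cazy_class not in ROLE_CLASSES:
            continue
        weights = {fid: w for fid, w in a.functions if w > 0}
        if not weights:
            if a.family not in family_tables:
                family_tables[a.family] = catalogue.family_function_table(a.family)
            weights = family_tables[a.family]
        if not weights:
            weights = {f"{a.family}:unknown": 1.0}
        total = sum(weights.values())
        for fid, w in weights.items():
            key = (fid, a.cazy_class)
            mass[key] = mass.get(key, 0.0) + unit * w / total
    return mass


def split_roles(function_class_mass: dict[tuple[str, str], float]) -> dict[str, dict[str, float]]:
    """Degradation table from GH/CE/PL contributions, synthesis from GT.
    A function reached through both appears in both tables with separate
    masses; CBM contributes to neither."""
    tables: dict[str, dict[str, float]] = {"degradation": {}, "synthesis": {}}
    for (fid, cls), m in function_class_mass.items():
        role = "degradation" if cls in DEGRADATION_CLASSES else "synthesis"
        tables[role][fid] = tables[role].get(fid, 0.0) + m
    return tables


def taxon_profile(assignments: list[ReadAssignment], rank: str,
                  n_glycan: int) -> dict[str, float]:
    """Relative abundance of taxa at `rank`; missing lineage -> 'unclassified'."""
    if rank not in ("phylum", "family", "genus"):
        raise ValueError(f"unsupported rank: {rank}")
    counts: dict[str, float] = {}
    for a in assignments:
        name = a.taxon.get(rank, "unclassified")
        counts[name] = counts.get(name, 0.0) + 1.0
    if n_glycan:
        counts = {k: v / n_glycan for k, v in counts.items()}
    return counts


def build_profile(sample_id: str, assignments: list[ReadAssignment],
                  n_reads_total: int, catalogue: ReferenceCatalogue) -> SampleProfile:
    """Assemble the full per-sample profile from one sample's assignments."""
    kept, class_rel = class_composition(assignments, n_reads_total)
    n_glycan = len(kept)
    family_counts: dict[str, int] = {}
    for a in kept:
        family_counts[a.family] = family_counts.get(a.family, 0) + 1
    fc_mass = distribute_family_to_function(kept, catalogue, n_glycan)
    function_rel: dict[str, float] = {}
    for (fid, _cls), m in fc_mass.items():
        function_rel[fid] = function_rel.get(fid, 0.0) + m
    return SampleProfile(
        sample_id=sample_id, n_reads_total=n_reads_total, n_glycan=n_glycan,
        class_rel=class_rel, family_counts=family_counts,
        function_rel=function_rel, function_class_mass=fc_mass,
        role_tables=split_roles(fc_mass),
        taxon_rel={r: taxon_profile(kept, r, n_glycan) for r in ("phylum", "family", "genus")},
        empty=(n_glycan == 0),
    )


def cohort_matrix(profiles: list[SampleProfile], role: str) -> pd.DataFrame:
    """Samples x enzyme-functions matrix for one role, zero-filled over the
    union of functions; row order follows the input order."""
    if role not in ("degradation", "synthesis"):
        raise ValueError(f"role must be degradation or synthesis, got {role!r}")
    if len(profiles) < 2:
        raise ValueError("need at least 2 profiles")
    ids = [p.sample_id for p in profiles]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sample_id in profiles")
    columns = sorted({fid for p in profiles for fid in p.role_tables[role]})
    data = [[p.role_tables[role].get(fid, 0.0) for fid in columns] for p in profiles]
    return pd.DataFrame(data, index=ids, columns=columns)


def log10_heatmap_values(matrix: pd.DataFrame) -> pd.DataFrame:
    """log10 of relative abundances for heatmap display; zeros are floored
    at log10 of half the smallest nonzero cell so they stay visually below
    every observed value."""
    values = matrix.to_numpy(copy=True)
    nonzero = values[values > 0]
    if nonzero.size == 0:
        return matrix * 0.0
    floor = math.log10(0.5 * nonzero.min())
    out = matrix.copy()
    for j, col in enumerate(out.columns):
        out[col] = [math.log10(v) if v > 0 else floor for v in values[:, j]]
    return out


def export_heatmap(matrix: pd.DataFrame, path, row_order=None) -> None:
    """Minimal log10 abundance heatmap (PNG) of a cohort matrix."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    values = log10_heatmap_values(matrix)
    if row_order is not None:
        values = values.loc[row_order]
    fig, ax = plt.subplots(figsize=(max(4, 0.2 * values.shape[1]),
                                    max(3, 0.2 * values.shape[0])))
    im = ax.imshow(values.to_numpy(), aspect="auto", cmap="viridis")
    ax.set_yticks(range(len(values.index)), values.index, fontsize=5)
    ax.set_xticks(range(len(values.columns)), values.columns, rotation=90, fontsize=5)
    fig.colorbar(im, ax=ax, label="log10 relative abundance")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def profiles_frame(profiles: list[SampleProfile]) -> pd.DataFrame:
    """Wide per-sample summary table (one row per sample)."""
    rows = []
    for p in profiles:
        row: dict[str, object] = {
            "sample_id": p.sample_id,
            "n_reads_total": p.n_reads_total,
            "n_glycan": p.n_glycan,
            "glycan_fraction_pct": p.glycan_fraction_pct,
        }
        for c in ANALYSIS_CLASSES:
            row[f"class_{c}"] = p.class_rel.get(c, 0.0)
        rows.append(row)
    return pd.DataFrame(rows).set_index("sample_id")
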