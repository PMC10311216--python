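"""Seeded generators for toy catalogues, host genomes and metagenome cohorts.

The generators plant known truth: every emitted read carries an origin
(glycan / background / host), glycan reads are reverse-translated windows of
catalogue proteins with a controlled amino-acid identity to their source
entry, and cohorts are built from per-cluster regimes that fix the glycan
fraction, the substrate / role / genus mixes and the identity band.  A truth
table accompanies every sample so that downstream stages can be scored
against the planted ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from ._encoding import AA_TO_CODONS, revcomp
from .refdb import SUBSTRATE_CLASSES, ReferenceCatalogue, ReferenceEntry

#: Toy gut taxonomy covering the genera most often discussed for this system.
TOY_TAXONOMY: dict[str, dict[str, str]] = {
    "Bacteroides": {"phylum": "Bacteroidota", "family": "Bacteroidaceae"},
    "Phocaeicola": {"phylum": "Bacteroidota", "family": "Bacteroidaceae"},
    "Ruminococcus": {"phylum": "Bacillota", "family": "Oscillospiraceae"},
    "Bifidobacterium": {"phylum": "Actinomycetota", "family": "Bifidobacteriaceae"},
    "Blautia": {"phylum": "Bacillota", "family": "Lachnospiraceae"},
    "Faecalibacterium": {"phylum": "Bacillota", "family": "Oscillospiraceae"},
}

_AA20 = "ACDEFGHIKLMNPQRSTVWY"


def _check_distribution(name: str, dist: dict[str, float]) -> None:
    if not dist:
        raise ValueError(f"{name} must be a non-empty distribution")
    total = sum(dist.values())
    if any(v < 0 for v in dist.values()) or abs(total - 1.0) > 1e-9:
        raise ValueError(f"{name} must be non-negative and sum to 1 (got {total})")


@dataclass
class RegimeSpec:
    """Study conditions for one sample cluster."""

    name: str
    glycan_fraction: float
    substrate_mix: dict[str, float]
    role_mix: dict[str, float]
    taxon_mix: dict[str, float]
    identity_band: tuple[float, float] = (0.92, 0.99)
    host_fraction: float = 0.02

    def __post_init__(self):
        if not 0.0 <= self.glycan_fraction <= 1.0:
            raise ValueError("glycan_fraction must be in [0, 1]")
        lo, hi = self.identity_band
        if not 0.0 <= lo <= hi <= 1.0:
            raise ValueError("identity_band must satisfy 0 <= lo <= hi <= 1")
        if self.glycan_fraction + self.host_fraction > 1.0:
            raise ValueError("glycan_fraction + host_fraction exceeds 1")
        _check_distribution("substrate_mix", self.substrate_mix)
        _check_distribution("role_mix", self.role_mix)
        _check_distribution("taxon_mix", self.taxon_mix)

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "glycan_fraction": self.glycan_fraction,
            "substrate_mix": dict(self.substrate_mix),
            "role_mix": dict(self.role_mix),
            "taxon_mix": dict(self.taxon_mix),
            "identity_band": list(self.identity_band),
            "host_fraction": self.host_fraction,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RegimeSpec":
        d = dict(d)
        d["identity_band"] = tuple(d.get("identity_band", (0.92, 0.99)))
        return cls(**d)


def save_regimes(regimes: list[RegimeSpec], path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump([r.to_dict() for r in regimes], fh, sort_keys=False)


def load_regimes(path) -> list[RegimeSpec]:
    with open(path) as fh:
        return [RegimeSpec.from_dict(d) for d in yaml.safe_load(fh)]


def default_regimes() -> list[RegimeSpec]:
    """The three-cluster study conditions.

    Planted glycan fractions are 1.8 / 2.4 / 3.6 % (lowest, intermediate and
    highest glycan-gene content).  Cluster 1 leans towards animal / mucin /
    peptidoglycan / fungal substrates carried by Bacillota and
    Actinomycetota genera; clusters 2 and 3 lean towards plant-derived
    polysaccharides, with cluster 3 dominated by Bacteroidota genera.
    """
    return [
        RegimeSpec(
            name="cluster1", glycan_fraction=0.018,
            substrate_mix={"Animal": 0.30, "Mucin": 0.30, "Peptidoglycan": 0.20, "Fungal": 0.20},
            role_mix={"degradation": 0.78, "synthesis": 0.22},
            taxon_mix={"Blautia": 0.30, "Faecalibacterium": 0.25,
                       "Bifidobacterium": 0.25, "Ruminococcus": 0.20},
        ),
        RegimeSpec(
            name="cluster2", glycan_fraction=0.024,
            substrate_mix={"Plant": 0.45, "Starch": 0.30, "Sucrose": 0.15,
                           "Mucin": 0.05, "Animal": 0.05},
            role_mix={"degradation": 0.78, "synthesis": 0.22},
            taxon_mix={"Faecalibacterium": 0.35, "Ruminococcus": 0.30,
                       "Blautia": 0.20, "Bifidobacterium": 0.15},
        ),
        RegimeSpec(
            name="cluster3", glycan_fraction=0.036,
            substrate_mix={"Plant": 0.70, "Starch": 0.15, "Sucrose": 0.05,
                           "Animal": 0.05, "Mucin": 0.05},
            role_mix={"degradation": 0.78, "synthesis": 0.22},
            taxon_mix={"Bacteroides": 0.55, "Phocaeicola": 0.35, "Blautia": 0.10},
        ),
    ]


# --------------------------------------------------------------------------
# Catalogue and host generators
# --------------------------------------------------------------------------

def generate_catalogue(n_families: int, entries_per_family: int, seed: int,
                       aa_len_range: tuple[int, int] = (150, 250),
                       classes: tuple[str, ...] = ("GH", "GT", "CE", "PL", "CBM"),
                       ) -> ReferenceCatalogue:
    """Deterministic toy catalogue.

    Families take classes round-robin (AA omitted by default because it is
    excluded from the analyses); entries cycle through the toy genera and
    the seven substrate classes so that every regime mix has support.  Pairs
    of entries within a family share an enzyme function, and every third
    entry carries a second function, exercising the weighted distribution
    rules downstream.
    """
    if n_families < 1 or entries_per_family < 1:
        raise ValueError("n_families and entries_per_family must be >= 1")
    rng = np.random.default_rng(seed)
    genera = list(TOY_TAXONOMY)
    entries: list[ReferenceEntry] = []
    idx = 0
    for i in range(n_families):
        cls = classes[i % len(classes)]
        family = f"{cls}{10 + i}"
        for j in range(entries_per_family):
            aa_len = int(rng.integers(aa_len_range[0], aa_len_range[1] + 1))
            aa_seq = "".join(rng.choice(list(_AA20), size=aa_len))
            genus = genera[idx % len(genera)]
            lineage = dict(TOY_TAXONOMY[genus])
            lineage["genus"] = genus
            lineage["species"] = f"{genus} sp{j + 1}"
            functions = [(f"{3 if cls != 'GT' else 2}.4.{10 + i}.{1 + j // 2}", 1.0)]
            if idx % 3 == 0:
                functions.append((f"{3 if cls != 'GT' else 2}.4.{10 + i}.{90 + j}", 1.0))
            substrates = [(SUBSTRATE_CLASSES[idx % 7], 1.0)]
            if idx % 2 == 1:
                second = SUBSTRATE_CLASSES[(idx * 3 + 1) % 7]
                if second != substrates[0][0]:
                    substrates.append((second, 1.0))
            entries.append(ReferenceEntry(
                ref_id=f"{family.lower()}.e{j}", aa_seq=aa_seq, family=family,
                cazy_class=cls, functions=functions, substrates=substrates,
                taxon=lineage,
            ))
            idx += 1
    return ReferenceCatalogue(entries)


_HOST_P = np.array([0.295, 0.205, 0.205, 0.295])  # A C G T, GC ~ 0.41
_NT_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _decode_nt(mat: np.ndarray) -> list[str]:
    arr = _NT_BYTES[mat]
    if arr.ndim == 1:
        return [arr.tobytes().decode()]
    return [row.tobytes().decode() for row in arr]


def generate_host(length_bp: int, seed: int) -> str:
    """Deterministic surrogate host chromosome at human-like GC (~41%)."""
    if length_bp < 1:
        raise ValueError("length_bp must be positive")
    rng = np.random.default_rng(seed)
    codes = rng.choice(4, size=length_bp, p=_HOST_P)
    return _decode_nt(codes.astype(np.uint8))[0]


# --------------------------------------------------------------------------
# Sample and cohort generators
# --------------------------------------------------------------------------

TRUTH_COLUMNS = ("read_id", "origin", "source_ref_id", "planted_identity", "strand", "frame")


def _entry_weights(catalogue: ReferenceCatalogue, regime: RegimeSpec):
    """Per-genus entry sampling weights under a regime's substrate and role
    mixes.  A genus whose entries give zero total weight falls back to a
    uniform draw over that genus (keeps the taxon marginal exact)."""
    absent = set(regime.substrate_mix) - {s for e in catalogue.entries for s, _ in e.substrates}
    if absent:
        raise ValueError(f"regime references substrate classes absent from catalogue: {sorted(absent)}")
    by_genus: dict[str, list[int]] = {}
    for k, e in enumerate(catalogue.entries):
        by_genus.setdefault(e.taxon.get("genus", "unclassified"), []).append(k)
    missing = set(regime.taxon_mix) - set(by_genus)
    if missing:
        raise ValueError(f"regime references genera absent from catalogue: {sorted(missing)}")
    weights: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for genus, idxs in by_genus.items():
        w = np.zeros(len(idxs))
        for pos, k in enumerate(idxs):
            e = catalogue.entries[k]
            total = sum(wt for _s, wt in e.substrates)
            sub = sum(regime.substrate_mix.get(s, 0.0) * wt for s, wt in e.substrates)
            sub = sub / total if total > 0 else 0.0
            role = regime.role_mix.get(e.role, 0.0) if e.role else 0.0
            w[pos] = sub * role
        if w.sum() <= 0:
            w[:] = 1.0
        weights[genus] = (np.asarray(idxs), w / w.sum())
    return weights


def _plant_read(rng: np.random.Generator, entry: ReferenceEntry, read_len_bp: int,
                identity_band: tuple[float, float]):
    """Reverse-translate a window of `entry` into one read; returns
    (nt_seq, planted_identity, strand, frame)."""
    pad_start = int(rng.integers(0, 3))
    aa_len = (read_len_bp - pad_start) // 3
    aa_len = min(aa_len, len(entry.aa_seq))
    offset = int(rng.integers(0, len(entry.aa_seq) - aa_len + 1))
    window = list(entry.aa_seq[offset:offset + aa_len])

    lo, hi = identity_band
    target = rng.uniform(lo, hi)
    n_sub = int(round(aa_len * (1.0 - target)))
    planted_identity = 1.0 - n_sub / aa_len
    if n_sub > 0:
        for pos in rng.choice(aa_len, size=n_sub, replace=False):
            choices = [a for a in _AA20 if a != window[pos]]
            window[pos] = choices[int(rng.integers(0, len(choices)))]

    codons = []
    for aa in window:
        opts = AA_TO_CODONS[aa]
        codons.append(opts[int(rng.integers(0, len(opts)))])
    pad_end = read_len_bp - pad_start - 3 * aa_len
    head = _decode_nt(rng.integers(0, 4, size=pad_start).astype(np.uint8))[0] if pad_start else ""
    tail = _decode_nt(rng.integers(0, 4, size=pad_end).astype(np.uint8))[0] if pad_end else ""
    nt = head + "".join(codons) + tail
    frame = pad_start + 1
    if rng.random() < 0.5:
        return revcomp(nt), planted_identity, "-", frame
    return nt, planted_identity, "+", frame


def generate_sample(catalogue: ReferenceCatalogue, host: str, regime: RegimeSpec,
                    n_reads: int, read_len_bp: int = 150, seed=0,
                    sample_id: str = "S") -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Generate one sample's reads plus its per-read truth table.

    Glycan reads are reverse-translated (uniform synonymous codons, no
    indels) windows of catalogue entries with substitutions planted to hit
    the regime's identity band, on a random strand and frame; background
    reads are uniform-random nucleotides; host reads are verbatim host
    substrings (half reverse-complemented).
    """
    if read_len_bp < 75:
        raise ValueError("read_len_bp must be >= 75 (needs to encode >= 25 aa)")
    rng = np.random.default_rng(seed)
    weights = _entry_weights(catalogue, regime)
    genera = sorted(regime.taxon_mix)
    genus_p = np.array([regime.taxon_mix[g] for g in genera])
    genus_p = genus_p / genus_p.sum()

    p = np.array([regime.glycan_fraction, regime.host_fraction,
                  1.0 - regime.glycan_fraction - regime.host_fraction])
    origin_codes = rng.choice(3, size=n_reads, p=p)

    n_bg = int((origin_codes == 2).sum())
    bg_seqs = iter(_decode_nt(rng.integers(0, 4, size=(n_bg, read_len_bp)).astype(np.uint8))
                   if n_bg else [])

    reads: list[tuple[str, str]] = []
    truth_rows = []
    origin_names = ("glycan", "host", "background")
    for i, code in enumerate(origin_codes):
        rid = f"{sample_id}:r{i:06d}"
        origin = origin_names[code]
        src, identity, strand, frame = "", np.nan, "", 0
        if code == 0:
            genus = genera[int(rng.choice(len(genera), p=genus_p))]
            idxs, w = weights[genus]
            entry = catalogue.entries[int(idxs[rng.choice(len(idxs), p=w)])]
            seq, identity, strand, frame = _plant_read(rng, entry, read_len_bp,
                                                       regime.identity_band)
            src = entry.ref_id
        elif code == 1:
            start = int(rng.integers(0, len(host) - read_len_bp + 1))
            seq = host[start:start + read_len_bp]
            strand = "+"
            if rng.random() < 0.5:
                seq, strand = revcomp(seq), "-"
        else:
            seq = next(bg_seqs)
        reads.append((rid, seq))
        truth_rows.append((rid, origin, src, identity, strand, frame))

    truth = pd.DataFrame(truth_rows, columns=list(TRUTH_COLUMNS))
    return reads, truth


@dataclass
class SampleData:
    sample_id: str
    regime_name: str
    cluster: int
    reads: list[tuple[str, str]]
    truth: pd.DataFrame


@dataclass
class CohortData:
    samples: list[SampleData] = field(default_factory=list)

    @property
    def labels_true(self) -> dict[str, int]:
        return {s.sample_id: s.cluster for s in self.samples}


def generate_cohort(catalogue: ReferenceCatalogue, host: str,
                    cluster_specs: list[tuple[RegimeSpec, int]],
                    n_reads: int, read_len_bp: int = 150, seed=0) -> CohortData:
    """Generate a labelled cohort; per-sample seeds derive from the cohort
    seed via numpy SeedSequence spawning, so the cohort is reproducible and
    samples are independent."""
    if len(cluster_specs) < 2:
        raise ValueError("need >= 2 regimes for between-cluster analyses")
    total = sum(n for _r, n in cluster_specs)
    children = np.random.SeedSequence(seed).spawn(total)
    cohort = CohortData()
    k = 0
    for ci, (regime, n_samples) in enumerate(cluster_specs, start=1):
        for si in range(n_samples):
            sid = f"c{ci}s{si:02d}"
            reads, truth = generate_sample(catalogue, host, regime, n_reads,
                                           read_len_bp, seed=children[k], sample_id=sid)
            cohort.samples.append(SampleData(sid, regime.name, ci, reads, truth))
            k += 1
    return cohort


def planted_effect_matrix(n_a: int = 15, n_b: int = 15, n_functions: int = 40,
                          n_enriched: int = 5, fold: float = 4.0,
                          sigma: float = 0.3, seed=0):
    """Samples x functions abundance matrix with `n_enriched` functions
    multiplied by `fold` in group B; returns (DataFrame, enriched ids,
    labels array).  Used to benchmark the differential-abundance stage."""
    rng = np.random.default_rng(seed)
    mu = rng.uniform(-7.0, -4.0, size=n_functions)
    log_x = rng.normal(mu, sigma, size=(n_a + n_b, n_functions))
    x = np.exp(log_x)
    enriched = sorted(rng.choice(n_functions, size=n_enriched, replace=False))
    x[n_a:, enriched] *= fold
    cols = [f"fn{j:03d}" for j in range(n_functions)]
    labels = np.array([1] * n_a + [2] * n_b)
    index = [f"a{i:02d}" for i in range(n_a)] + [f"b{i:02d}" for i in range(n_b)]
    return pd.DataFrame(x, columns=cols, index=index), [cols[j] for j in enriched], labels


# --------------------------------------------------------------------------
# Plain-text read I/O
# --------------------------------------------------------------------------

def write_fastq(reads: list[tuple[str, str]], path, quality_char: str = "?") -> None:
    """FASTQ with constant placeholder qualities (Q30 by default)."""
    with open(path, "w") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{quality_char * len(seq)}\n")


def read_sequences(path) -> list[tuple[str, str]]:
    """Read FASTA or FASTQ (sniffed from the first byte) into (id, seq)."""
    from Bio import SeqIO
    with open(path) as fh:
        first = fh.read(1)
    fmt = "fastq" if first == "@" else "fasta"
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), fmt)]
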