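"""Annotated CAZyme reference catalogue: data model and I/O.

The catalogue couples protein sequences (one FASTA record per reference
gene) with a tab-separated annotation table carrying, per entry, the CAZy
family (e.g. ``GH13``), the class (GH/GT/CE/PL/CBM/AA), weighted enzyme
functions (EC numbers or names), weighted substrate classes (Plant, Animal,
Mucin, Fungal, Peptidoglycan, Sucrose, Starch) and a partial taxonomic
lineage.  Twelve-column tabular alignment hit files (the common BLAST-like
dialect) can be read and written for interoperability with external
translated-search tools.
"""

from __future__ import annotations

import collections
from dataclasses import dataclass, field, replace
from pathlib import Path

from Bio import SeqIO

#: Recognised CAZy classes.  AA (auxiliary activities) is accepted at load
#: but excluded from downstream analyses.
CAZY_CLASSES = ("GH", "GT", "CE", "PL", "CBM", "AA")

#: The seven substrate origin classes used for apportionment.
SUBSTRATE_CLASSES = ("Plant", "Animal", "Mucin", "Fungal", "Peptidoglycan", "Sucrose", "Starch")

TAXON_RANKS = ("phylum", "family", "genus", "species")

#: Entries shorter than this can never satisfy the >=25 aa alignment rule.
MIN_ENTRY_AA = 25


@dataclass
class ReferenceEntry:
    """One annotated CAZyme protein."""

    ref_id: str
    aa_seq: str
    family: str
    cazy_class: str
    functions: list[tuple[str, float]] = field(default_factory=list)
    substrates: list[tuple[str, float]] = field(default_factory=list)
    taxon: dict[str, str] = field(default_factory=dict)

    @property
    def role(self) -> str | None:
        """'degradation' for GH/CE/PL, 'synthesis' for GT, else None."""
        if self.cazy_class in ("GH", "CE", "PL"):
            return "degradation"
        if self.cazy_class == "GT":
            return "synthesis"
        return None


@dataclass
class LoadReport:
    n_total: int = 0
    n_loaded: int = 0
    dropped_short: int = 0
    dropped_class: int = 0


class ReferenceCatalogue:
    """Container over ReferenceEntry with id lookup and a seed k-mer index."""

    def __init__(self, entries: list[ReferenceEntry]):
        self.entries = list(entries)
        self.index: dict[str, ReferenceEntry] = {}
        for e in self.entries:
            if e.ref_id in self.index:
                raise ValueError(f"duplicate ref_id {e.ref_id!r}")
            self.index[e.ref_id] = e
        self._kmer_index: dict[str, list[tuple[str, int]]] | None = None
        self._kmer_k: int | None = None

    def __len__(self) -> int:
        return len(self.entries)

    def lookup(self, ref_id: str) -> ReferenceEntry:
        return self.index[ref_id]

    def kmer_index(self, k: int = 4) -> dict[str, list[tuple[str, int]]]:
        """aa k-mer -> list of (ref_id, offset) postings; built lazily,
        regeneration from entries is idempotent."""
        if self._kmer_index is None or self._kmer_k != k:
            idx: dict[str, list[tuple[str, int]]] = collections.defaultdict(list)
            for e in self.entries:
                s = e.aa_seq
                for i in range(len(s) - k + 1):
                    idx[s[i:i + k]].append((e.ref_id, i))
            self._kmer_index = dict(idx)
            self._kmer_k = k
        return self._kmer_index

    # -- annotation aggregates used by the profiling stage -----------------

    def family_function_table(self, family: str) -> dict[str, float]:
        """function -> number of entries of `family` annotated with it."""
        table: dict[str, float] = collections.defaultdict(float)
        for e in self.entries:
            if e.family == family:
                for fid, _w in e.functions:
                    table[fid] += 1.0
        return dict(table)

    def function_substrates(self, function_id: str) -> dict[str, float]:
        """Pooled substrate weights of all entries carrying `function_id`."""
        table: dict[str, float] = collections.defaultdict(float)
        for e in self.entries:
            if any(fid == function_id for fid, _w in e.functions):
                for sub, w in e.substrates:
                    table[sub] += w
        return dict(table)


def _parse_weighted(cell: str) -> list[tuple[str, float]]:
    """Parse 'name[:weight];name[:weight];...' (empty cell -> [])."""
    out: list[tuple[str, float]] = []
    cell = cell.strip()
    if not cell or cell == "-":
        return out
    for token in cell.split(";"):
        token = token.strip()
        if not token:
            continue
        if ":" in token:
            name, w = token.rsplit(":", 1)
            out.append((name.strip(), float(w)))
        else:
            out.append((token, 1.0))
    return out


def _parse_taxonomy(cell: str) -> dict[str, str]:
    """Parse 'rank=name;rank=name' into a lineage dict."""
    taxon: dict[str, str] = {}
    cell = cell.strip()
    if not cell or cell == "-":
        return taxon
    for token in cell.split(";"):
        token = token.strip()
        if not token or "=" not in token:
            continue
        rank, name = token.split("=", 1)
        rank = rank.strip().lower()
        if rank in TAXON_RANKS and name.strip():
            taxon[rank] = name.strip()
    return taxon


def _format_weighted(items: list[tuple[str, float]]) -> str:
    return ";".join(f"{n}:{w:g}" if w != 1.0 else n for n, w in items) or "-"


def _format_taxonomy(taxon: dict[str, str]) -> str:
    return ";".join(f"{r}={taxon[r]}" for r in TAXON_RANKS if r in taxon) or "-"


ANNOTATION_COLUMNS = ("ref_id", "family", "class", "functions", "substrates", "taxonomy")


def load_catalogue(protein_fasta: str | Path, annotation_table: str | Path) -> tuple[ReferenceCatalogue, LoadReport]:
    """Load and validate a catalogue from a protein FASTA plus annotation TSV.

    Entries with sequences shorter than 25 aa (which can never satisfy the
    acceptance rule) or with an unrecognised class label, or whose family
    prefix contradicts the class, are dropped and counted in the report.
    A FASTA id missing from the table, or a duplicated ref_id, is a hard
    error.
    """
    records = list(SeqIO.parse(str(protein_fasta), "fasta"))
    seqs: dict[str, str] = {}
    for rec in records:
        if rec.id in seqs:
            raise ValueError(f"duplicate ref_id in FASTA: {rec.id!r}")
        seqs[rec.id] = str(rec.seq).upper()

    rows: dict[str, dict[str, str]] = {}
    with open(annotation_table) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        missing_cols = [c for c in ANNOTATION_COLUMNS if c not in header]
        if missing_cols:
            raise ValueError(f"annotation table missing columns: {missing_cols}")
        col = {c: header.index(c) for c in ANNOTATION_COLUMNS}
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            rid = parts[col["ref_id"]]
            if rid in rows:
                raise ValueError(f"duplicate ref_id in annotation table: {rid!r}")
            rows[rid] = {c: parts[col[c]] for c in ANNOTATION_COLUMNS}

    orphans = [rid for rid in seqs if rid not in rows]
    if orphans:
        raise ValueError(f"FASTA ids without annotation rows (first 10): {orphans[:10]}")

    report = LoadReport(n_total=len(seqs))
    entries: list[ReferenceEntry] = []
    for rid, aa in seqs.items():
        row = rows[rid]
        family = row["family"].strip()
        cls = row["class"].strip()
        if len(aa) < MIN_ENTRY_AA:
            report.dropped_short += 1
            continue
        if cls not in CAZY_CLASSES or not family.startswith(cls):
            report.dropped_class += 1
            continue
        substrates = _parse_weighted(row["substrates"])
        bad = [s for s, w in substrates if w <= 0]
        if bad:
            raise ValueError(f"non-positive substrate weight on {rid!r}")
        entries.append(ReferenceEntry(
            ref_id=rid, aa_seq=aa, family=family, cazy_class=cls,
            functions=_parse_weighted(row["functions"]),
            substrates=substrates,
            taxon=_parse_taxonomy(row["taxonomy"]),
        ))
    report.n_loaded = len(entries)
    return ReferenceCatalogue(entries), report


def write_catalogue(catalogue: ReferenceCatalogue, protein_fasta: str | Path, annotation_table: str | Path) -> None:
    """Write a catalogue back to FASTA + annotation TSV (inverse of load)."""
    with open(protein_fasta, "w") as fa:
        for e in catalogue.entries:
            fa.write(f">{e.ref_id}\n{e.aa_seq}\n")
    with open(annotation_table, "w") as tsv:
        tsv.write("\t".join(ANNOTATION_COLUMNS) + "\n")
        for e in catalogue.entries:
            tsv.write("\t".join([
                e.ref_id, e.family, e.cazy_class,
                _format_weighted(e.functions),
                _format_weighted(e.substrates),
                _format_taxonomy(e.taxon),
            ]) + "\n")


def deduplicate(catalogue: ReferenceCatalogue) -> ReferenceCatalogue:
    """Collapse entries with byte-identical protein sequences.

    The representative is the lexicographically smallest ref_id; functions
    and substrates of collapsed duplicates are merged by union with weights
    summed.  Lineages keep the representative's value per rank, falling back
    to the first duplicate carrying one.  Applying twice equals applying
    once.
    """
    groups: dict[str, list[ReferenceEntry]] = collections.defaultdict(list)
    for e in catalogue.entries:
        groups[e.aa_seq].append(e)

    keep: dict[str, ReferenceEntry] = {}
    for seq, members in groups.items():
        if len(members) == 1:
            keep[members[0].ref_id] = members[0]
            continue
        members = sorted(members, key=lambda e: e.ref_id)
        rep = members[0]
        functions: dict[str, float] = collections.defaultdict(float)
        substrates: dict[str, float] = collections.defaultdict(float)
        taxon: dict[str, str] = {}
        for m in members:
            for fid, w in m.functions:
                functions[fid] += w
            for sub, w in m.substrates:
                substrates[sub] += w
            for rank, name in m.taxon.items():
                taxon.setdefault(rank, name)
        keep[rep.ref_id] = replace(
            rep,
            functions=sorted(functions.items()),
            substrates=sorted(substrates.items()),
            taxon=taxon,
        )

    return ReferenceCatalogue([keep[e.ref_id] for e in catalogue.entries if e.ref_id in keep])


# --------------------------------------------------------------------------
# Tabular alignment hit files (12-column dialect)
# --------------------------------------------------------------------------

@dataclass
class HitRecord:
    """One accepted-candidate alignment row from a tabular hit file."""

    read_id: str
    ref_id: str
    identity_pct: float
    aln_len_aa: int
    score: float = 0.0
    frame: int = 0

    def __post_init__(self):
        if not (0.0 <= self.identity_pct <= 100.0):
            raise ValueError(f"identity_pct out of range: {self.identity_pct}")
        if self.aln_len_aa < 1:
            raise ValueError(f"aln_len_aa must be >= 1, got {self.aln_len_aa}")


@dataclass
class HitTableReport:
    n_rows: int = 0
    bad_rows: int = 0


def read_hit_table(path: str | Path) -> tuple[list[HitRecord], HitTableReport]:
    """Read a 12-column tab-separated hit table.

    Columns 1-4 are query, subject, percent identity and alignment length as
    in the common tabular dialect; column 11 is interpreted as the frame
    when it is a small integer (our own files) and ignored otherwise
    (external files put the e-value there); column 12 is the score.
    Rows with a non-numeric identity are skipped and counted.
    """
    hits: list[HitRecord] = []
    report = HitTableReport()
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            report.n_rows += 1
            parts = line.rstrip("\n").split("\t")
            try:
                identity = float(parts[2])
                length = int(parts[3])
                frame = 0
                if len(parts) >= 11:
                    try:
                        f = int(parts[10])
                        if -3 <= f <= 3:
                            frame = f
                    except ValueError:
                        pass
                score = float(parts[11]) if len(parts) >= 12 else 0.0
                hits.append(HitRecord(parts[0], parts[1], identity, length,
                                      score=score, frame=frame))
            except (ValueError, IndexError):
                report.bad_rows += 1
    return hits, report


def write_hit_table(hits: list[HitRecord], path: str | Path) -> None:
    """Write hits in the 12-column dialect (identity/score to 4 decimals)."""
    with open(path, "w") as fh:
        for h in hits:
            fh.write("\t".join([
                h.read_id, h.ref_id, f"{h.identity_pct:.4f}", str(h.aln_len_aa),
                "0", "0", "0", "0", "0", "0", str(h.frame), f"{h.score:.4f}",
            ]) + "\n")
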