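"""Identification of glycan-related reads by translated protein alignment.

Each nucleotide read is translated in all six frames; fragments between
stop codons are aligned against the CAZyme catalogue by exact amino-acid
k-mer seeding (k=4) followed by an exact search for the maximal-scoring
ungapped segment on each seeded diagonal (BLOSUM62 scores).  A read is
considered glycan-related when its best alignment reaches at least 90%
amino-acid identity over at least 25 aligned residues — the acceptance rule
this whole pipeline hinges on — and it is then assigned the family, class,
enzyme functions and taxon of the best-matching reference entry.

Why ungapped: the acceptance rule is purely identity/length based and the
planted-read model contains substitutions only, so gapped refinements
cannot change a decision; ungapped segments also admit an exhaustive,
independently implemented oracle against which the seeded search is tested.

Seeding note: any ungapped alignment with identity >= 90% over >= 25 aa
contains a run of at least five consecutive identities, so a 4-mer seed
starting at an even query offset always exists; the seeder therefore steps
the query by 2 without losing any acceptable alignment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from ._encoding import (AA_DECODE_LUT, SCORE, STOP_CODE, encode_aa,
                        six_frame_code_arrays)
from .refdb import HitRecord, ReferenceCatalogue

MIN_FRAGMENT_AA = 8  # shorter fragments cannot seed two strides of k=4


@dataclass(frozen=True)
class Fragment:
    """A stop-free stretch of one reading frame.

    `frame` follows the usual +-1..3 convention; `start` is the 0-based
    aa offset of the fragment within its frame's translation.
    """
    frame: int
    start: int
    seq: str


def _code_fragments(nt_seq: str, min_len: int = MIN_FRAGMENT_AA,
                    ) -> list[tuple[int, int, np.ndarray]]:
    """Stop-free (frame, start, aa-code array) fragments of length >= min_len."""
    fragments = []
    for frame, aa in six_frame_code_arrays(nt_seq):
        stops = np.flatnonzero(aa == STOP_CODE)
        prev = 0
        for s in list(stops) + [len(aa)]:
            if s - prev >= min_len:
                fragments.append((frame, prev, aa[prev:s]))
            prev = int(s) + 1
    return fragments


def translate_six_frames(nt_seq: str) -> list[Fragment]:
    """All six reading frames, split at stop codons, short fragments
    (< 8 aa) discarded.  N bases translate to X."""
    return [Fragment(frame, start, AA_DECODE_LUT[codes].tobytes().decode("ascii"))
            for frame, start, codes in _code_fragments(nt_seq)]


@dataclass
class Alignment:
    """An ungapped local alignment of a translated fragment to a reference."""

    query_id: str
    ref_id: str
    frame: int
    q_start: int
    q_end: int
    r_start: int
    r_end: int
    matches: int
    aln_len_aa: int
    score: int

    @property
    def identity_pct(self) -> float:
        return 100.0 * self.matches / self.aln_len_aa

    def sort_key(self):
        """Higher score, then identity, then length; ties broken towards the
        lexicographically smallest ref_id.  Deterministic."""
        return (-self.score, -self.identity_pct, -self.aln_len_aa, self.ref_id)


def accept_hit(alignment: Alignment | HitRecord, min_identity: float = 90.0,
               min_len_aa: int = 25) -> bool:
    """The acceptance rule: identity >= 90% AND alignment length >= 25 aa
    (both bounds inclusive)."""
    return alignment.identity_pct >= min_identity and alignment.aln_len_aa >= min_len_aa


@dataclass
class ReadAssignment:
    """The single best accepted hit of a read, carrying its annotation."""

    read_id: str
    ref_id: str
    family: str
    cazy_class: str
    functions: list[tuple[str, float]]
    taxon: dict[str, str]
    identity_pct: float
    aln_len_aa: int
    score: int = 0
    frame: int = 0


@dataclass
class AlignParams:
    min_identity: float = 90.0
    min_len_aa: int = 25
    seed_k: int = 4
    seed_step: int = 2
    count_mode: str = "best"  # "best" (one assignment per read) or "all"


def min_acceptable_score(min_len_aa: int = 25) -> int:
    """A lower bound on the BLOSUM62 score of any acceptable segment.

    With identity >= 90% over length l >= min_len, at least 0.9*l columns
    score >= +4 (the smallest diagonal entry) and at most 0.1*l score
    >= -4, so score >= 3.2*l >= 3.2*min_len.  Segments below this bound can
    be discarded without changing any accept/reject decision.
    """
    return int(math.ceil(3.2 * min_len_aa))


def best_segment_on_diagonal(q_enc: np.ndarray, r_enc: np.ndarray, diag: int,
                             score_floor: int = 1):
    """Maximal-scoring ungapped segment where query position i pairs with
    reference position i + diag.

    Returns (score, matches, q_start, q_end_exclusive), or None when no
    segment reaches `score_floor` (callers pass the acceptance bound from
    :func:`min_acceptable_score` to skip hopeless diagonals early).  Among
    equal-score segments the one with the higher identity, then the longer,
    then the left-most is kept — the same convention the exhaustive oracle
    uses.
    """
    q0 = max(0, -diag)
    r0 = q0 + diag
    n = min(len(q_enc) - q0, len(r_enc) - r0)
    if n < 1:
        return None
    qs = q_enc[q0:q0 + n]
    rs = r_enc[r0:r0 + n]
    s = SCORE[qs, rs]

    prefix = np.empty(n + 1, dtype=np.int64)
    prefix[0] = 0
    np.cumsum(s, out=prefix[1:])
    runmin = np.minimum.accumulate(prefix[:-1])
    gains = prefix[1:] - runmin
    best = int(gains.max())
    if best <= 0 or best < score_floor:
        return None

    eq = qs == rs
    mpre = np.empty(n + 1, dtype=np.int64)
    mpre[0] = 0
    np.cumsum(eq, out=mpre[1:])

    chosen = None
    for end in np.flatnonzero(gains == best):
        for start in np.flatnonzero(prefix[:end + 1] == runmin[end]):
            length = int(end) + 1 - int(start)
            matches = int(mpre[end + 1] - mpre[start])
            key = (matches / length, length, -int(start))
            if chosen is None or key > chosen[0]:
                chosen = (key, int(start), int(end) + 1, matches)
    _key, start, stop, matches = chosen
    return best, matches, q0 + start, q0 + stop


class CatalogueAligner:
    """Seed-and-score translated search of reads against a catalogue."""

    def __init__(self, catalogue: ReferenceCatalogue, params: AlignParams | None = None):
        self.catalogue = catalogue
        self.params = params or AlignParams()
        self._ids = [e.ref_id for e in catalogue.entries]
        self._idx_of = {rid: i for i, rid in enumerate(self._ids)}
        self._enc = [encode_aa(e.aa_seq) for e in catalogue.entries]
        self._floor = min_acceptable_score(self.params.min_len_aa)
        k = self.params.seed_k
        index: dict[bytes, list[tuple[int, int]]] = {}
        for idx, enc in enumerate(self._enc):
            b = enc.tobytes()
            for i in range(len(b) - k + 1):
                index.setdefault(b[i:i + k], []).append((idx, i))
        self._index = index

    def _candidates(self, nt_seq: str, query_id: str) -> dict[int, Alignment]:
        """Best alignment per reference entry over all six-frame fragments.

        Fragments shorter than min_len_aa are skipped: no segment inside
        them can satisfy the length rule, so decisions are unaffected.
        """
        k = self.params.seed_k
        step = self.params.seed_step
        floor = self._floor
        best: dict[int, Alignment] = {}
        min_frag = max(MIN_FRAGMENT_AA, self.params.min_len_aa)
        for frame, start, fenc in _code_fragments(nt_seq, min_len=min_frag):
            fb = fenc.tobytes()
            seen: set[tuple[int, int]] = set()
            for i in range(0, len(fb) - k + 1, step):
                postings = self._index.get(fb[i:i + k])
                if not postings:
                    continue
                for eidx, off in postings:
                    key = (eidx, off - i)
                    if key in seen:
                        continue
                    seen.add(key)
                    seg = best_segment_on_diagonal(fenc, self._enc[eidx], off - i,
                                                   score_floor=floor)
                    if seg is None:
                        continue
                    score, matches, qs, qe = seg
                    diag = off - i
                    aln = Alignment(
                        query_id=query_id, ref_id=self._ids[eidx], frame=frame,
                        q_start=start + qs, q_end=start + qe,
                        r_start=qs + diag, r_end=qe + diag,
                        matches=matches, aln_len_aa=qe - qs, score=score,
                    )
                    cur = best.get(eidx)
                    if cur is None or aln.sort_key() < cur.sort_key():
                        best[eidx] = aln
        return best

    def align_fragment(self, fragment: Fragment, ref_id: str,
                       query_id: str = "q") -> Alignment | None:
        """Best alignment of one fragment against one entry (over all seeded
        diagonals); None when no seed matches."""
        eidx = self._idx_of[ref_id]
        best = None
        k, step = self.params.seed_k, self.params.seed_step
        fenc = encode_aa(fragment.seq)
        fb = fenc.tobytes()
        seen: set[int] = set()
        for i in range(0, len(fb) - k + 1, step):
            for idx, off in self._index.get(fb[i:i + k], ()):
                if idx != eidx or (off - i) in seen:
                    continue
                seen.add(off - i)
                seg = best_segment_on_diagonal(fenc, self._enc[eidx], off - i)
                if seg is None:
                    continue
                score, matches, qs, qe = seg
                aln = Alignment(query_id, ref_id, fragment.frame,
                                fragment.start + qs, fragment.start + qe,
                                qs + (off - i), qe + (off - i),
                                matches, qe - qs, score)
                if best is None or aln.sort_key() < best.sort_key():
                    best = aln
        return best

    def best_hits(self, read_id: str, nt_seq: str) -> list[Alignment]:
        """Per-entry best alignments for a read.  Only candidates reaching
        the acceptance score bound are computed (cheaper ones cannot change
        any accept/reject decision)."""
        return sorted(self._candidates(nt_seq, read_id).values(),
                      key=Alignment.sort_key)

    def assign_read(self, read_id: str, nt_seq: str) -> ReadAssignment | None:
        """The read's single best accepted hit, or None.

        Ordering among accepted hits: higher score, then higher identity,
        then longer alignment, then lexicographically smallest ref_id.
        """
        accepted = [a for a in self.best_hits(read_id, nt_seq)
                    if accept_hit(a, self.params.min_identity, self.params.min_len_aa)]
        if not accepted:
            return None
        return self._to_assignment(accepted[0])

    def _to_assignment(self, aln: Alignment) -> ReadAssignment:
        e = self.catalogue.lookup(aln.ref_id)
        return ReadAssignment(
            read_id=aln.query_id, ref_id=e.ref_id, family=e.family,
            cazy_class=e.cazy_class, functions=list(e.functions),
            taxon=dict(e.taxon), identity_pct=aln.identity_pct,
            aln_len_aa=aln.aln_len_aa, score=aln.score, frame=aln.frame,
        )


@dataclass
class AnnotationReport:
    n_reads: int = 0
    n_assigned: int = 0

    @property
    def glycan_fraction(self) -> float:
        return self.n_assigned / self.n_reads if self.n_reads else 0.0


def assignments_from_hits(hits: list[HitRecord], catalogue: ReferenceCatalogue,
                          params: AlignParams | None = None) -> list[ReadAssignment]:
    """Apply the acceptance rule and best-hit selection to an external hit
    table (e.g. from a translated-search tool), re-using its identity,
    length and score columns."""
    params = params or AlignParams()
    by_read: dict[str, HitRecord] = {}
    for h in hits:
        if h.ref_id not in catalogue.index:
            continue
        if not accept_hit(h, params.min_identity, params.min_len_aa):
            continue
        cur = by_read.get(h.read_id)
        key = (-h.score, -h.identity_pct, -h.aln_len_aa, h.ref_id)
        if cur is None or key < (-cur.score, -cur.identity_pct, -cur.aln_len_aa, cur.ref_id):
            by_read[h.read_id] = h
    out = []
    for rid in sorted(by_read):
        h = by_read[rid]
        e = catalogue.lookup(h.ref_id)
        out.append(ReadAssignment(
            read_id=rid, ref_id=e.ref_id, family=e.family, cazy_class=e.cazy_class,
            functions=list(e.functions), taxon=dict(e.taxon),
            identity_pct=h.identity_pct, aln_len_aa=h.aln_len_aa,
            score=int(h.score), frame=h.frame,
        ))
    return out


def annotate_sample(reads: list[tuple[str, str]], catalogue: ReferenceCatalogue,
                    params: AlignParams | None = None,
                    hits: list[HitRecord] | None = None,
                    ) -> tuple[list[ReadAssignment], AnnotationReport]:
    """Annotate one (host-filtered) sample.

    When `hits` is given, the internal aligner is bypassed and the
    acceptance + best-hit rules are applied to the external table instead;
    the read list then only sets the denominator of the glycan fraction.
    """
    params = params or AlignParams()
    report = AnnotationReport(n_reads=len(reads))
    if hits is not None:
        assignments = assignments_from_hits(hits, catalogue, params)
    else:
        aligner = CatalogueAligner(catalogue, params)
        assignments = []
        if params.count_mode == "best":
            for rid, seq in reads:
                a = aligner.assign_read(rid, seq)
                if a is not None:
                    assignments.append(a)
        else:  # "all": every accepted per-entry best hit
            for rid, seq in reads:
                for aln in aligner.best_hits(rid, seq):
                    if accept_hit(aln, params.min_identity, params.min_len_aa):
                        assignments.append(aligner._to_assignment(aln))
    assigned_reads = {a.read_id for a in assignments}
    report.n_assigned = len(assigned_reads)
    return assignments, report
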