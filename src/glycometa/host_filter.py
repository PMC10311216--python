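"""Host-read exclusion before annotation.

A desk-scale, dependency-free surrogate for mapping reads against a host
reference: exact canonical k-mer membership (k=31 by default).  A read is
removed when at least `min_host_kmer_frac` of its k-mers, on either strand,
occur in the host; verbatim host substrings of length >= k are therefore
always removed.  A pre-computed removal list (one read id per line) can be
applied instead to honour external mappers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

from ._encoding import revcomp


@dataclass
class FilterReport:
    n_input: int = 0
    n_removed_host: int = 0
    n_kept: int = 0
    n_too_short_to_test: int = 0


class HostIndex:
    """Strand-collapsed (canonical) k-mer set of the host sequence."""

    def __init__(self, host_seq: str, k: int = 31):
        if len(host_seq) < k:
            raise ValueError(f"host sequence shorter than k={k}")
        self.k = k
        host_seq = host_seq.upper()
        rc = revcomp(host_seq)
        n = len(host_seq)
        kmers = set()
        for i in range(n - k + 1):
            f = host_seq[i:i + k]
            r = rc[n - k - i:n - i]
            kmers.add(f if f <= r else r)
        self.kmers = frozenset(kmers)

    def __contains__(self, kmer: str) -> bool:
        rc = revcomp(kmer)
        return (kmer if kmer <= rc else rc) in self.kmers

    def __len__(self) -> int:
        return len(self.kmers)


def build_host_index(host_seq: str, k: int = 31) -> HostIndex:
    return HostIndex(host_seq, k=k)


def filter_host_reads(reads: list[tuple[str, str]], host_index: HostIndex,
                      min_host_kmer_frac: float = 0.5,
                      removal_list: set[str] | None = None,
                      ) -> tuple[list[tuple[str, str]], FilterReport]:
    """Split reads into kept vs host-derived.

    When `removal_list` is given, membership in it is the only criterion
    (external-mapper mode).  Otherwise a read is removed iff at least
    `min_host_kmer_frac` of its canonical k-mers are host-index members.
    Reads shorter than k cannot be tested and are kept (counted).
    """
    if not 0.0 < min_host_kmer_frac <= 1.0:
        raise ValueError("min_host_kmer_frac must be in (0, 1]")
    k = host_index.k
    kmers = host_index.kmers
    kept: list[tuple[str, str]] = []
    report = FilterReport(n_input=len(reads))

    for rid, seq in reads:
        if removal_list is not None:
            if rid in removal_list:
                report.n_removed_host += 1
            else:
                kept.append((rid, seq))
            continue
        n = len(seq)
        if n < k:
            report.n_too_short_to_test += 1
            kept.append((rid, seq))
            continue
        rc = revcomp(seq)
        total = n - k + 1
        # smallest hit count h with h/total >= min_host_kmer_frac
        need = max(1, math.ceil(min_host_kmer_frac * total - 1e-9))
        hits = 0
        removed = False
        for i in range(total):
            f = seq[i:i + k]
            r = rc[n - k - i:n - i]
            if (f if f <= r else r) in kmers:
                hits += 1
                if hits >= need:
                    removed = True
                    break
            elif hits + (total - 1 - i) < need:
                break
        if removed:
            report.n_removed_host += 1
        else:
            kept.append((rid, seq))

    report.n_kept = len(kept)
    return kept, report


def load_removal_list(path: str | Path) -> set[str]:
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip()}
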