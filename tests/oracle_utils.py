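"""Independent brute-force oracles used to validate the implementations.

Everything here is deliberately written against different primitives than
the package: translation goes through Bio.Seq, the exhaustive ungapped
aligner enumerates every (start, end) segment on every diagonal of every
fragment/reference pair, and the statistics are computed from first
principles (full enumeration for the rank-sum null, the literal step-up
formula for Benjamini-Hochberg).
"""

from itertools import combinations

import numpy as np
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

_B = substitution_matrices.load("BLOSUM62")
_CODE = {aa: i for i, aa in enumerate(_B.alphabet)}
_M = np.asarray(_B, dtype=np.int64)

_TRIU_CACHE: dict[int, tuple[np.ndarray, np.ndarray]] = {}


def _encode(seq):
    return np.array([_CODE.get(a, _CODE["X"]) for a in seq], dtype=np.int64)


def six_frame_fragments(nt, min_len=8):
    """Six-frame translation via Biopython, split at stops."""
    out = []
    s = Seq(nt)
    for strand in (s, s.reverse_complement()):
        for off in range(3):
            trimmed = strand[off: off + 3 * ((len(strand) - off) // 3)]
            for part in str(trimmed.translate()).split("*"):
                if len(part) >= min_len:
                    out.append(part)
    return out


def _triu(n):
    if n not in _TRIU_CACHE:
        _TRIU_CACHE[n] = np.triu_indices(n)
    return _TRIU_CACHE[n]


def best_ungapped_segment(frag, ref_aa):
    """Best ungapped local alignment of one aa fragment vs one reference by
    exhaustive enumeration of all segments on all diagonals.

    Selection: highest score, then identity, then length, then left-most
    start.  Returns (score, identity_fraction, length) or None.
    """
    q = _encode(frag)
    r = _encode(ref_aa)
    scores = _M[q[:, None], r[None, :]]
    eq = (q[:, None] == r[None, :]).astype(np.int64)
    best = None
    for d in range(-(len(q) - 1), len(r)):
        s = np.diagonal(scores, offset=d)
        e = np.diagonal(eq, offset=d)
        n = len(s)
        ps = np.concatenate([[0], np.cumsum(s)])
        pe = np.concatenate([[0], np.cumsum(e)])
        ii, jj = _triu(n)
        sc = ps[jj + 1] - ps[ii]
        smax = int(sc.max())
        if smax <= 0 or (best is not None and smax < best[0]):
            continue
        cand = None
        for t in np.flatnonzero(sc == smax):
            ln = int(jj[t]) + 1 - int(ii[t])
            ident = float(pe[jj[t] + 1] - pe[ii[t]]) / ln
            key = (smax, ident, ln)
            if cand is None or key > cand:
                cand = key
        if best is None or cand > best:
            best = cand
    return best


def oracle_decision(read_nt, ref_aa, min_identity=90.0, min_len_aa=25):
    """Accept/reject a (read, reference) pair: translate all frames,
    exhaustively find the best segment, apply the identity/length rule."""
    best = None
    for frag in six_frame_fragments(read_nt):
        cand = best_ungapped_segment(frag, ref_aa)
        if cand is not None and (best is None or cand > best):
            best = cand
    if best is None:
        return False
    _score, ident, length = best
    return 100.0 * ident >= min_identity and length >= min_len_aa


def bh_stepup(p_values):
    """Literal Benjamini-Hochberg step-up: q_(i) = min_{j>=i} m*p_(j)/j."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    q_sorted = np.empty(m)
    running = np.inf
    for rank in range(m, 0, -1):
        running = min(running, m * p[order[rank - 1]] / rank)
        q_sorted[rank - 1] = min(running, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def ranksum_exact_enumeration(a, b):
    """Two-sided exact rank-sum p-value by full enumeration of all
    C(n_a+n_b, n_a) group assignments of the pooled ranks (no ties)."""
    a = list(a)
    b = list(b)
    pooled = sorted(a + b)
    assert len(set(pooled)) == len(pooled), "exact enumeration requires no ties"
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    n_a, n_b = len(a), len(b)
    r_obs = sum(ranks[v] for v in a)
    u_obs = r_obs - n_a * (n_a + 1) / 2
    u_all = []
    for combo in combinations(range(1, n_a + n_b + 1), n_a):
        u_all.append(sum(combo) - n_a * (n_a + 1) / 2)
    u_all = np.asarray(u_all)
    lo = np.mean(u_all <= u_obs)
    hi = np.mean(u_all >= u_obs)
    return float(min(1.0, 2.0 * min(lo, hi)))


def shannon_direct(p):
    p = np.asarray(p, dtype=float)
    p = p[p > 0]
    p = p / p.sum()
    return float(-(p * np.log2(p)).sum())
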