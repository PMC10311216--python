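"""Shared sequence encodings: amino-acid integer codes, BLOSUM62 scores,
codon tables and nucleotide helpers used by the aligner and the simulator."""

from __future__ import annotations

import numpy as np
from Bio.Align import substitution_matrices
from Bio.Data import CodonTable

_BLOSUM = substitution_matrices.load("BLOSUM62")

#: Amino-acid alphabet in BLOSUM62 order ('ARNDCQEGHILKMFPSTWYVBZX*').
AA_ALPHABET: str = str(_BLOSUM.alphabet)
AA_INDEX = {aa: i for i, aa in enumerate(AA_ALPHABET)}
_X_CODE = AA_INDEX["X"]

#: 24x24 integer substitution-score matrix, indexed by the codes above.
SCORE = np.asarray(_BLOSUM, dtype=np.int32)

# Byte-value -> aa code lookup; unknown bytes map to X.
ENCODE_LUT = np.full(256, _X_CODE, dtype=np.uint8)
for _aa, _i in AA_INDEX.items():
    ENCODE_LUT[ord(_aa)] = _i
    ENCODE_LUT[ord(_aa.lower())] = _i


def encode_aa(seq: str) -> np.ndarray:
    """Encode a protein string as a uint8 array of BLOSUM62 row indices."""
    return ENCODE_LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


_STD_TABLE = CodonTable.unambiguous_dna_by_id[1]

#: codon -> single-letter aa; stop codons map to '*'. Codons containing
#: any base outside ACGT (e.g. N) are absent and translate to X.
CODON_TO_AA: dict[str, str] = dict(_STD_TABLE.forward_table)
for _stop in _STD_TABLE.stop_codons:
    CODON_TO_AA[_stop] = "*"

#: aa -> list of synonymous codons (stops excluded), for reverse translation.
AA_TO_CODONS: dict[str, list[str]] = {}
for _codon, _aa in sorted(_STD_TABLE.forward_table.items()):
    AA_TO_CODONS.setdefault(_aa, []).append(_codon)

_NT_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (N is self-complementary)."""
    return seq.translate(_NT_COMPLEMENT)[::-1]


def translate_frame(seq: str, offset: int) -> str:
    """Translate one forward frame of an ACGTN string; stops become '*',
    codons containing N become 'X'. Trailing partial codons are dropped."""
    n = (len(seq) - offset) // 3
    get = CODON_TO_AA.get
    return "".join([get(seq[offset + 3 * i:offset + 3 * i + 3], "X") for i in range(n)])


# -- vectorised translation used by the aligner's hot path -----------------

STOP_CODE = AA_INDEX["*"]
X_CODE = _X_CODE

# nucleotide byte -> 2-bit code; anything outside ACGT (e.g. N) -> 4
NT_CODE_LUT = np.full(256, 4, dtype=np.uint8)
for _i, _nt in enumerate("ACGT"):
    NT_CODE_LUT[ord(_nt)] = _i
    NT_CODE_LUT[ord(_nt.lower())] = _i

# codon index (a*16 + b*4 + c) -> aa code in BLOSUM62 order
CODON_AA_CODES = np.empty(64, dtype=np.uint8)
for _a, _na in enumerate("ACGT"):
    for _b, _nb in enumerate("ACGT"):
        for _c, _nc in enumerate("ACGT"):
            CODON_AA_CODES[_a * 16 + _b * 4 + _c] = AA_INDEX[CODON_TO_AA[_na + _nb + _nc]]

# aa code -> ASCII byte, for decoding code arrays back to strings
AA_DECODE_LUT = np.frombuffer(AA_ALPHABET.encode("ascii"), dtype=np.uint8)


def six_frame_code_arrays(nt_seq: str) -> list[tuple[int, np.ndarray]]:
    """Translate all six frames into aa-code arrays (stops included as
    STOP_CODE, N-containing codons as X_CODE).  Frames follow the +-1..3
    convention; empty frames are omitted."""
    raw = NT_CODE_LUT[np.frombuffer(nt_seq.encode("ascii"), dtype=np.uint8)]
    rc = np.where(raw < 4, 3 - raw, raw)[::-1]
    out: list[tuple[int, np.ndarray]] = []
    for strand, codes in ((1, raw), (-1, rc)):
        for off in range(3):
            m = (len(codes) - off) // 3
            if m < 1:
                continue
            c = codes[off:off + 3 * m].reshape(m, 3).astype(np.int16)
            valid = (c < 4).all(axis=1)
            idx = np.where(valid, c[:, 0] * 16 + c[:, 1] * 4 + c[:, 2], 0)
            aa = np.where(valid, CODON_AA_CODES[idx], X_CODE).astype(np.uint8)
            out.append((strand * (off + 1), aa))
    return out
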