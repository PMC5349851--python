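"""Integer encoding of DNA k-mers.

Every k-mer over the alphabet A<C<G<T is identified with its base-4 integer in
``[0, 4**k)``, most-significant digit first, so lexicographic order of k-mer
strings coincides with numeric order of indices.  All tables in the package
(counts, expected counts, enrichment, CSI intensity) are dense numpy vectors
indexed this way.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

BASES = "ACGT"
INVALID = np.uint8(255)

_CODE = np.full(256, INVALID, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i

_COMPLEMENT = str.maketrans("ACGTacgtnN", "TGCAtgcanN")


def encode(seq: str) -> np.ndarray:
    """Return uint8 codes (A=0, C=1, G=2, T=3; other letters -> INVALID)."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def encode_strict(seq: str) -> np.ndarray:
    codes = encode(seq)
    if codes.size == 0 or np.any(codes == INVALID):
        raise ValueError(f"sequence contains non-ACGT letters: {seq!r}")
    return codes


def decode(codes: np.ndarray) -> str:
    return "".join(BASES[c] for c in np.asarray(codes))


def is_dna(seq: str) -> bool:
    return len(seq) > 0 and not np.any(encode(seq) == INVALID)


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def kmer_to_index(kmer: str) -> int:
    codes = encode_strict(kmer)
    idx = 0
    for c in codes:
        idx = idx * 4 + int(c)
    return idx


def index_to_kmer(idx: int, k: int) -> str:
    out = []
    for shift in range(k - 1, -1, -1):
        out.append(BASES[(idx >> (2 * shift)) & 3])
    return "".join(out)


def base_at(idx: np.ndarray | int, pos: np.ndarray | int, k: int):
    """Base code at string position ``pos`` (0-based from the 5' end)."""
    return (np.asarray(idx, dtype=np.int64) >> (2 * (k - 1 - np.asarray(pos)))) & 3


@lru_cache(maxsize=8)
def revcomp_index_table(k: int) -> np.ndarray:
    """Permutation ``t`` with ``t[i]`` = index of the reverse complement."""
    idx = np.arange(4**k, dtype=np.int64)
    rc = np.zeros_like(idx)
    for pos in range(k):
        b = (idx >> (2 * (k - 1 - pos))) & 3
        rc |= (3 - b) << (2 * pos)
    rc.setflags(write=False)
    return rc


def window_indices(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """All length-k window indices of each row of a 2-D code matrix.

    Returns ``(idx, ok)`` of shape ``(n, L-k+1)``; ``ok`` is False for windows
    touching an invalid (non-ACGT) code, whose ``idx`` is meaningless.
    """
    codes = np.atleast_2d(codes)
    n, L = codes.shape
    if k > L:
        raise ValueError(f"k={k} exceeds sequence length {L}")
    nw = L - k + 1
    valid = codes != INVALID
    clean = np.where(valid, codes, 0).astype(np.int64)
    idx = np.zeros((n, nw), dtype=np.int64)
    ok = np.ones((n, nw), dtype=bool)
    for j in range(k):
        idx = idx * 4 + clean[:, j : j + nw]
        ok &= valid[:, j : j + nw]
    return idx, ok
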