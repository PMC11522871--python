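"""Canonical k-mers, 2-bit integer hashing, and minimizer selection.

A k-mer ``z = b_{k-1} ... b_1 b_0`` (first character most significant) is
hashed to the integer ``sum_i map(b_i) * 4**i`` with ``map`` sending
A,C,G,T to 0,1,2,3.  The hash is a bijection from ACGT k-mers onto
``[0, 4**k)`` and preserves lexicographic order, so "lexicographically
smallest k-mer in a window" and "numerically smallest hash in a window"
are the same thing; the array routines below exploit that.

Minimizers are selected from every window of k consecutive k-mer
positions (window span 2k-1 bases) and additionally from the k-1 shorter
windows anchored at each end of the sequence (1, 2, ..., k-1 consecutive
k-mers), so that every k-mer position is covered by at least one window.
The k-mer compared in each position is the canonical one: the
lexicographically smaller of the k-mer and its reverse complement.
K-mers containing a non-ACGT character are excluded from every window;
a window with no valid k-mer yields no minimizer.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .errors import AmbiguousBaseError

_BASES = "ACGT"
_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}

# byte value -> 2-bit code, -1 for anything that is not an unambiguous base
_LUT = np.full(256, -1, dtype=np.int8)
for _b, _c in zip("ACGTacgt", [0, 1, 2, 3, 0, 1, 2, 3]):
    _LUT[ord(_b)] = _c

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def encode_base(base: str) -> int:
    """Map a single nucleotide to its 2-bit code (A=0, C=1, G=2, T=3).

    Raises :class:`AmbiguousBaseError` for anything outside ACGT
    (case-insensitive); callers are expected to pre-filter ambiguity
    codes such as N.
    """
    code = _CODE.get(base.upper()) if len(base) == 1 else None
    if code is None:
        raise AmbiguousBaseError(f"ambiguous base {base!r}: expected one of A, C, G, T")
    return code


def hash_kmer(kmer: str) -> int:
    """Hash an ACGT k-mer to its integer in ``[0, 4**k)``.

    The first character carries weight ``4**(k-1)``, i.e. the hash is the
    k-mer read as a base-4 numeral, which makes hash order identical to
    lexicographic order under A<C<G<T.
    """
    h = 0
    for ch in kmer.upper():
        code = _CODE.get(ch)
        if code is None:
            raise AmbiguousBaseError(f"ambiguous base {ch!r} in k-mer {kmer!r}")
        h = (h << 2) | code
    return h


def unhash_kmer(h: int, k: int) -> str:
    """Invert :func:`hash_kmer`: recover the k-mer of a hash value."""
    if not 0 <= h < 4**k:
        raise ValueError(f"hash {h} out of range for k={k} (must be in [0, {4**k}))")
    out = []
    for _ in range(k):
        out.append(_BASES[h & 3])
        h >>= 2
    return "".join(reversed(out))


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement; non-ACGT characters pass through."""
    return seq.translate(_COMPLEMENT)[::-1]


def canonical_kmer(kmer: str) -> str:
    """The lexicographically smaller of a k-mer and its reverse complement."""
    kmer = kmer.upper()
    for ch in kmer:
        if ch not in _CODE:
            raise AmbiguousBaseError(f"ambiguous base {ch!r} in k-mer {kmer!r}")
    rc = reverse_complement(kmer)
    return kmer if kmer <= rc else rc


def _encode_sequence(seq: str) -> np.ndarray:
    """2-bit codes for a sequence; -1 marks ambiguous bases."""
    raw = np.frombuffer(seq.encode("latin-1"), dtype=np.uint8)
    return _LUT[raw]


def canonical_hash_array(seq: str, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-position canonical k-mer hashes for one sequence record.

    Returns ``(hashes, valid)`` of length ``len(seq) - k + 1`` where
    ``hashes[j]`` is the hash of the canonical k-mer starting at ``j``
    (meaningless where ``valid[j]`` is False, i.e. the k-mer contains an
    ambiguous base).
    """
    codes = _encode_sequence(seq)
    n_pos = codes.size - k + 1
    if n_pos <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
    valid_base = codes >= 0
    clean = np.where(valid_base, codes, 0).astype(np.int64)
    win = sliding_window_view(clean, k)
    pow_desc = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    fwd = win @ pow_desc
    # reverse complement of window [j, j+k): hash weight of position j+s is 4**s
    rev = (3 - win) @ pow_desc[::-1]
    hashes = np.minimum(fwd, rev)
    valid = sliding_window_view(valid_base, k).all(axis=1)
    return hashes, valid


def count_valid_kmers(seq: str, k: int) -> int:
    """Number of all-ACGT k-mer positions in one sequence (one strand)."""
    _, valid = canonical_hash_array(seq, k)
    return int(valid.sum())


def minimizer_array(seq: str, k: int) -> np.ndarray:
    """Sorted, deduplicated minimizer hashes of one sequence record.

    Covers every interior window of k consecutive k-mers and the 1..k-1
    anchored end windows at both ends.  Windows with no valid k-mer
    contribute nothing; a sequence shorter than k yields an empty array.
    """
    hashes, valid = canonical_hash_array(seq, k)
    n_pos = hashes.size
    if n_pos == 0:
        return np.empty(0, dtype=np.int64)
    sentinel = np.int64(4) ** k
    canon = np.where(valid, hashes, sentinel)
    parts = []
    if n_pos >= k:
        parts.append(sliding_window_view(canon, k).min(axis=1))
    n_end = min(k - 1, n_pos)
    if n_end:
        parts.append(np.minimum.accumulate(canon[:n_end]))
        parts.append(np.minimum.accumulate(canon[::-1][:n_end]))
    mins = np.unique(np.concatenate(parts))
    return mins[mins < sentinel]


def extract_minimizers(seq: str, k: int) -> set[int]:
    """Minimizer hash set of one sequence record (see :func:`minimizer_array`)."""
    return set(int(h) for h in minimizer_array(seq, k))
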