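"""Vectorized canonical k-mer extraction and seeded 64-bit hashing.

K-mers are 2-bit packed into uint64 (k <= 31); the canonical form of a k-mer
is the numerically smaller of the packed k-mer and its reverse complement,
which coincides with taking the lexicographically smaller string under the
A<C<G<T encoding.  Windows containing N are dropped.  Hashing uses the
splitmix64 finalizer, seeded, so sketches are reproducible across runs and
platforms.
"""

from __future__ import annotations

import numpy as np

__all__ = ["canonical_kmers", "hash_kmers", "canonical_kmer_set", "decode_kmer"]

_CODE = np.full(256, 4, dtype=np.uint8)
for i, base in enumerate(b"ACGT"):
    _CODE[base] = i
_BASES = "ACGT"

_MASK64 = np.uint64(0xFFFFFFFFFFFFFFFF)


def _encode(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def canonical_kmers(seq: str, k: int) -> np.ndarray:
    """All canonical k-mers of ``seq`` as packed uint64, in sequence order.

    Windows overlapping an N (or any non-ACGT character) are excluded.
    Returns an empty array when ``len(seq) < k``.  Requires ``1 <= k <= 31``.
    """
    if not 1 <= k <= 31:
        raise ValueError(f"k must be in [1, 31], got {k}")
    n = len(seq)
    if n < k:
        return np.empty(0, dtype=np.uint64)
    codes = _encode(seq)
    valid_base = codes < 4
    codes = np.where(valid_base, codes, 0).astype(np.uint64)
    m = n - k + 1
    fwd = np.zeros(m, dtype=np.uint64)
    rev = np.zeros(m, dtype=np.uint64)
    comp = np.uint64(3) - codes
    for i in range(k):
        fwd = (fwd << np.uint64(2)) | codes[i : i + m]
        # reverse complement read right-to-left: base at offset k-1-i
        rev = (rev << np.uint64(2)) | comp[k - 1 - i : k - 1 - i + m]
    canon = np.minimum(fwd, rev)
    # window valid iff all k bases valid
    ok = np.ones(m, dtype=bool)
    for i in range(k):
        ok &= valid_base[i : i + m]
    return canon[ok]


def decode_kmer(code: int, k: int) -> str:
    """Unpack a 2-bit encoded k-mer back to its string form."""
    chars = []
    for _ in range(k):
        chars.append(_BASES[code & 3])
        code >>= 2
    return "".join(reversed(chars))


def hash_kmers(kmers: np.ndarray, seed: int = 0) -> np.ndarray:
    """Seeded splitmix64 finalizer applied elementwise to packed k-mers."""
    x = kmers.astype(np.uint64) + np.uint64(seed * 0x9E3779B97F4A7C15 & 0xFFFFFFFFFFFFFFFF)
    with np.errstate(over="ignore"):
        x = (x ^ (x >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9) & _MASK64
        x = (x ^ (x >> np.uint64(27))) * np.uint64(0x94D049BB133111EB) & _MASK64
        x = x ^ (x >> np.uint64(31))
    return x


def canonical_kmer_set(seq: str, k: int) -> set[int]:
    """Distinct canonical k-mers of a sequence, as Python ints."""
    return set(map(int, canonical_kmers(seq, k)))
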