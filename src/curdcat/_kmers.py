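"""Vectorised canonical k-mer encoding and hashing.

Sequences are 2-bit encoded; each window of k bases becomes a uint64 code,
canonicalised against its reverse complement (strand independence), and
mixed through splitmix64 so bottom-sketch MinHash sampling is uniform.
Windows containing N are dropped.
"""

from __future__ import annotations

import numpy as np

_CODE = np.full(256, 255, dtype=np.uint8)
for i, b in enumerate(b"ACGT"):
    _CODE[b] = i


def encode(sequence: str) -> np.ndarray:
    """2-bit codes per base; 255 marks N/invalid."""
    raw = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    return _CODE[raw]


def canonical_kmers(sequence: str, k: int) -> np.ndarray:
    """Canonical (strand-min) k-mer codes of one sequence, order preserved."""
    codes = encode(sequence)
    n = codes.size
    if n < k:
        return np.empty(0, dtype=np.uint64)
    valid = codes != 255
    # window is usable iff all k bases are valid
    ok = np.ones(n - k + 1, dtype=bool)
    if not valid.all():
        cs = np.concatenate(([0], np.cumsum(valid)))
        ok = (cs[k:] - cs[:-k]) == k
    x = codes.astype(np.uint64)
    fwd = np.zeros(n - k + 1, dtype=np.uint64)
    for i in range(k):
        fwd = (fwd << np.uint64(2)) | x[i : i + n - k + 1]
    # reverse complement read in the same left-to-right frame
    xr = (np.uint64(3) - x[::-1]) & np.uint64(3)
    rev = np.zeros(n - k + 1, dtype=np.uint64)
    for i in range(k):
        rev = (rev << np.uint64(2)) | xr[i : i + n - k + 1]
    rev = rev[::-1]
    return np.minimum(fwd, rev)[ok]


def splitmix64(x: np.ndarray) -> np.ndarray:
    """Stateless 64-bit mixer; vectorised, wraps modulo 2^64."""
    z = x + np.uint64(0x9E3779B97F4A7C15)
    z = (z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
    z = (z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
    return z ^ (z >> np.uint64(31))


def hashed_kmer_set(sequences, k: int) -> np.ndarray:
    """Sorted unique hashed canonical k-mers over a list of sequences.

    k-mers do not span contig boundaries (as in sketch-based ANI tools).
    """
    parts = [canonical_kmers(s, k) for s in sequences]
    if not parts:
        return np.empty(0, dtype=np.uint64)
    allk = np.unique(np.concatenate(parts))
    return np.sort(splitmix64(allk))


def forward_kmers(sequence: str, k: int) -> np.ndarray:
    """Non-canonical forward k-mer codes (for seed matching), with N windows
    marked by code 2^64-1 (never a valid code is excluded; callers mask)."""
    codes = encode(sequence)
    n = codes.size
    if n < k:
        return np.empty(0, dtype=np.uint64)
    x = np.where(codes == 255, 0, codes).astype(np.uint64)
    out = np.zeros(n - k + 1, dtype=np.uint64)
    for i in range(k):
        out = (out << np.uint64(2)) | x[i : i + n - k + 1]
    valid = codes != 255
    if not valid.all():
        cs = np.concatenate(([0], np.cumsum(valid)))
        bad = (cs[k:] - cs[:-k]) != k
        out[bad] = np.uint64(0xFFFFFFFFFFFFFFFF)
    return out
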