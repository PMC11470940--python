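"""Shared low-level helpers: DNA arrays, k-mer encoding, intervals."""

from __future__ import annotations

import numpy as np

_ALPHABET = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
    _CODE[_b + 32] = _i  # lowercase

_RC_TABLE = bytes.maketrans(b"ACGTacgt", b"TGCAtgca")


def random_dna(rng: np.random.Generator, n: int) -> str:
    return _ALPHABET[rng.integers(0, 4, n)].tobytes().decode("ascii")


def encode_dna(seq: str) -> np.ndarray:
    """Map ACGT (case-insensitive) to uint8 codes 0..3; other bases -> 255."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode_dna(codes: np.ndarray) -> str:
    return _ALPHABET[codes].tobytes().decode("ascii")


def revcomp(seq: str) -> str:
    return seq.translate(_RC_TABLE)[::-1]


def mutate_dna(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Substitute each base independently with probability `rate`.

    Substitutions are uniform over the three alternative bases; no indels.
    """
    if rate <= 0:
        return seq
    codes = encode_dna(seq).copy()
    hit = rng.random(codes.size) < rate
    n_hit = int(hit.sum())
    if n_hit:
        codes[hit] = (codes[hit] + rng.integers(1, 4, n_hit)) % 4
    return decode_dna(codes)


def kmer_codes(seq: str, k: int) -> np.ndarray:
    """Canonical k-mer integer codes (base-4, min of strand and revcomp).

    Windows containing non-ACGT characters are dropped.
    """
    codes = encode_dna(seq).astype(np.int64)
    n = codes.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    valid_base = codes < 4
    fwd = np.zeros(n, dtype=np.int64)
    rev = np.zeros(n, dtype=np.int64)
    safe = np.where(valid_base, codes, 0)
    for j in range(k):
        fwd += safe[j : j + n] << (2 * (k - 1 - j))
        rev += (3 - safe[j : j + n]) << (2 * j)
    ok = np.ones(n, dtype=bool)
    bad = np.flatnonzero(~valid_base)
    for b in bad:
        lo = max(0, b - k + 1)
        ok[lo : min(n, b + 1)] = False
    canon = np.minimum(fwd, rev)
    return canon[ok]


def count_canonical_kmers(seqs, k: int):
    """Exact canonical k-mer counting across sequences.

    Returns (codes, counts) for distinct canonical k-mers.
    """
    parts = [kmer_codes(s, k) for s in seqs]
    allk = np.concatenate(parts) if parts else np.empty(0, dtype=np.int64)
    if allk.size == 0:
        return allk, allk
    return np.unique(allk, return_counts=True)


def interval_union_length(starts: np.ndarray, ends: np.ndarray) -> int:
    """Total length covered by 1-based inclusive intervals, overlaps merged."""
    if len(starts) == 0:
        return 0
    order = np.argsort(starts, kind="stable")
    s = np.asarray(starts)[order]
    e = np.asarray(ends)[order]
    total = 0
    cur_s, cur_e = int(s[0]), int(e[0])
    for i in range(1, len(s)):
        si, ei = int(s[i]), int(e[i])
        if si <= cur_e:
            cur_e = max(cur_e, ei)
        else:
            total += cur_e - cur_s + 1
            cur_s, cur_e = si, ei
    total += cur_e - cur_s + 1
    return total


def moving_average3(x: np.ndarray) -> np.ndarray:
    """3-bin moving average with edge bins averaged over the available window."""
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        return x.copy()
    out = np.empty_like(x)
    out[1:-1] = (x[:-2] + x[1:-1] + x[2:]) / 3.0
    out[0] = (x[0] + x[1]) / 2.0
    out[-1] = (x[-2] + x[-1]) / 2.0
    return out
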