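"""Nucleotide encoding helpers.

Sequences are held as ``uint8`` arrays with A=0, C=1, G=2, T=3 and N=4.
The 2-bit codes are what the k-mer machinery packs into ``uint64`` words,
so everything downstream of the simulator stays in integer space.
"""

from __future__ import annotations

import numpy as np

A, C, G, T, N = 0, 1, 2, 3, 4
_BASES = np.frombuffer(b"ACGTN", dtype=np.uint8)

# byte -> code lookup, everything unknown maps to N
_LUT = np.full(256, N, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _LUT[_b] = _i
    _LUT[_b + 32] = _i  # lower case


def encode(seq: str | bytes) -> np.ndarray:
    """String -> uint8 code array."""
    if isinstance(seq, str):
        seq = seq.encode("ascii")
    return _LUT[np.frombuffer(seq, dtype=np.uint8)].copy()


def decode(codes: np.ndarray) -> str:
    """uint8 code array -> string."""
    return _BASES[np.asarray(codes, dtype=np.uint8)].tobytes().decode("ascii")


def revcomp(codes: np.ndarray) -> np.ndarray:
    """Reverse complement of a code array (N stays N)."""
    codes = np.asarray(codes, dtype=np.uint8)
    out = np.where(codes < 4, 3 - codes, codes).astype(np.uint8)
    return out[::-1]


def revcomp_str(seq: str) -> str:
    return decode(revcomp(encode(seq)))


def random_seq(rng: np.random.Generator, n: int) -> np.ndarray:
    """IID uniform ACGT sequence of length n."""
    return rng.integers(0, 4, size=n, dtype=np.uint8)
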