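"""Low-level DNA sequence helpers shared across the package.

Sequences are strings over {A,C,G,T} at every public interface; internally
they are numpy ``uint8`` code arrays with A=0, C=1, G=2, T=3 so that the
complement is ``3 - code`` and k-mers pack exactly into ``uint64``.
"""

from __future__ import annotations

import numpy as np

_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: sentinel code used for padding; never equal to a real base code
SENTINEL = np.uint8(255)


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string into a uint8 code array (A=0 C=1 G=2 T=3).

    Raises ``ValueError`` on any character outside the 4-letter uppercase
    alphabet, including ambiguity codes such as N.
    """
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    codes = _CODE[raw]
    if codes.size and codes.max() == 255:
        bad = chr(raw[int(np.argmax(codes == 255))])
        raise ValueError(
            f"illegal character {bad!r} in sequence: only uppercase A/C/G/T are "
            "accepted (mask or remove ambiguity codes such as N before ingest)"
        )
    return codes


def decode(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode("ascii")


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    return (3 - codes)[::-1]


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return decode(revcomp_codes(encode(seq)))


def kmer_values(codes: np.ndarray, k: int) -> np.ndarray:
    """Pack every k-mer of ``codes`` into a uint64 (2 bits per base).

    Requires k <= 31 so values fit without overflow.
    """
    if k > 31:
        raise ValueError("k must be <= 31 for exact uint64 packing")
    m = len(codes) - k + 1
    if m <= 0:
        return np.empty(0, dtype=np.uint64)
    v = np.zeros(m, dtype=np.uint64)
    for j in range(k):
        v = v * np.uint64(4) + codes[j : j + m].astype(np.uint64)
    return v
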