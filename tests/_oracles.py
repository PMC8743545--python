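"""Independent brute-force oracles used to cross-check the implementation.

These deliberately use naive enumeration (string scans, per-diagonal
Kadane in pure Python) so they share no code path with the package.
"""

from __future__ import annotations

COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def revcomp(seq: str) -> str:
    return "".join(COMP[b] for b in reversed(seq))


def best_ungapped_block(p: str, q: str, match: int = 1, mismatch: int = -2):
    """Best-scoring ungapped local block between two strings, enumerating
    every diagonal with a scalar Kadane scan.

    Returns (score, p_start, p_end, q_start, q_end, mismatches), all
    0-based inclusive, or None if no positive-scoring block exists.
    Ties resolve to the lowest diagonal (q_start - p_start), then the
    earliest block on it.
    """
    best = None
    for d in range(-(len(p) - 1), len(q)):
        i0 = max(0, -d)
        j0 = i0 + d
        run = min(len(p) - i0, len(q) - j0)
        cur = 0
        cur_start = 0
        cur_mism = 0
        for t in range(run):
            hit = p[i0 + t] == q[j0 + t]
            cur += match if hit else mismatch
            cur_mism += 0 if hit else 1
            if cur < 0:
                cur, cur_start, cur_mism = 0, t + 1, 0
            elif best is None or cur > best[0]:
                best = (cur, i0 + cur_start, i0 + t, j0 + cur_start, j0 + t, cur_mism)
    return best


def hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def off_target_sites(spacer: str, sequences: dict[str, str], max_mismatches: int):
    """All (replicon, strand, protospacer_start) sites within Hamming
    distance of the spacer that carry an NGG PAM. 1-based strand-oriented
    start coordinates matching the package convention."""
    sites = []
    rc = revcomp(spacer)
    for name, seq in sequences.items():
        n = len(seq)
        for p in range(n - 22):
            if seq[p + 21 : p + 23] == "GG" and hamming(seq[p : p + 20], spacer) <= max_mismatches:
                sites.append((name, "+", p + 1))
            if seq[p : p + 2] == "CC" and hamming(seq[p + 3 : p + 23], rc) <= max_mismatches:
                sites.append((name, "-", p + 23))
    return sites


def pam_site_count(sequences: dict[str, str], start: int | None = None, end: int | None = None):
    """Number of NGG-adjacent 20-mers (both strands) per replicon, with the
    whole protospacer+PAM inside [start, end] when given (1-based)."""
    counts = {}
    for name, seq in sequences.items():
        lo = 0 if start is None else start - 1
        hi = len(seq) - 23 if end is None else end - 23
        c = 0
        for p in range(lo, hi + 1):
            if seq[p + 21 : p + 23] == "GG":
                c += 1
            if seq[p : p + 2] == "CC":
                c += 1
        counts[name] = c
    return counts
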