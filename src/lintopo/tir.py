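"""Terminal inverted repeat (TIR) detection for linear replicons.

Linear actinomycete replicons end in inverted repeats: the sequence at the
left terminus recurs, reverse-complemented, at the right terminus. The
finder aligns the 5' terminal window against the reverse complement of the
3' terminal window and reports the best-scoring ungapped block (match +1,
mismatch -2). Ungapped scoring keeps "differences" a well-defined mismatch
count; a gapped mode is deliberately not offered.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from ._seq import encode, revcomp, revcomp_codes
from .model import Replicon, TIRReport

DEFAULT_WINDOW = 2000
DEFAULT_MIN_LEN = 30
DEFAULT_MIN_IDENTITY = 90.0

_MATCH = 1
_MISMATCH = -2
_PAD = -10_000  # diagonal padding: never bridged by the block search


def terminal_motif(replicon: Replicon, k: int) -> tuple[str, str]:
    """The first k bases and the reverse complement of the last k bases.

    Equality of the pair indicates a perfect terminal repeat of length >= k.
    """
    if k < 1 or k > replicon.length:
        raise ValueError(f"k must be in [1, {replicon.length}]")
    return replicon.sequence[:k], revcomp(replicon.sequence[-k:])


def find_tir(
    replicon: Replicon,
    window: int = DEFAULT_WINDOW,
    min_len: int = DEFAULT_MIN_LEN,
    min_identity: float = DEFAULT_MIN_IDENTITY,
) -> Optional[TIRReport]:
    """Best ungapped local alignment between the two terminal windows.

    Returns ``None`` when the best block is shorter than ``min_len`` or
    below ``min_identity`` percent. Intervals are reported in forward
    coordinates of both ends; ``left_offset`` counts unmatched bases of the
    left window before the repeat, ``right_truncation`` counts bases of the
    idealised repeat missing at the right end (right copy stopping short of
    the terminus).
    """
    n = replicon.length
    if not replicon.is_linear:
        raise ValueError(f"{replicon.name}: TIR search requires a linear replicon")
    if 2 * window > n:
        raise ValueError(f"window {window} too large: 2*window must not exceed length {n}")

    codes = encode(replicon.sequence)
    P = codes[:window]  # left terminal window, 5'->3'
    Q = revcomp_codes(codes[n - window :])  # right window read inward from the terminus
    w = window

    # score matrix over all (i, j) pairs, sheared so each row of C is one
    # diagonal (j - i constant) traversed in increasing i
    eq = P[:, None] == Q[None, :]
    score = np.where(eq, _MATCH, _MISMATCH).astype(np.int32)
    ndiag = 2 * w - 1
    C = np.full((ndiag, w), _PAD, dtype=np.int32)
    E = np.zeros((ndiag, w), dtype=bool)
    ii = np.repeat(np.arange(w), w)
    jj = np.tile(np.arange(w), w)
    C[jj - ii + (w - 1), ii] = score.ravel()
    E[jj - ii + (w - 1), ii] = eq.ravel()

    # best block per diagonal via running-minimum prefix sums
    # (int32 is safe: |sum| <= window * |_PAD| < 2^31 for window <= 2 kb scale)
    cums = np.cumsum(C, axis=1, dtype=np.int32)
    pre = np.concatenate([np.zeros((ndiag, 1), dtype=np.int32), cums[:, :-1]], axis=1)
    runmin = np.minimum.accumulate(pre, axis=1)
    gain = cums - runmin
    end_i = np.argmax(gain, axis=1)
    rows = np.arange(ndiag)
    best = gain[rows, end_i]
    d = int(np.argmax(best))
    if best[d] <= 0:
        return None
    e = int(end_i[d])
    target = runmin[d, e]
    s = int(np.argmax((pre[d] == target) & (np.arange(w) <= e)))

    length = e - s + 1
    mism = int(np.sum(~E[d, s : e + 1]))
    identity_frac = 100.0 * (1.0 - mism / length)
    if length < min_len or identity_frac < min_identity:
        return None

    # map back: block pairs P[i] with Q[i + d'] where d' = d - (w - 1)
    dprime = d - (w - 1)
    js, je = s + dprime, e + dprime
    left_interval = (s + 1, e + 1)
    # Q index j corresponds to forward position n - j (1-based)
    right_interval = (n - je, n - js)
    # idealised-repeat bookkeeping: extending the block back along its
    # diagonal, the side whose terminus is reached first fixes where the
    # repeat conceptually starts. If the right copy abuts its terminus
    # (js < s), the unaligned left-window bases correspond to repeat bases
    # truncated away at the right end; any back-extension possible on both
    # sides is an offset of the repeat from the left terminus.
    left_offset = min(s, js)
    right_truncation = max(0, s - js)
    return TIRReport(
        replicon=replicon.name,
        left_interval=left_interval,
        right_interval=right_interval,
        repeat_length=length,
        identity=int(round(identity_frac)),
        differences=mism,
        left_offset=left_offset,
        right_truncation=right_truncation,
    )
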