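"""Exact-k-mer seed-and-extend read/contig mapping and coverage profiles.

The built-in mapper keeps the pipeline self-contained: it indexes the
reference with exact k-mers (packed 2-bit, k <= 31), anchors queries at a
few seed offsets, and extends candidates ungapped. A query whose prefix and
suffix anchor to different loci — a read or contig spanning a
circularization junction — yields two segments (the best one primary, the
other supplementary), which is what the junction caller consumes. Real
indel-rich data should instead be imported as SAM from a production mapper;
the two routes are interchangeable downstream.

Multi-mapping queries (e.g. reads wholly inside a terminal inverted repeat,
which match both ends of the molecule exactly) are assigned one placement
chosen deterministically by a hash of the query id, flagged ``ambiguous``
and excluded from junction evidence.
"""

from __future__ import annotations

import zlib
from typing import Iterable, Optional, Sequence

import numpy as np

from ._seq import SENTINEL, encode, kmer_values
from .model import AlignmentSegment, CoverageProfile, Genome, Read, Replicon

DEFAULT_K = 31
DEFAULT_MIN_ANCHOR = 50
DEFAULT_MAX_MISMATCH_RATE = 0.05

_MATCH = 1
_MISMATCH = -3  # extension tolerates <25% local mismatch density
_MAX_SEED_HITS = 16  # seeds hitting more loci than this are skipped
_SUPPL_MAX_OVERLAP = 10  # bp of query overlap tolerated between segments
_MAX_SUPPLEMENTARY = 3


class KmerIndex:
    """2-bit packed k-mer index over all replicons of a genome.

    Circular replicons are indexed on a doubled sequence so seeds cross the
    origin; their positions are reported modulo n.
    """

    def __init__(self, genome: Genome, k: int = DEFAULT_K, pad: int = 2048):
        if not 1 <= k <= 31:
            raise ValueError("k must be in [1, 31]")
        self.genome = genome
        self.k = k
        self.pad = pad
        self.names: list[str] = []
        self.lengths: list[int] = []
        self.circular: list[bool] = []
        ext_codes: list[np.ndarray] = []
        for rep in genome:
            codes = encode(rep.sequence)
            self.names.append(rep.name)
            self.lengths.append(rep.length)
            self.circular.append(not rep.is_linear)
            ext_codes.append(np.concatenate([codes, codes]) if not rep.is_linear else codes)

        # global coordinate space: replicon r occupies [gstart[r], gstart[r]+ext_len)
        self.ext_lens = np.array([len(c) for c in ext_codes], dtype=np.int64)
        self.gstart = np.concatenate([[0], np.cumsum(self.ext_lens)])[:-1]

        # verification buffer with sentinel padding around each replicon so
        # overhanging windows compare as mismatches instead of going OOB
        self.vstart = np.empty(len(ext_codes), dtype=np.int64)
        total = pad + int(sum(self.ext_lens + pad))
        vbuf = np.full(total, SENTINEL, dtype=np.uint8)
        pos = pad
        for i, codes in enumerate(ext_codes):
            self.vstart[i] = pos
            vbuf[pos : pos + len(codes)] = codes
            pos += len(codes) + pad
        self.vbuf = vbuf

        # k-mer table: sorted values with their global positions
        vals_parts, gpos_parts = [], []
        for i, codes in enumerate(ext_codes):
            n = self.lengths[i]
            vals = kmer_values(codes, k)
            if self.circular[i]:
                vals = vals[:n]  # one entry per origin-crossing start
            if vals.size:
                vals_parts.append(vals)
                gpos_parts.append(self.gstart[i] + np.arange(len(vals), dtype=np.int64))
        if vals_parts:
            vals = np.concatenate(vals_parts)
            gpos = np.concatenate(gpos_parts)
            order = np.argsort(vals, kind="stable")
            self._vals = vals[order]
            self._gpos = gpos[order]
        else:
            self._vals = np.empty(0, dtype=np.uint64)
            self._gpos = np.empty(0, dtype=np.int64)

    def lookup(self, kmers: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        lo = np.searchsorted(self._vals, kmers, side="left")
        hi = np.searchsorted(self._vals, kmers, side="right")
        return lo, hi

    def replicon_of(self, gpos: np.ndarray) -> np.ndarray:
        """Replicon indices for *hit* global positions (always in range)."""
        return np.searchsorted(self.gstart, gpos, side="right") - 1


# ---------------------------------------------------------------------------
# best ungapped block (vectorised Kadane via running-minimum prefix sums)
# ---------------------------------------------------------------------------


def _best_blocks(eq: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Best-scoring ungapped block per row of a boolean equality matrix.

    Returns (start, end, mismatches, score) with 0-based inclusive ends.
    Scoring is +1 per match, -3 per mismatch; ties resolve to the earliest
    block deterministically.
    """
    if eq.ndim == 1:
        eq = eq[None, :]
    nrow, L = eq.shape
    score = np.where(eq, _MATCH, _MISMATCH).astype(np.int64)
    cums = np.cumsum(score, axis=1)
    pre = np.concatenate([np.zeros((nrow, 1), dtype=np.int64), cums[:, :-1]], axis=1)
    runmin = np.minimum.accumulate(pre, axis=1)
    gain = cums - runmin
    end = np.argmax(gain, axis=1)
    rows = np.arange(nrow)
    best = gain[rows, end]
    # block start: first prefix index achieving the running minimum at `end`
    target = runmin[rows, end][:, None]
    candidates = (pre == target) & (np.arange(L)[None, :] <= end[:, None])
    start = np.argmax(candidates, axis=1)
    mis_cum = np.cumsum(~eq, axis=1)
    mis_pre = np.concatenate([np.zeros((nrow, 1), dtype=np.int64), mis_cum[:, :-1]], axis=1)
    mism = mis_cum[rows, end] - mis_pre[rows, start]
    return start, end, mism, best


# ---------------------------------------------------------------------------
# candidate placements
# ---------------------------------------------------------------------------


def _hash_pick(query_id: str, n: int) -> int:
    return zlib.crc32(query_id.encode()) % n


class _Block:
    __slots__ = ("orient", "rep", "qs", "qe", "rstart0", "mism", "score")

    def __init__(self, orient, rep, qs, qe, rstart0, mism, score):
        self.orient = orient  # 0 forward, 1 reverse-complement frame
        self.rep = rep
        self.qs = qs  # 0-based on the oriented query
        self.qe = qe
        self.rstart0 = rstart0  # 0-based on the (extended) replicon
        self.mism = mism
        self.score = score


def _blocks_to_segments(
    query_id: str,
    qlen: int,
    blocks: list[_Block],
    index: KmerIndex,
    min_anchor: int,
    max_mismatch_rate: float,
) -> list[AlignmentSegment]:
    """Select primary + supplementary segments among candidate blocks."""
    good = [
        b
        for b in blocks
        if b.qe - b.qs + 1 >= min_anchor
        and b.mism <= max_mismatch_rate * (b.qe - b.qs + 1)
        and b.score > 0
    ]
    if not good:
        return []
    good.sort(key=lambda b: (-b.score, b.rep, b.rstart0, b.orient))
    top_score = good[0].score
    tied = [b for b in good if b.score == top_score]
    ambiguous = len(tied) > 1
    primary = tied[_hash_pick(query_id, len(tied))] if ambiguous else tied[0]

    chosen: list[tuple[_Block, str]] = [(primary, "primary")]
    for b in good:
        if b is primary or len(chosen) > _MAX_SUPPLEMENTARY:
            continue
        ok = True
        for c, _ in chosen:
            lo = max(b.qs, c.qs)
            hi = min(b.qe, c.qe)
            if hi - lo + 1 > _SUPPL_MAX_OVERLAP:
                ok = False
                break
        if ok:
            chosen.append((b, "supplementary"))

    segments = []
    for b, role in chosen:
        segments.extend(
            _emit_segment(query_id, qlen, b, role, ambiguous and role == "primary", index)
        )
    return segments


def _oriented_to_given(qlen: int, orient: int, s0: int, e0: int) -> tuple[int, int]:
    """Convert a 0-based oriented query interval to 1-based as-given coords."""
    if orient == 0:
        return s0 + 1, e0 + 1
    return qlen - e0, qlen - s0


def _emit_segment(query_id, qlen, b: _Block, role, ambiguous, index) -> list[AlignmentSegment]:
    n = index.lengths[b.rep]
    rstart0 = b.rstart0 + b.qs
    rend0 = b.rstart0 + b.qe
    strand = "+" if b.orient == 0 else "-"
    name = index.names[b.rep]
    if index.circular[b.rep] and rend0 >= n:
        if rstart0 >= n:
            rstart0, rend0 = rstart0 - n, rend0 - n
        else:
            # split a wrap-around placement at the origin into two segments
            split = b.qs + (n - 1 - rstart0)  # last oriented index on ref n-1
            parts = [
                (b.qs, split, rstart0, n - 1, role),
                (split + 1, b.qe, 0, rend0 - n, "supplementary"),
            ]
            segs = []
            for i, (s0, e0, r0, r1, prole) in enumerate(parts):
                qstart, qend = _oriented_to_given(qlen, b.orient, s0, e0)
                segs.append(
                    AlignmentSegment(
                        query_id, qstart, qend, name, r0 + 1, r1 + 1, strand,
                        int(b.mism) if i == 0 else 0, prole, ambiguous,
                    )
                )
            return segs
    qstart, qend = _oriented_to_given(qlen, b.orient, b.qs, b.qe)
    return [
        AlignmentSegment(
            query_id, qstart, qend, name, rstart0 + 1, rend0 + 1, strand,
            int(b.mism), role, ambiguous,
        )
    ]


# ---------------------------------------------------------------------------
# single-query mapping (reads of any length, contigs)
# ---------------------------------------------------------------------------


def map_query(
    query: str,
    genome: Genome,
    k: int = DEFAULT_K,
    min_anchor: int = DEFAULT_MIN_ANCHOR,
    max_mismatch_rate: float = DEFAULT_MAX_MISMATCH_RATE,
    index: Optional[KmerIndex] = None,
    query_id: str = "query",
) -> list[AlignmentSegment]:
    """Map one query sequence; returns 0, 1 or several segments.

    Chimeric queries (prefix and suffix anchoring at different loci) yield
    multiple segments, enabling split/junction detection downstream.
    """
    if len(query) < k:
        raise ValueError(f"query shorter than k={k}")
    if index is None or index.k != k:
        index = KmerIndex(genome, k)
    codes = encode(query)
    L = len(codes)
    step = max(1, min(16, (min_anchor - k) + 1 if min_anchor > k else 1))
    offsets = list(range(0, L - k + 1, step))
    if offsets[-1] != L - k:
        offsets.append(L - k)

    blocks: list[_Block] = []
    seen: set[tuple[int, int, int]] = set()
    for orient, oriented in ((0, codes), (1, (3 - codes)[::-1])):
        kmers = kmer_values(oriented, k)
        sel = kmers[np.array(offsets)]
        lo, hi = index.lookup(sel)
        for j, off in enumerate(offsets):
            cnt = int(hi[j] - lo[j])
            if cnt == 0 or cnt > _MAX_SEED_HITS:
                continue
            for g in index._gpos[lo[j] : hi[j]]:
                rep = int(index.replicon_of(np.array([g]))[0])
                pos0 = int(g - index.gstart[rep]) - off
                key = (orient, rep, pos0)
                if key in seen:
                    continue
                seen.add(key)
                # build the comparison window with explicit bounds handling
                # (queries may be longer than the index padding)
                ext_len = int(index.ext_lens[rep])
                window = np.full(L, SENTINEL, dtype=np.uint8)
                lo_q = max(0, -pos0)
                hi_q = min(L, ext_len - pos0)
                if hi_q > lo_q:
                    vpos = index.vstart[rep] + pos0
                    window[lo_q:hi_q] = index.vbuf[vpos + lo_q : vpos + hi_q]
                eq = window == oriented
                qs, qe, mism, score = _best_blocks(eq)
                blocks.append(
                    _Block(orient, rep, int(qs[0]), int(qe[0]), pos0, int(mism[0]), int(score[0]))
                )
    return _blocks_to_segments(query_id, L, blocks, index, min_anchor, max_mismatch_rate)


# ---------------------------------------------------------------------------
# batch read mapping
# ---------------------------------------------------------------------------


def map_reads(
    reads: Sequence[Read],
    genome: Genome,
    k: int = DEFAULT_K,
    min_anchor: int = DEFAULT_MIN_ANCHOR,
    max_mismatch_rate: float = DEFAULT_MAX_MISMATCH_RATE,
    index: Optional[KmerIndex] = None,
) -> list[AlignmentSegment]:
    """Map a batch of reads (vectorised fast path for uniform-length reads).

    Reads shorter than k are left unmapped.
    """
    if index is None or index.k != k:
        index = KmerIndex(genome, k)
    by_len: dict[int, list[int]] = {}
    for i, read in enumerate(reads):
        by_len.setdefault(len(read.sequence), []).append(i)

    segments: list[AlignmentSegment] = []
    for L, idxs in sorted(by_len.items()):
        if L < k:
            continue
        if L > index.pad:
            for i in idxs:
                segments.extend(
                    map_query(
                        reads[i].sequence, genome, k, min_anchor, max_mismatch_rate,
                        index, reads[i].id,
                    )
                )
            continue
        segments.extend(
            _map_uniform(
                [reads[i] for i in idxs], L, index, k, min_anchor, max_mismatch_rate
            )
        )
    return segments


def _read_matrix(reads: Sequence[Read], L: int) -> np.ndarray:
    blob = "".join(r.sequence for r in reads)
    return encode(blob).reshape(len(reads), L)


def _map_uniform(reads, L, index: KmerIndex, k, min_anchor, max_mismatch_rate):
    N = len(reads)
    M = _read_matrix(reads, L)
    RC = np.ascontiguousarray((3 - M)[:, ::-1])
    offsets = sorted({0, (L - k) // 2, L - k})

    # ---- gather candidate placements (read, orientation, replicon, pos0)
    cand_ri, cand_or, cand_rep, cand_pos0 = [], [], [], []
    for orient, mat in ((0, M), (1, RC)):
        for off in offsets:
            v = np.zeros(N, dtype=np.uint64)
            for j in range(k):
                v = v * np.uint64(4) + mat[:, off + j].astype(np.uint64)
            lo, hi = index.lookup(v)
            cnt = hi - lo
            sel = (cnt > 0) & (cnt <= _MAX_SEED_HITS)
            if not sel.any():
                continue
            ri = np.flatnonzero(sel)
            c = cnt[sel].astype(np.int64)
            starts = lo[sel].astype(np.int64)
            total = int(c.sum())
            flat = starts.repeat(c) + (np.arange(total) - np.repeat(np.cumsum(c) - c, c))
            g = index._gpos[flat]
            rep = index.replicon_of(g)
            pos0 = g - index.gstart[rep] - off
            cand_ri.append(ri.repeat(c))
            cand_or.append(np.full(total, orient, dtype=np.int8))
            cand_rep.append(rep)
            cand_pos0.append(pos0)
    if not cand_ri:
        return []
    ri = np.concatenate(cand_ri)
    orient = np.concatenate(cand_or)
    rep = np.concatenate(cand_rep)
    pos0 = np.concatenate(cand_pos0)

    # dedupe identical placements suggested by several seeds
    key = (
        (ri.astype(np.int64) * 2 + orient) * np.int64(1 << 42)
        + (pos0 + L)
        + rep.astype(np.int64) * np.int64(1 << 34)
    )
    _, keep = np.unique(key, return_index=True)
    ri, orient, rep, pos0 = ri[keep], orient[keep], rep[keep], pos0[keep]

    # ---- verify candidates: mismatch counts over the full-length window
    vpos = index.vstart[rep] + pos0
    C = len(ri)
    mism = np.empty(C, dtype=np.int64)
    eq_store: dict[int, np.ndarray] = {}
    offs = np.arange(L)
    chunk = 65536
    mm_full = int(np.floor(max_mismatch_rate * L))
    # candidates whose window pokes past the replicon must be trimmed by the
    # block search even when the sentinel mismatches stay under the full-
    # length budget, so a segment never overruns the reference bounds
    oob = (pos0 < 0) | (pos0 + L > index.ext_lens[rep])
    hard_rows: list[int] = []
    for c0 in range(0, C, chunk):
        c1 = min(C, c0 + chunk)
        win = index.vbuf[vpos[c0:c1, None] + offs[None, :]]
        rows = np.where(orient[c0:c1, None] == 0, M[ri[c0:c1]], RC[ri[c0:c1]])
        eq = win == rows
        m = L - eq.sum(axis=1)
        mism[c0:c1] = m
        bad = np.flatnonzero((m > mm_full) | oob[c0:c1])
        for b in bad:
            eq_store[c0 + int(b)] = eq[b]
            hard_rows.append(c0 + int(b))

    qs = np.zeros(C, dtype=np.int64)
    qe = np.full(C, L - 1, dtype=np.int64)
    score = (L - mism) + _MISMATCH * mism
    block_mism = mism.copy()
    if hard_rows:
        hr = np.array(hard_rows)
        eqm = np.stack([eq_store[i] for i in hard_rows])
        s, e, bm, sc = _best_blocks(eqm)
        qs[hr], qe[hr], block_mism[hr], score[hr] = s, e, bm, sc

    # ---- assemble per read
    order = np.lexsort((pos0, rep, orient, -score, ri))
    ri_s = ri[order]
    boundaries = np.flatnonzero(np.diff(ri_s)) + 1
    starts = np.concatenate([[0], boundaries])
    ends = np.concatenate([boundaries, [len(ri_s)]])

    segments: list[AlignmentSegment] = []

    # fast path: reads with a single valid placement on a linear replicon
    # (the overwhelming majority) skip the generic block selection
    single = (ends - starts) == 1
    rows1 = order[starts[single]]
    blen = qe[rows1] - qs[rows1] + 1
    ok1 = (
        (score[rows1] > 0)
        & (blen >= min_anchor)
        & (block_mism[rows1] <= max_mismatch_rate * blen)
        & ~np.array([index.circular[r] for r in rep[rows1]], dtype=bool)
    )
    rows1 = rows1[ok1]
    r0 = pos0[rows1] + qs[rows1] + 1
    r1 = pos0[rows1] + qe[rows1] + 1
    q0 = np.where(orient[rows1] == 0, qs[rows1] + 1, L - qe[rows1])
    q1 = np.where(orient[rows1] == 0, qe[rows1] + 1, L - qs[rows1])
    names = index.names
    segments.extend(
        AlignmentSegment(
            reads[ri_i].id, int(q0_i), int(q1_i), names[rep_i], int(r0_i), int(r1_i),
            "+" if or_i == 0 else "-", int(mm_i), "primary", False,
        )
        for ri_i, or_i, rep_i, q0_i, q1_i, r0_i, r1_i, mm_i in zip(
            ri[rows1], orient[rows1], rep[rows1], q0, q1, r0, r1, block_mism[rows1]
        )
    )

    # generic path: multi-candidate reads and circular-reference placements
    for s0, e0 in zip(starts[~single], ends[~single]):
        rows = order[s0:e0]
        read = reads[int(ri_s[s0])]
        blocks = [
            _Block(
                int(orient[r]), int(rep[r]), int(qs[r]), int(qe[r]),
                int(pos0[r]), int(block_mism[r]), int(score[r]),
            )
            for r in rows
        ]
        segments.extend(
            _blocks_to_segments(read.id, L, blocks, index, min_anchor, max_mismatch_rate)
        )
    # single-placement reads on circular replicons fall through the generic path
    for row in order[starts[single]][~ok1]:
        if not index.circular[rep[row]]:
            continue
        read = reads[int(ri[row])]
        blocks = [
            _Block(
                int(orient[row]), int(rep[row]), int(qs[row]), int(qe[row]),
                int(pos0[row]), int(block_mism[row]), int(score[row]),
            )
        ]
        segments.extend(
            _blocks_to_segments(read.id, L, blocks, index, min_anchor, max_mismatch_rate)
        )
    return segments


# ---------------------------------------------------------------------------
# coverage
# ---------------------------------------------------------------------------


def compute_coverage(
    segments: Iterable[AlignmentSegment], replicon: Replicon
) -> CoverageProfile:
    """Per-base depth: ``depth[i]`` = number of segments whose reference
    interval contains position i (1-based)."""
    n = replicon.length
    diff = np.zeros(n + 1, dtype=np.int64)
    for seg in segments:
        if seg.replicon != replicon.name:
            raise ValueError(
                f"segment on {seg.replicon!r} fed to coverage of {replicon.name!r}"
            )
        if not (1 <= seg.rstart <= seg.rend <= n):
            raise ValueError(
                f"segment [{seg.rstart},{seg.rend}] outside replicon bounds [1,{n}]"
            )
        diff[seg.rstart - 1] += 1
        diff[seg.rend] -= 1
    return CoverageProfile(replicon.name, np.cumsum(diff[:-1]))


def trimmed_mean_depth(profile: CoverageProfile, end_trim: int) -> float:
    """Mean depth over [end_trim+1, n-end_trim]; robust to terminal dips."""
    n = profile.n
    if end_trim < 0 or 2 * end_trim >= n:
        raise ValueError(f"end_trim={end_trim} leaves no interior on length {n}")
    return float(np.mean(profile.depth[end_trim : n - end_trim]))
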