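"""Cas9 spacer design with a genome-wide off-target screen.

Streptococcus pyogenes Cas9 recognises any 20-mer protospacer immediately
5' of an NGG PAM. In ~70% GC genomes NGG occurs at high frequency, so a
usable spacer must be screened against every NGG-adjacent 20-mer in the
genome. The screen is an explicit Hamming-distance contract: a candidate's
off-target count is the number of genomic sites (both strands, all
replicons) within ``max_mismatches`` of the spacer that carry a PAM,
excluding the on-target site itself. Overlapping hits at the same
(replicon, strand, start) collapse to one site.

An optional stricter seed-region rule (zero mismatches tolerated in the 12
PAM-proximal bases) reflects common Cas9 practice and is off by default.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from ._seq import decode, encode, revcomp, revcomp_codes
from .model import Genome, SpacerCandidate

SPACER_LEN = 20
PAM_LEN = 3
SITE_LEN = SPACER_LEN + PAM_LEN
DEFAULT_MAX_MISMATCHES = 2
SEED_REGION = 12  # PAM-proximal bases under the optional strict rule

_G = 2  # code for G
_C = 1


def enumerate_protospacers(
    genome: Genome, replicon: str, start: int, end: int
) -> list[SpacerCandidate]:
    """Every 20-mer immediately 5' of an NGG on either strand, with the
    full protospacer+PAM inside [start, end] (1-based inclusive).

    ``protospacer_start`` is strand-oriented: the forward coordinate of the
    spacer's 5' end on its own strand.
    """
    rep = genome[replicon]
    n = rep.length
    if not (1 <= start <= end <= n):
        raise ValueError(f"region [{start},{end}] out of bounds for {replicon!r} (1..{n})")
    codes = encode(rep.sequence)
    candidates: list[SpacerCandidate] = []
    # forward: spacer at [p, p+19], PAM NGG at [p+20, p+22] (0-based p)
    lo, hi = start - 1, end - SITE_LEN  # inclusive 0-based range of p
    for p in range(lo, hi + 1):
        if codes[p + 21] == _G and codes[p + 22] == _G:
            candidates.append(
                SpacerCandidate(
                    spacer=decode(codes[p : p + 20]),
                    replicon=replicon,
                    protospacer_start=p + 1,
                    strand="+",
                    pam=decode(codes[p + 20 : p + 23]),
                )
            )
        # reverse: forward window [p, p+22] holds CCN + revcomp(spacer)
        if codes[p] == _C and codes[p + 1] == _C:
            candidates.append(
                SpacerCandidate(
                    spacer=decode(revcomp_codes(codes[p + 3 : p + 23])),
                    replicon=replicon,
                    protospacer_start=p + 23,
                    strand="-",
                    pam=decode(revcomp_codes(codes[p : p + 3])),
                )
            )
    candidates.sort(key=lambda c: (c.protospacer_start if c.strand == "+" else c.protospacer_start - 19, c.strand))
    return candidates


def _site_mismatches(spacer_codes: np.ndarray, codes: np.ndarray, seed_only: bool = False):
    """Mismatch counts of the spacer against every forward window of a
    replicon, for both strand interpretations.

    Returns (mm_plus, mm_minus, pam_plus, pam_minus) where index p refers to
    the forward window starting at 0-based p: on + the spacer occupies
    [p, p+19] with NGG at [p+20, p+22]; on - the site is CCN + revcomp
    spacer over [p, p+22].
    """
    n = len(codes)
    m = n - SITE_LEN + 1
    if m <= 0:
        z = np.zeros(0, dtype=np.int64)
        return z, z, z.astype(bool), z.astype(bool)
    rc = revcomp_codes(spacer_codes)
    mm_plus = np.zeros(m, dtype=np.int64)
    mm_minus = np.zeros(m, dtype=np.int64)
    js = range(SPACER_LEN - SEED_REGION, SPACER_LEN) if seed_only else range(SPACER_LEN)
    for j in js:
        mm_plus += codes[j : j + m] != spacer_codes[j]
        # on the minus strand the spacer's PAM-proximal end sits at low
        # forward coordinates; revcomp(spacer)[i] occupies forward p+3+i
        i = SPACER_LEN - 1 - j  # spacer index j maps to rc index i
        mm_minus += codes[3 + i : 3 + i + m] != rc[i]
    pam_plus = (codes[21 : 21 + m] == _G) & (codes[22 : 22 + m] == _G)
    pam_minus = (codes[0:m] == _C) & (codes[1 : 1 + m] == _C)
    return mm_plus, mm_minus, pam_plus, pam_minus


def screen_off_targets(
    candidate: SpacerCandidate,
    genome: Genome,
    max_mismatches: int = DEFAULT_MAX_MISMATCHES,
    require_pam: bool = True,
    seed_region_strict: bool = False,
) -> SpacerCandidate:
    """Count genome-wide sites within ``max_mismatches`` of the candidate.

    The on-target site is excluded. ``near_miss_hits`` counts sites at
    exactly ``max_mismatches + 1`` (used for ranking). With
    ``seed_region_strict`` a site additionally needs zero mismatches in the
    12 PAM-proximal bases to count as an off-target.
    """
    spacer_codes = encode(candidate.spacer)
    hits = 0
    near = 0
    for rep in genome:
        codes = encode(rep.sequence)
        mm_p, mm_m, pam_p, pam_m = _site_mismatches(spacer_codes, codes)
        if seed_region_strict:
            smm_p, smm_m, _, _ = _site_mismatches(spacer_codes, codes, seed_only=True)
        m = len(mm_p)
        if m == 0:
            continue
        ok_p = np.ones(m, dtype=bool) if not require_pam else pam_p
        ok_m = np.ones(m, dtype=bool) if not require_pam else pam_m
        hit_p = ok_p & (mm_p <= max_mismatches)
        hit_m = ok_m & (mm_m <= max_mismatches)
        if seed_region_strict:
            hit_p &= smm_p == 0
            hit_m &= smm_m == 0
        near_p = ok_p & (mm_p == max_mismatches + 1)
        near_m = ok_m & (mm_m == max_mismatches + 1)
        if rep.name == candidate.replicon:
            # exclude the on-target site at its exact (strand, start)
            if candidate.strand == "+":
                p0 = candidate.protospacer_start - 1
                if 0 <= p0 < m and hit_p[p0]:
                    hit_p = hit_p.copy()
                    hit_p[p0] = False
            else:
                p0 = candidate.protospacer_start - SITE_LEN  # forward window start
                if 0 <= p0 < m and hit_m[p0]:
                    hit_m = hit_m.copy()
                    hit_m[p0] = False
        hits += int(hit_p.sum()) + int(hit_m.sum())
        near += int(near_p.sum()) + int(near_m.sum())
    return SpacerCandidate(
        spacer=candidate.spacer,
        replicon=candidate.replicon,
        protospacer_start=candidate.protospacer_start,
        strand=candidate.strand,
        pam=candidate.pam,
        off_target_hits=hits,
        near_miss_hits=near,
        unique=hits == 0,
    )


def design_spacers(
    genome: Genome,
    replicon: str,
    start: int,
    end: int,
    max_mismatches: int = DEFAULT_MAX_MISMATCHES,
    require_pam: bool = True,
    seed_region_strict: bool = False,
) -> list[SpacerCandidate]:
    """Enumerate, screen and rank spacers for a target region.

    Only off-target-free candidates are returned, ranked by fewest
    near-miss sites (at ``max_mismatches + 1``), then position, then
    strand. An empty list is a valid outcome (e.g. a target region
    duplicated verbatim elsewhere in the genome).
    """
    screened = [
        screen_off_targets(c, genome, max_mismatches, require_pam, seed_region_strict)
        for c in enumerate_protospacers(genome, replicon, start, end)
    ]
    unique = [c for c in screened if c.unique]
    unique.sort(key=lambda c: (c.near_miss_hits, c.protospacer_start, c.strand))
    return unique
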