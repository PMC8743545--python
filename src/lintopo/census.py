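"""Per-replicon presence/absence calls and copy number relative to the
chromosome.

Copy number is the ratio of trimmed mean depths (plasmid over chromosome),
a read-depth proxy for plasmid molecules per chromosome. Trimming one read
length off each end keeps the terminal coverage dips of linear replicons
and PCR coverage spikes from biasing the ratio. Presence is operationalised
as breadth of coverage: near-complete breadth means the replicon is there,
near-zero breadth means it was lost (cured); anything in between is called
partial.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np

from .mapping import trimmed_mean_depth
from .model import CopyNumberEstimate, CoverageProfile

DEFAULT_PRESENT_BREADTH_MIN = 0.95
DEFAULT_ABSENT_BREADTH_MAX = 0.05
DEFAULT_MIN_DEPTH = 1
DEFAULT_END_TRIM = 150  # one read length


def breadth_of_coverage(profile: CoverageProfile, min_depth: int = DEFAULT_MIN_DEPTH) -> float:
    """Fraction of positions covered at depth >= min_depth."""
    return float(np.mean(profile.depth >= min_depth))


def call_presence(
    breadth: float,
    present_breadth_min: float = DEFAULT_PRESENT_BREADTH_MIN,
    absent_breadth_max: float = DEFAULT_ABSENT_BREADTH_MAX,
) -> str:
    """Classify a breadth value as present / absent / partial."""
    if not (0 < absent_breadth_max < present_breadth_min < 1):
        raise ValueError(
            "thresholds must satisfy 0 < absent_breadth_max < present_breadth_min < 1"
        )
    if breadth >= present_breadth_min:
        return "present"
    if breadth <= absent_breadth_max:
        return "absent"
    return "partial"


def copy_number(
    profiles: Mapping[str, CoverageProfile],
    chromosome_name: str,
    end_trim: int = DEFAULT_END_TRIM,
    min_depth: int = DEFAULT_MIN_DEPTH,
    present_breadth_min: float = DEFAULT_PRESENT_BREADTH_MIN,
    absent_breadth_max: float = DEFAULT_ABSENT_BREADTH_MAX,
) -> list[CopyNumberEstimate]:
    """Copy-number and presence estimates for every replicon profile.

    ``ratio_vs_chromosome`` = trimmed mean depth of the replicon divided by
    that of the chromosome. Raises if the chromosome profile is missing or
    has zero trimmed mean depth.
    """
    if chromosome_name not in profiles:
        raise ValueError(f"no coverage profile for chromosome {chromosome_name!r}")

    def _trim(profile: CoverageProfile) -> int:
        # degrade gracefully for replicons too short to trim
        return end_trim if 2 * end_trim < profile.n else 0

    chrom = profiles[chromosome_name]
    chrom_depth = trimmed_mean_depth(chrom, _trim(chrom))
    if chrom_depth <= 0:
        raise ValueError("chromosome trimmed mean depth is zero; cannot normalise")

    estimates = []
    for name, profile in profiles.items():
        mean = trimmed_mean_depth(profile, _trim(profile))
        breadth = breadth_of_coverage(profile, min_depth)
        estimates.append(
            CopyNumberEstimate(
                replicon=name,
                mean_depth=mean,
                ratio_vs_chromosome=mean / chrom_depth,
                breadth=breadth,
                status=call_presence(breadth, present_breadth_min, absent_breadth_max),
            )
        )
    return estimates
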