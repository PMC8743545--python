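"""Domain types for linear-replicon topology analysis.

All coordinates at public interfaces are 1-based and inclusive, the
convention genome papers print positions in. Any half-open arithmetic is an
implementation detail and never escapes a function boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Literal, Mapping, Optional, Sequence

from ._seq import encode

Topology = Literal["linear", "circular"]
Strand = Literal["+", "-"]

TOPOLOGIES = ("linear", "circular")


@dataclass(frozen=True)
class Replicon:
    """One independently replicating DNA molecule (chromosome or plasmid)."""

    name: str
    sequence: str
    topology: Topology = "linear"

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("replicon name must be non-empty")
        if not self.sequence:
            raise ValueError(f"replicon {self.name!r}: sequence must be non-empty")
        if self.topology not in TOPOLOGIES:
            raise ValueError(f"replicon {self.name!r}: topology must be linear or circular")
        encode(self.sequence)  # validates the {A,C,G,T} alphabet

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def is_linear(self) -> bool:
        return self.topology == "linear"


class Genome:
    """Ordered collection of uniquely named replicons with a designated
    chromosome that serves as the normalisation reference for copy number."""

    def __init__(self, replicons: Sequence[Replicon], chromosome_name: Optional[str] = None):
        replicons = list(replicons)
        if not replicons:
            raise ValueError("genome must contain at least one replicon")
        names = [r.name for r in replicons]
        seen = set()
        for n in names:
            if n in seen:
                raise ValueError(f"duplicate replicon name {n!r}")
            seen.add(n)
        if chromosome_name is None:
            chromosome_name = names[0]
        if chromosome_name not in seen:
            raise ValueError(f"chromosome_name {chromosome_name!r} is not a member replicon")
        self.replicons = replicons
        self.chromosome_name = chromosome_name
        self._by_name = {r.name: r for r in replicons}

    def __iter__(self) -> Iterator[Replicon]:
        return iter(self.replicons)

    def __len__(self) -> int:
        return len(self.replicons)

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def __getitem__(self, name: str) -> Replicon:
        try:
            return self._by_name[name]
        except KeyError:
            raise KeyError(f"no replicon named {name!r} in genome") from None

    @property
    def names(self) -> list[str]:
        return [r.name for r in self.replicons]

    @property
    def chromosome(self) -> Replicon:
        return self._by_name[self.chromosome_name]

    @property
    def total_length(self) -> int:
        return sum(r.length for r in self.replicons)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        parts = ", ".join(f"{r.name}:{r.length}bp/{r.topology}" for r in self.replicons)
        return f"Genome({parts}; chromosome={self.chromosome_name})"


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one simulated read: where it was sampled from."""

    source_replicon: str
    source_start: int  # 1-based position of the read's leftmost base on the forward strand
    strand: Strand
    errors_introduced: int = 0


@dataclass(frozen=True)
class Read:
    """A sequencing read. ``mate`` is 1 or 2 for paired reads, 0 if unpaired."""

    id: str
    sequence: str
    mate: int = 0
    truth: Optional[TruthRecord] = None


@dataclass(slots=True)
class AlignmentSegment:
    """One aligned block of a query (read or contig) on a replicon.

    ``qstart``/``qend`` are 1-based inclusive on the query *as given* (i.e.
    in the original read orientation even for minus-strand placements);
    ``rstart``/``rend`` are 1-based inclusive on the replicon forward strand.
    Split queries produce several segments: the best-scoring one is
    ``primary``, the rest ``supplementary``.
    """

    query_id: str
    qstart: int
    qend: int
    replicon: str
    rstart: int
    rend: int
    strand: Strand
    edit_distance: int = 0
    role: str = "primary"
    ambiguous: bool = False

    @property
    def query_interval(self) -> tuple[int, int]:
        return (self.qstart, self.qend)

    @property
    def ref_interval(self) -> tuple[int, int]:
        return (self.rstart, self.rend)

    @property
    def ref_length(self) -> int:
        return self.rend - self.rstart + 1


@dataclass
class CoverageProfile:
    """Per-base read depth for one replicon; ``depth[i-1]`` is position i."""

    replicon: str
    depth: "object"  # numpy int array of length n

    @property
    def n(self) -> int:
        return len(self.depth)


@dataclass(frozen=True)
class CopyNumberEstimate:
    replicon: str
    mean_depth: float
    ratio_vs_chromosome: float
    breadth: float
    status: str  # present | absent | partial


@dataclass(frozen=True)
class TerminalBoundary:
    """First (left) or last (right) retained position of a linear replicon."""

    replicon: str
    end: str  # left | right
    position: int
    support_depth: float


@dataclass(frozen=True)
class JunctionEvidence:
    """One query demonstrating contiguity from the retained right end (R)
    back to the retained left end (L) of a replicon."""

    query_id: str
    R: int
    L: int
    right_anchor_len: int
    left_anchor_len: int
    junction_gap: int  # <0 overlap, >0 gap between the two query intervals


@dataclass
class CircularizationCall:
    replicon: str
    replicon_length: int
    L: int
    R: int
    status: str  # circularized | terminal_deletion_only | intact
    evidence: list[JunctionEvidence] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (1 <= self.L <= self.replicon_length and 1 <= self.R <= self.replicon_length):
            raise ValueError("L and R must lie within [1, replicon length]")
        if self.L > self.R:
            raise ValueError("L must not exceed R")
        if self.status == "circularized" and not self.evidence:
            raise ValueError("a circularized call requires junction evidence")

    @property
    def left_deletion(self) -> int:
        return self.L - 1

    @property
    def right_deletion(self) -> int:
        return self.replicon_length - self.R


@dataclass(frozen=True)
class TIRReport:
    """Terminal inverted repeat of a linear replicon, in forward coordinates
    of both ends.

    ``left_offset`` counts bases of the left terminal window preceding the
    repeat; ``right_truncation`` counts bases of the idealised repeat missing
    at the right end (the right copy stopping short of the terminus).
    """

    replicon: str
    left_interval: tuple[int, int]
    right_interval: tuple[int, int]
    repeat_length: int
    identity: int  # percent, rounded to nearest integer
    differences: int
    left_offset: int
    right_truncation: int


@dataclass(frozen=True)
class SpacerCandidate:
    """A 20-mer Cas9 protospacer with its NGG PAM.

    ``protospacer_start`` is the 1-based forward-strand coordinate of the
    protospacer's 5' end on its own strand.
    """

    spacer: str
    replicon: str
    protospacer_start: int
    strand: Strand
    pam: str
    off_target_hits: Optional[int] = None
    near_miss_hits: Optional[int] = None
    unique: Optional[bool] = None

    def __post_init__(self) -> None:
        if len(self.spacer) != 20:
            raise ValueError("spacer must be a 20-mer")
        if len(self.pam) != 3 or not self.pam.endswith("GG"):
            raise ValueError("PAM must match NGG")
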