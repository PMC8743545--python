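"""Synthetic genomes, mutant strains and paired-end reads.

The generator emulates the data regime of a multi-replicon actinomycete
genome project: one large linear chromosome plus linear plasmids of widely
differing sizes and copy numbers, short terminal inverted repeats (TIRs)
planted at linear-replicon ends, and paired-end Illumina-like reads with
uniform substitution errors. Mutant strains are derived from a parental
genome by whole-replicon loss and/or chromosome circularization with
terminal deletions, the two event classes megaplasmid curing produces.

Linear replicons are sampled with fragments wholly inside the molecule,
which mechanically depresses depth over the terminal ~read length — the
same under-coverage real shotgun data shows at linear-plasmid ends.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import numpy as np

from ._seq import _BASES, decode, encode, revcomp_codes
from .model import Genome, Read, Replicon, TruthRecord

# ---------------------------------------------------------------------------
# strain specifications
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DropReplicon:
    """Whole-replicon loss (plasmid curing)."""

    name: str


@dataclass(frozen=True)
class Circularize:
    """Fuse the two ends of a linear replicon after deleting ``left_del``
    bases from the left terminus and ``right_del`` from the right."""

    name: str
    left_del: int = 0
    right_del: int = 0


Event = Union[DropReplicon, Circularize]


@dataclass
class StrainSpec:
    """Ordered derivation of a mutant strain from a parental genome.

    ``copy_numbers`` scales the sequencing depth of individual replicons
    relative to the chromosome (plasmid copies per chromosome); unlisted
    replicons are at one copy.
    """

    events: Sequence[Event] = ()
    copy_numbers: Mapping[str, float] = field(default_factory=dict)


def derive_strain(genome: Genome, spec: StrainSpec) -> Genome:
    """Apply a :class:`StrainSpec` to a parental genome.

    A circularize event on a length-n replicon with deletions (dl, dr)
    yields a circular replicon of length n-dl-dr whose sequence starts at
    original position dl+1 and ends at n-dr; the junction joins original
    positions n-dr -> dl+1. Untouched replicons are passed through intact.
    """
    reps = {r.name: r for r in genome}
    order = list(genome.names)
    for event in spec.events:
        if event.name not in reps:
            raise ValueError(f"strain event on missing replicon {event.name!r}")
        if isinstance(event, DropReplicon):
            del reps[event.name]
            order.remove(event.name)
        elif isinstance(event, Circularize):
            rep = reps[event.name]
            dl, dr = event.left_del, event.right_del
            if dl < 0 or dr < 0 or dl + dr >= rep.length:
                raise ValueError(
                    f"circularize({event.name}): deletions {dl}+{dr} must be "
                    f"non-negative and smaller than the replicon length {rep.length}"
                )
            seq = rep.sequence[dl : rep.length - dr]
            reps[event.name] = Replicon(rep.name, seq, "circular")
        else:  # pragma: no cover - exhaustive by construction
            raise TypeError(f"unknown event {event!r}")
    chromosome = genome.chromosome_name if genome.chromosome_name in reps else None
    if chromosome is None:
        raise ValueError("strain derivation removed the chromosome")
    return Genome([reps[n] for n in order], chromosome)


# ---------------------------------------------------------------------------
# replicon generation
# ---------------------------------------------------------------------------


def generate_replicon(
    name: str,
    length: int,
    gc: float = 0.70,
    tir_length: int = 0,
    seed: int = 0,
    topology: str = "linear",
) -> Replicon:
    """Random replicon at the given GC fraction with an optional planted TIR.

    With ``tir_length`` t > 0 the last t bases are set to the reverse
    complement of the first t, the defining symmetry of a perfect terminal
    inverted repeat. Deterministic for a given seed.
    """
    if not 0 < gc < 1:
        raise ValueError("gc must lie strictly between 0 and 1")
    if tir_length < 0 or 2 * tir_length > length:
        raise ValueError("tir_length must satisfy 0 <= tir_length <= length/2")
    rng = np.random.default_rng(seed)
    at, gcp = (1 - gc) / 2, gc / 2
    codes = rng.choice(4, size=length, p=[at, gcp, gcp, at]).astype(np.uint8)
    if tir_length:
        codes[length - tir_length :] = revcomp_codes(codes[:tir_length])
    return Replicon(name, decode(codes), topology)


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------


def simulate_reads(
    genome: Genome,
    mean_depth: float = 50.0,
    read_len: int = 150,
    insert_mean: int = 500,
    insert_sd: float = 50.0,
    sub_error: float = 0.005,
    seed: int = 0,
    copy_numbers: Optional[Mapping[str, float]] = None,
) -> list[Read]:
    """Simulate paired-end reads with uniform substitution errors.

    Pair counts per replicon are Poisson with mean
    ``depth * n / (2 * read_len)`` where depth is ``mean_depth`` scaled by
    the replicon's copy number. Fragments on linear replicons lie wholly
    inside [1, n]; circular replicons are sampled across the origin. Each
    read carries a :class:`TruthRecord` (replicon, 1-based start of its
    leftmost base on the forward strand, strand, error count).
    """
    if read_len > insert_mean:
        raise ValueError("read_len must not exceed insert_mean")
    if not 0 <= sub_error < 1:
        raise ValueError("sub_error must be a rate in [0, 1)")
    if mean_depth < 0:
        raise ValueError("mean_depth must be non-negative")
    copy_numbers = dict(copy_numbers or {})
    rng = np.random.default_rng(seed)
    reads: list[Read] = []

    for rep in genome:
        depth = mean_depth * copy_numbers.get(rep.name, 1.0)
        n = rep.length
        if depth <= 0:
            continue
        n_pairs = int(rng.poisson(depth * n / (2.0 * read_len)))
        if n_pairs == 0:
            continue
        codes = encode(rep.sequence)
        flen = np.rint(rng.normal(insert_mean, insert_sd, n_pairs)).astype(np.int64)
        flen = np.clip(flen, read_len, n)
        if rep.is_linear:
            # fragments wholly inside [0, n): depresses terminal depth
            starts = rng.integers(0, n - flen + 1)
            ext = codes
        else:
            starts = rng.integers(0, n, n_pairs)
            ext = np.concatenate([codes, codes])  # flen <= n so windows fit
        offs = np.arange(read_len)
        left = ext[starts[:, None] + offs[None, :]]
        rstart = starts + flen - read_len
        right_fwd = ext[rstart[:, None] + offs[None, :]]
        right = np.ascontiguousarray(3 - right_fwd[:, ::-1])  # revcomp

        # R1 is drawn from either fragment end with equal probability
        swap = rng.integers(0, 2, n_pairs).astype(bool)
        r1 = np.where(swap[:, None], right, left)
        r2 = np.where(swap[:, None], left, right)
        r1_strand = np.where(swap, "-", "+")
        r2_strand = np.where(swap, "+", "-")
        r1_start0 = np.where(swap, rstart, starts)
        r2_start0 = np.where(swap, starts, rstart)
        if not rep.is_linear:
            r1_start0 = r1_start0 % n
            r2_start0 = r2_start0 % n

        err1 = err2 = np.zeros(n_pairs, dtype=np.int64)
        if sub_error > 0:
            for mat in (r1, r2):
                mask = rng.random(mat.shape) < sub_error
                shifts = rng.integers(1, 4, mat.shape).astype(np.uint8)
                mat[mask] = (mat[mask] + shifts[mask]) % 4
                if mat is r1:
                    err1 = mask.sum(axis=1)
                else:
                    err2 = mask.sum(axis=1)

        for mate, mat, strands, starts0, errs in (
            (1, r1, r1_strand, r1_start0, err1),
            (2, r2, r2_strand, r2_start0, err2),
        ):
            blob = _BASES[mat].tobytes()
            for i in range(n_pairs):
                seq = blob[i * read_len : (i + 1) * read_len].decode("ascii")
                truth = TruthRecord(
                    rep.name, int(starts0[i]) + 1, str(strands[i]), int(errs[i])
                )
                reads.append(Read(f"{rep.name}-{i:07d}/{mate}", seq, mate, truth))
    return reads


def write_truth_table(reads: Sequence[Read], dest) -> None:
    """TSV of simulation ground truth: read id, replicon, start, strand, errors."""
    close = False
    if not hasattr(dest, "write"):
        dest, close = open(dest, "w"), True
    try:
        dest.write("read_id\treplicon\tstart\tstrand\terrors\n")
        for read in reads:
            t = read.truth
            if t is None:
                continue
            dest.write(
                f"{read.id}\t{t.source_replicon}\t{t.source_start}\t{t.strand}\t"
                f"{t.errors_introduced}\n"
            )
    finally:
        if close:
            dest.close()


# ---------------------------------------------------------------------------
# the shipped desk-scale fixture
# ---------------------------------------------------------------------------

#: Desk-scale stand-in preserving the size hierarchy of a megaplasmid-bearing
#: actinomycete genome: a 500 kb "chromosome", a 50 kb large plasmid at one
#: copy and a 5 kb small plasmid at two copies, all linear with 400 bp TIRs,
#: at 70% GC.
FIXTURE_CHROMOSOME_LEN = 500_000
FIXTURE_LARGE_PLASMID_LEN = 50_000
FIXTURE_SMALL_PLASMID_LEN = 5_000
FIXTURE_TIR_LEN = 400
FIXTURE_GC = 0.70
FIXTURE_DEPTH = 50.0
FIXTURE_READ_LEN = 150
FIXTURE_INSERT_MEAN = 500
FIXTURE_INSERT_SD = 50.0
FIXTURE_SUB_ERROR = 0.005

#: Terminal deletions of the shipped circularized strain: the losses of the
#: worked 6.75 Mb example (98,993 and 115,914 bp) scaled proportionally onto
#: the 500 kb fixture chromosome.
FIXTURE_LEFT_DEL = 7_334
FIXTURE_RIGHT_DEL = 8_588


def default_reference(seed: int = 0) -> Genome:
    """The shipped parental fixture genome (chromosome + 2 linear plasmids)."""
    rng = np.random.default_rng(seed)
    child = [int(s) for s in rng.integers(0, 2**31 - 1, 3)]
    return Genome(
        [
            generate_replicon(
                "chromosome", FIXTURE_CHROMOSOME_LEN, FIXTURE_GC, FIXTURE_TIR_LEN, child[0]
            ),
            generate_replicon(
                "pLarge", FIXTURE_LARGE_PLASMID_LEN, FIXTURE_GC, FIXTURE_TIR_LEN, child[1]
            ),
            generate_replicon(
                "pSmall", FIXTURE_SMALL_PLASMID_LEN, FIXTURE_GC, FIXTURE_TIR_LEN, child[2]
            ),
        ],
        chromosome_name="chromosome",
    )


def default_copy_numbers() -> dict[str, float]:
    return {"pSmall": 2.0}


def cured_circularized_spec() -> StrainSpec:
    """Megaplasmid-cured, chromosome-circularized strain spec for the fixture:
    the large plasmid is lost and the chromosome circularizes with terminal
    deletions of 7,334 / 8,588 bp."""
    return StrainSpec(
        events=[
            DropReplicon("pLarge"),
            Circularize("chromosome", FIXTURE_LEFT_DEL, FIXTURE_RIGHT_DEL),
        ],
        copy_numbers=default_copy_numbers(),
    )


def parental_spec() -> StrainSpec:
    return StrainSpec(events=[], copy_numbers=default_copy_numbers())
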