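"""Reading and writing of FASTA, FASTQ, SAM and the topology sidecar config.

FASTA/FASTQ go through Biopython's SeqIO; SAM goes through pysam. Only the
SAM fields QNAME, FLAG, RNAME, POS, CIGAR, SEQ and the NM tag are consumed;
qualities are ignored. All coordinates surfaced here are 1-based inclusive.
"""

from __future__ import annotations

import os
import tempfile
from typing import Iterable, Mapping, Optional, TextIO, Union

import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._seq import revcomp
from .model import AlignmentSegment, Genome, Read, Replicon

__all__ = [
    "read_topology_config", "write_topology_config", "read_fasta",
    "write_fasta", "read_fastq", "write_fastq", "read_sam", "write_sam",
]

PathOrHandle = Union[str, os.PathLike, TextIO]


def _as_handle(source: PathOrHandle, mode: str):
    """Return (handle, needs_close)."""
    if hasattr(source, "read") or hasattr(source, "write"):
        return source, False
    return open(source, mode), True


# ---------------------------------------------------------------------------
# topology sidecar config
# ---------------------------------------------------------------------------

def read_topology_config(source: PathOrHandle) -> tuple[Optional[str], dict[str, str]]:
    """Parse a flat ``key = value`` sidecar file.

    The reserved key ``chromosome`` names the normalisation reference; every
    other key maps a replicon name to ``linear`` or ``circular``. Blank lines
    and ``#`` comments are ignored.
    """
    handle, close = _as_handle(source, "r")
    chromosome = None
    topology: dict[str, str] = {}
    try:
        for lineno, line in enumerate(handle, 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"topology config line {lineno}: expected 'key = value'")
            key, value = (part.strip() for part in line.split("=", 1))
            if key == "chromosome":
                chromosome = value
            else:
                if value not in ("linear", "circular"):
                    raise ValueError(
                        f"topology config line {lineno}: {value!r} is not linear/circular"
                    )
                topology[key] = value
    finally:
        if close:
            handle.close()
    return chromosome, topology


def write_topology_config(genome: Genome, dest: PathOrHandle) -> None:
    handle, close = _as_handle(dest, "w")
    try:
        handle.write(f"chromosome = {genome.chromosome_name}\n")
        for rep in genome:
            handle.write(f"{rep.name} = {rep.topology}\n")
    finally:
        if close:
            handle.close()


# ---------------------------------------------------------------------------
# FASTA / FASTQ
# ---------------------------------------------------------------------------

def read_fasta(
    source: PathOrHandle,
    topology: Optional[Mapping[str, str]] = None,
    chromosome_name: Optional[str] = None,
) -> Genome:
    """Read a multi-record FASTA into a :class:`Genome`.

    Topology defaults to linear for every record; a sidecar mapping (see
    :func:`read_topology_config`) overrides per replicon. Duplicate names,
    empty sequences and non-ACGT characters raise ``ValueError``.
    """
    topology = dict(topology or {})
    handle, close = _as_handle(source, "r")
    replicons = []
    try:
        for rec in SeqIO.parse(handle, "fasta"):
            seq = str(rec.seq).upper()
            try:
                replicons.append(
                    Replicon(rec.id, seq, topology.get(rec.id, "linear"))
                )
            except ValueError as exc:
                raise ValueError(f"FASTA record {rec.id!r}: {exc}") from None
    finally:
        if close:
            handle.close()
    return Genome(replicons, chromosome_name)


def write_fasta(genome: Genome, dest: PathOrHandle) -> None:
    handle, close = _as_handle(dest, "w")
    try:
        records = [
            SeqRecord(Seq(rep.sequence), id=rep.name, description="")
            for rep in genome
        ]
        SeqIO.write(records, handle, "fasta")
    finally:
        if close:
            handle.close()


def read_fastq(source: PathOrHandle) -> list[Read]:
    """Read a 4-line FASTQ; mate numbers are inferred from ``/1``/``/2``
    id suffixes, anything else is unpaired. Qualities are discarded."""
    handle, close = _as_handle(source, "r")
    reads = []
    try:
        for rec in SeqIO.parse(handle, "fastq"):
            mate = 0
            if rec.id.endswith("/1"):
                mate = 1
            elif rec.id.endswith("/2"):
                mate = 2
            reads.append(Read(rec.id, str(rec.seq).upper(), mate))
    finally:
        if close:
            handle.close()
    return reads


def write_fastq(reads: Iterable[Read], dest: PathOrHandle) -> None:
    """Write reads as 4-line FASTQ with constant placeholder qualities."""
    handle, close = _as_handle(dest, "w")
    try:
        for read in reads:
            handle.write(f"@{read.id}\n{read.sequence}\n+\n{'I' * len(read.sequence)}\n")
    finally:
        if close:
            handle.close()


# ---------------------------------------------------------------------------
# SAM
# ---------------------------------------------------------------------------

def read_sam(source: PathOrHandle, genome: Genome) -> list[AlignmentSegment]:
    """Parse a SAM file into :class:`AlignmentSegment` records.

    The header's sequence names and lengths must match ``genome``; unmapped
    lines are dropped; lines with the supplementary flag bit get
    ``role="supplementary"``. POS stays 1-based; query intervals are reported
    in the original read orientation (flipped back for minus-strand lines).
    """
    if hasattr(source, "read"):
        # pysam wants a path; spool file-like input to a temp file
        with tempfile.NamedTemporaryFile("w", suffix=".sam", delete=False) as tmp:
            tmp.write(source.read())
            path = tmp.name
        try:
            return read_sam(path, genome)
        finally:
            os.unlink(path)

    segments: list[AlignmentSegment] = []
    with pysam.AlignmentFile(str(source), "r", check_sq=False) as sam:
        header = sam.header.to_dict()
        for sq in header.get("SQ", []):
            name, length = sq["SN"], int(sq["LN"])
            if name not in genome:
                raise ValueError(f"SAM header sequence {name!r} absent from genome")
            if genome[name].length != length:
                raise ValueError(
                    f"SAM header length {length} for {name!r} does not match "
                    f"genome length {genome[name].length}"
                )
        for aln in sam:
            if aln.is_unmapped or aln.cigartuples is None:
                continue
            rname = aln.reference_name
            if rname not in genome:
                raise ValueError(f"alignment references unknown sequence {rname!r}")
            qlen = aln.infer_read_length()
            if qlen is None:
                qlen = len(aln.query_sequence or "")
            qs_stored = aln.query_alignment_start + 1  # 1-based on stored SEQ
            qe_stored = aln.query_alignment_end
            if aln.is_reverse:
                qstart = qlen - qe_stored + 1
                qend = qlen - qs_stored + 1
            else:
                qstart, qend = qs_stored, qe_stored
            nm = aln.get_tag("NM") if aln.has_tag("NM") else 0
            segments.append(
                AlignmentSegment(
                    query_id=aln.query_name,
                    qstart=qstart,
                    qend=qend,
                    replicon=rname,
                    rstart=aln.reference_start + 1,
                    rend=aln.reference_end,
                    strand="-" if aln.is_reverse else "+",
                    edit_distance=int(nm),
                    role="supplementary" if aln.is_supplementary else "primary",
                )
            )
    return segments


def write_sam(
    segments: Iterable[AlignmentSegment],
    genome: Genome,
    dest: PathOrHandle,
    sequences: Optional[Mapping[str, str]] = None,
) -> None:
    """Write segments as SAM with soft-clip CIGARs and NM tags.

    ``sequences`` maps query id to the query sequence as given; if absent,
    SEQ is written as ``*`` (the CIGAR then carries no trailing clip because
    the full query length is unknown).
    """
    handle, close = _as_handle(dest, "w")
    try:
        handle.write("@HD\tVN:1.6\tSO:unknown\n")
        for rep in genome:
            handle.write(f"@SQ\tSN:{rep.name}\tLN:{rep.length}\n")
        for seg in segments:
            flag = 0
            if seg.strand == "-":
                flag |= 16
            if seg.role == "supplementary":
                flag |= 2048
            seq = sequences.get(seg.query_id) if sequences else None
            aligned = seg.qend - seg.qstart + 1
            if seq is not None:
                qlen = len(seq)
                lead, trail = seg.qstart - 1, qlen - seg.qend
                if seg.strand == "-":
                    lead, trail = trail, lead
                    seq_out = revcomp(seq)
                else:
                    seq_out = seq
                cigar = (f"{lead}S" if lead else "") + f"{aligned}M" + (
                    f"{trail}S" if trail else ""
                )
            else:
                seq_out = "*"
                cigar = f"{aligned}M"
            mapq = 0 if seg.ambiguous else 60
            handle.write(
                f"{seg.query_id}\t{flag}\t{seg.replicon}\t{seg.rstart}\t{mapq}\t"
                f"{cigar}\t*\t0\t0\t{seq_out}\t*\tNM:i:{seg.edit_distance}\n"
            )
    finally:
        if close:
            handle.close()
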