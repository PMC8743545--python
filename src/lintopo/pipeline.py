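"""End-to-end orchestration: map -> coverage -> census -> topology -> TIR
(-> spacers), producing one per-strain report.

Everything is deterministic given (inputs, parameters, seed). Every
parameter actually used is recorded in the report so a run can be
regenerated from its logged configuration alone.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from . import census as census_mod
from . import io as io_mod
from . import mapping, topology
from . import tir as tir_mod
from .model import (
    AlignmentSegment,
    CircularizationCall,
    CopyNumberEstimate,
    CoverageProfile,
    Genome,
    Read,
    TIRReport,
)


@dataclass
class RunConfig:
    """All inputs and stage parameters of one pipeline run.

    Inputs may be given as paths (FASTA/FASTQ/SAM) or as in-memory objects;
    in-memory objects win when both are set.
    """

    # inputs
    reference: Optional[str] = None  # FASTA path
    reads: Optional[Sequence[str]] = None  # FASTQ paths (R1 [, R2])
    sam: Optional[str] = None  # pre-computed alignments instead of reads
    contigs: Optional[str] = None  # FASTA of assembled contigs
    topology_config: Optional[str] = None  # sidecar naming chromosome/topologies
    genome: Optional[Genome] = None
    read_objects: Optional[Sequence[Read]] = None
    contig_objects: Optional[Sequence[tuple[str, str]]] = None  # (id, sequence)
    sample_id: str = "sample"

    # mapping
    k: int = mapping.DEFAULT_K
    min_anchor: int = mapping.DEFAULT_MIN_ANCHOR
    max_mismatch_rate: float = mapping.DEFAULT_MAX_MISMATCH_RATE

    # census
    end_trim: int = census_mod.DEFAULT_END_TRIM
    min_depth: int = census_mod.DEFAULT_MIN_DEPTH
    present_breadth_min: float = census_mod.DEFAULT_PRESENT_BREADTH_MIN
    absent_breadth_max: float = census_mod.DEFAULT_ABSENT_BREADTH_MAX

    # topology
    min_run: int = topology.DEFAULT_MIN_RUN
    terminal_dip: int = topology.DEFAULT_TERMINAL_DIP
    terminal_window: int = topology.DEFAULT_TERMINAL_WINDOW
    max_junction_gap: int = topology.DEFAULT_MAX_JUNCTION_GAP
    tolerance: int = topology.DEFAULT_TOLERANCE
    min_evidence: int = topology.DEFAULT_MIN_EVIDENCE
    long_anchor: int = topology.DEFAULT_LONG_ANCHOR

    # tir
    tir_window: int = tir_mod.DEFAULT_WINDOW
    tir_min_len: int = tir_mod.DEFAULT_MIN_LEN
    tir_min_identity: float = tir_mod.DEFAULT_MIN_IDENTITY

    seed: int = 0
    outdir: Optional[str] = None

    def parameters(self) -> dict:
        """The full parameter record (reproducibility contract)."""
        d = {f.name: getattr(self, f.name) for f in dataclasses.fields(self)}
        for key in ("genome", "read_objects", "contig_objects"):
            d[key] = None if d[key] is None else "<in-memory>"
        if d["reads"] is not None:
            d["reads"] = list(d["reads"])
        return d


@dataclass
class StrainReport:
    sample_id: str
    census: pd.DataFrame
    call: Optional[CircularizationCall]
    boundaries: pd.DataFrame
    junctions: pd.DataFrame
    tir: pd.DataFrame
    warnings: list[str]
    parameters: dict
    genome_loss_percent: Optional[float] = None

    def summary(self) -> str:
        lines = [f"sample: {self.sample_id}", "", "replicon census:"]
        lines.append(self.census.to_string(index=False))
        lines.append("")
        if self.call is not None:
            c = self.call
            kb = topology.deletion_sizes_kb(c)
            lines.append(
                f"chromosome call: {c.status} (L={c.L}, R={c.R}; deletions "
                f"{c.left_deletion} bp / {c.right_deletion} bp = {kb[0]} kb / {kb[1]} kb; "
                f"junction evidence: {len(c.evidence)})"
            )
        else:
            lines.append("chromosome call: unavailable (no usable chromosome coverage)")
        if self.genome_loss_percent is not None:
            lines.append(f"genome lost vs parental reference: {self.genome_loss_percent:.2f} %")
        if len(self.tir):
            lines.append("")
            lines.append("terminal inverted repeats:")
            lines.append(self.tir.to_string(index=False))
        if self.warnings:
            lines.append("")
            lines.append("warnings:")
            lines.extend(f"  - {w}" for w in self.warnings)
        lines.append("")
        return "\n".join(lines)


def _load_inputs(config: RunConfig) -> tuple[Genome, list[Read], Optional[list[AlignmentSegment]], list[tuple[str, str]]]:
    chromosome_name, topo = None, {}
    if config.topology_config:
        chromosome_name, topo = io_mod.read_topology_config(config.topology_config)
    if config.genome is not None:
        genome = config.genome
    elif config.reference:
        genome = io_mod.read_fasta(config.reference, topo, chromosome_name)
    else:
        raise ValueError("RunConfig needs a reference FASTA or an in-memory genome")

    reads: list[Read] = []
    segments = None
    if config.read_objects is not None:
        reads = list(config.read_objects)
    elif config.reads:
        for path in config.reads:
            reads.extend(io_mod.read_fastq(path))
    elif config.sam:
        segments = io_mod.read_sam(config.sam, genome)
    else:
        raise ValueError("RunConfig needs reads (FASTQ), read objects or a SAM file")

    contigs: list[tuple[str, str]] = []
    if config.contig_objects is not None:
        contigs = list(config.contig_objects)
    elif config.contigs:
        cg = io_mod.read_fasta(config.contigs)
        contigs = [(r.name, r.sequence) for r in cg]
    return genome, reads, segments, contigs


def run_pipeline(config: RunConfig) -> StrainReport:
    """Execute the full per-strain analysis and (optionally) write outputs."""
    stage = "load_inputs"
    try:
        genome, reads, segments, contigs = _load_inputs(config)

        stage = "mapping"
        index = mapping.KmerIndex(genome, config.k)
        if segments is None:
            segments = mapping.map_reads(
                reads, genome, config.k, config.min_anchor,
                config.max_mismatch_rate, index,
            )
        for cid, cseq in contigs:
            segments.extend(
                mapping.map_query(
                    cseq, genome, config.k, config.min_anchor,
                    config.max_mismatch_rate, index, cid,
                )
            )

        stage = "coverage"
        by_rep: dict[str, list[AlignmentSegment]] = {r.name: [] for r in genome}
        n_ambiguous = 0
        for seg in segments:
            by_rep[seg.replicon].append(seg)
            if seg.ambiguous and seg.role == "primary":
                n_ambiguous += 1
        profiles = {
            name: mapping.compute_coverage(segs, genome[name])
            for name, segs in by_rep.items()
        }

        stage = "census"
        estimates = census_mod.copy_number(
            profiles, genome.chromosome_name, config.end_trim, config.min_depth,
            config.present_breadth_min, config.absent_breadth_max,
        )
        order = {n: i for i, n in enumerate(genome.names)}
        estimates.sort(key=lambda e: order[e.replicon])
        census_df = pd.DataFrame(
            {
                "replicon": [e.replicon for e in estimates],
                "mean_depth": [round(e.mean_depth, 3) for e in estimates],
                "ratio_vs_chromosome": [round(e.ratio_vs_chromosome, 4) for e in estimates],
                "breadth": [round(e.breadth, 5) for e in estimates],
                "status": [e.status for e in estimates],
            }
        )

        stage = "topology"
        warnings: list[str] = []
        if n_ambiguous:
            warnings.append(f"{n_ambiguous} reads with ambiguous (multi-mapping) placement")
        chrom = genome.chromosome
        call = None
        boundaries_rows = []
        junction_rows = []
        if chrom.is_linear:
            try:
                left_b = topology.detect_boundary(
                    profiles[chrom.name], "left", config.min_depth,
                    config.min_run, config.terminal_dip,
                )
                right_b = topology.detect_boundary(
                    profiles[chrom.name], "right", config.min_depth,
                    config.min_run, config.terminal_dip,
                )
                boundaries_rows = [
                    (chrom.name, b.end, b.position, round(b.support_depth, 2))
                    for b in (left_b, right_b)
                ]
                junctions = topology.find_junctions(
                    by_rep[chrom.name], chrom.name, chrom.length,
                    config.min_anchor, config.max_junction_gap, config.terminal_window,
                )
                junction_rows = [
                    (e.query_id, e.L, e.R, e.left_anchor_len, e.right_anchor_len, e.junction_gap)
                    for e in junctions
                ]
                call = topology.call_topology(
                    left_b, right_b, junctions, chrom.length,
                    config.tolerance, config.min_evidence, config.long_anchor,
                )
                warnings.extend(call.warnings)
                warnings.extend(
                    topology.coverage_peaks_beyond_boundary(
                        profiles[chrom.name], left_b, right_b
                    )
                )
            except topology.RepliconAbsentError as exc:
                warnings.append(str(exc))

        stage = "genome_loss"
        loss = None
        if call is not None:
            lost = [e.replicon for e in estimates if e.status == "absent"]
            loss = topology.genome_loss_fraction(genome, lost, call)

        stage = "tir"
        tir_rows = []
        for rep in genome:
            if not rep.is_linear or 2 * config.tir_window > rep.length:
                continue
            report = tir_mod.find_tir(
                rep, config.tir_window, config.tir_min_len, config.tir_min_identity
            )
            if report is not None:
                tir_rows.append(
                    (
                        rep.name, report.repeat_length, report.identity,
                        report.differences, f"{report.left_interval[0]}-{report.left_interval[1]}",
                        f"{report.right_interval[0]}-{report.right_interval[1]}",
                        report.left_offset, report.right_truncation,
                    )
                )
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    report = StrainReport(
        sample_id=config.sample_id,
        census=census_df,
        call=call,
        boundaries=pd.DataFrame(
            boundaries_rows, columns=["replicon", "end", "position", "support_depth"]
        ),
        junctions=pd.DataFrame(
            junction_rows,
            columns=["query_id", "L", "R", "left_anchor_len", "right_anchor_len", "junction_gap"],
        ),
        tir=pd.DataFrame(
            tir_rows,
            columns=[
                "replicon", "repeat_length", "identity", "differences",
                "left_interval", "right_interval", "left_offset", "right_truncation",
            ],
        ),
        warnings=warnings,
        parameters=config.parameters(),
        genome_loss_percent=loss,
    )

    if config.outdir:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        report.census.to_csv(outdir / "census.tsv", sep="\t", index=False)
        report.boundaries.to_csv(outdir / "boundaries.tsv", sep="\t", index=False)
        report.junctions.to_csv(outdir / "junctions.tsv", sep="\t", index=False)
        report.tir.to_csv(outdir / "tir.tsv", sep="\t", index=False)
        (outdir / "report.txt").write_text(report.summary())
        (outdir / "parameters.json").write_text(
            json.dumps(report.parameters, indent=2, sort_keys=True) + "\n"
        )
    return report
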