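"""End-to-end integration detection: reads + references in, calls out.

Wires the stages together: anchor indexing of host chromosomes and viral
circles, read mapping, fragment-level duplicate removal, chimera calling,
junction clustering, support filtering, microhomology measurement and
integration-call assembly.  Accepts paired FASTQ files or a name-sorted SAM
(for users who map with an external aligner first); either way the reads are
re-anchored internally so results are identical for identical sequences.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pysam

from . import junctions as jx
from . import microhomology as mh
from .seqcore import (CircularSegment, LinearSequence, SegmentedGenome,
                      read_fasta, revcomp)


@dataclass
class DetectionParams:
    """Thresholds of the detection pipeline.

    ``min_support`` (15 reads) is the survey's junction filter; the mapper
    settings (k, anchors, slack, clustering tolerance) are this package's
    own defaults and are all config-exposed.
    """

    k: int = 21
    min_anchor: int = 25
    max_unaligned: int = 10
    cluster_tol: int = 5
    min_support: int = 15
    max_mh: int = 100
    motif_windows: tuple[int, ...] = tuple(mh.DEFAULT_MOTIF_WINDOWS)
    dedup: bool = True
    max_pair_span: int | None = None


@dataclass
class DetectionResult:
    clusters_all: list[jx.JunctionCluster]
    clusters: list[jx.JunctionCluster]
    filtered_out: list[tuple[jx.JunctionCluster, str]]
    mh_calls: list[mh.MicrohomologyCall]
    calls: list[mh.IntegrationCall]
    summaries: list[mh.SegmentSummary]
    n_pairs: int = 0
    n_duplicates: int = 0
    n_chimeric: int = 0
    n_discordant: int = 0
    chimeric_reads: list[jx.ChimericRead] = field(default_factory=list)


def read_pairs_fastq(r1_path: str | Path, r2_path: str | Path,
                     ) -> Iterator[tuple[str, str, str]]:
    """Yield (name, read1, read2) from two synchronized FASTQ files."""
    with pysam.FastxFile(str(r1_path)) as f1, pysam.FastxFile(str(r2_path)) as f2:
        for e1, e2 in itertools.zip_longest(f1, f2):
            if e1 is None or e2 is None:
                raise ValueError("R1 and R2 have different read counts")
            yield e1.name, e1.sequence.upper(), e2.sequence.upper()


def read_pairs_sam(sam_path: str | Path) -> Iterator[tuple[str, str, str]]:
    """Yield read pairs from a name-sorted SAM.

    Sequences stored reverse-complemented by the aligner are restored to
    original read orientation; secondary and supplementary records are
    ignored, so the pipeline re-maps from raw sequence exactly as in FASTQ
    mode.
    """
    pending: dict[str, tuple[bool, str]] = {}
    with pysam.AlignmentFile(str(sam_path), "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_secondary or rec.is_supplementary or rec.query_sequence is None:
                continue
            seq = rec.query_sequence.upper()
            if rec.is_reverse:
                seq = revcomp(seq)
            first = not rec.is_paired or rec.is_read1
            prev = pending.pop(rec.query_name, None)
            if prev is None:
                pending[rec.query_name] = (first, seq)
            else:
                p_first, p_seq = prev
                r1, r2 = (seq, p_seq) if first and not p_first else (p_seq, seq)
                yield rec.query_name, r1, r2
    if pending:
        raise ValueError(f"{len(pending)} unpaired reads in SAM (name-sorted input "
                         "with both mates required)")


def _best_signature(runs: Sequence[jx.Run]) -> tuple | None:
    if not runs:
        return None
    r = max(runs, key=lambda r: (r.length, r.ref_id))
    return (r.ref_id, r.ref_start, r.strand)


def _full_viral(runs: Sequence[jx.Run], read_len: int) -> jx.Run | None:
    for r in runs:
        if r.circular and r.length >= 0.9 * read_len:
            return r
    return None


def detect(host: Sequence[LinearSequence], viral: SegmentedGenome,
           pairs: Iterable[tuple[str, str, str]],
           params: DetectionParams | None = None) -> DetectionResult:
    """Run the full detection pipeline over read pairs.

    ``pairs`` yields (name, read1, read2).  Duplicate fragments — identical
    best placements of both mates — are removed before support counting.
    Pairs with one mate fully viral and the other fully host are tallied as
    discordant-pair evidence but never contribute junction support.
    """
    params = params or DetectionParams()
    refs = list(host) + list(viral.segments)
    index = jx.AnchorIndex(refs, k=params.k)
    circle_lengths = {s.id: len(s) for s in viral}
    host_by_id = {h.id: h for h in host}

    chimeras: list[jx.ChimericRead] = []
    seen_frags: set[tuple] = set()
    seg_bases: dict[str, int] = {}
    n_pairs = n_dup = n_disc = 0

    for name, r1, r2 in pairs:
        n_pairs += 1
        runs1 = jx.map_read_fast(r1, index)
        runs2 = jx.map_read_fast(r2, index)
        if params.dedup:
            key = (_best_signature(runs1), _best_signature(runs2))
            if key != (None, None) and key in seen_frags:
                n_dup += 1
                continue
            seen_frags.add(key)
        fv1, fv2 = _full_viral(runs1, len(r1)), _full_viral(runs2, len(r2))
        fh1 = any(not r.circular and r.length >= 0.9 * len(r1) for r in runs1)
        fh2 = any(not r.circular and r.length >= 0.9 * len(r2) for r in runs2)
        if (fv1 and fh2) or (fv2 and fh1):
            n_disc += 1
        for mate, read, runs in (("1", r1, runs1), ("2", r2, runs2)):
            fv = fv1 if mate == "1" else fv2
            if fv is not None and fv.length == len(read):
                seg_bases[fv.ref_id] = seg_bases.get(fv.ref_id, 0) + fv.length
                continue
            chi = jx.call_chimeric(f"{name}/{mate}", runs, len(read),
                                   min_anchor=params.min_anchor,
                                   max_unaligned=params.max_unaligned,
                                   circle_lengths=circle_lengths)
            if chi is not None:
                chimeras.append(chi)
            elif fv is not None:
                seg_bases[fv.ref_id] = seg_bases.get(fv.ref_id, 0) + fv.length

    clusters_all = jx.cluster_junctions(chimeras, cluster_tol=params.cluster_tol)
    kept, removed = jx.filter_support(clusters_all, min_support=params.min_support)
    mh_calls = [mh.measure_microhomology(
        c, viral[c.segment_id], host_by_id[c.host_chrom],
        max_mh=params.max_mh, windows=params.motif_windows) for c in kept]
    depth = {sid: bases / len(viral[sid]) for sid, bases in seg_bases.items()}
    calls, summaries = mh.assemble_calls(mh_calls, viral,
                                         max_span=params.max_pair_span,
                                         segment_depth=depth)
    return DetectionResult(
        clusters_all=clusters_all, clusters=kept, filtered_out=removed,
        mh_calls=mh_calls, calls=calls, summaries=summaries,
        n_pairs=n_pairs, n_duplicates=n_dup, n_chimeric=len(chimeras),
        n_discordant=n_disc, chimeric_reads=chimeras)


def detect_files(host_fasta: str | Path, viral_fasta: str | Path,
                 r1: str | Path | None = None, r2: str | Path | None = None,
                 sam: str | Path | None = None,
                 params: DetectionParams | None = None) -> DetectionResult:
    """File-based entry point: FASTA references plus FASTQ pair or SAM."""
    host = read_fasta(host_fasta, "linear")
    viral = read_fasta(viral_fasta, "circular")
    if sam is not None:
        pairs = read_pairs_sam(sam)
    elif r1 is not None and r2 is not None:
        pairs = read_pairs_fastq(r1, r2)
    else:
        raise ValueError("provide either r1+r2 FASTQ paths or a SAM path")
    return detect(host, viral, pairs, params)


def write_junctions_tsv(result: DetectionResult, path: str | Path) -> None:
    """One row per junction cluster, kept and filtered, with filter reason."""
    mh_by_cluster = {id(m.cluster): m for m in result.mh_calls}
    with open(path, "w") as fh:
        fh.write("segment_id\thost_chrom\tside\thost_breakpoint\t"
                 "viral_breakpoint\trel_strand\tsupport\tmh_len\tstatus\treason\n")
        removed = {id(c): why for c, why in result.filtered_out}
        for c in result.clusters_all:
            m = mh_by_cluster.get(id(c))
            mh_len = str(m.mh_len) if m is not None else "."
            status, reason = ("kept", ".") if id(c) not in removed \
                else ("filtered", removed[id(c)])
            fh.write(f"{c.segment_id}\t{c.host_chrom}\t{c.side}\t"
                     f"{c.host_breakpoint}\t{c.viral_breakpoint}\t{c.rel_strand}\t"
                     f"{c.support}\t{mh_len}\t{status}\t{reason}\n")


def write_calls_tsv(result: DetectionResult, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("segment_id\thost_chrom\tleft_pos\tright_pos\tsupport\t"
                 "mh_len_left\tmh_len_right\tmh_len\tmotif_seq\tstatus\t"
                 "n_host_sites\n")
        for c in result.calls:
            fmt = lambda v: "." if v is None else str(v)
            fh.write(f"{c.segment_id}\t{c.host_chrom}\t{fmt(c.left_pos)}\t"
                     f"{fmt(c.right_pos)}\t{c.support}\t{fmt(c.mh_len_left)}\t"
                     f"{fmt(c.mh_len_right)}\t{c.mh_len}\t{c.motif_seq}\t"
                     f"{c.status}\t{c.n_host_sites}\n")


def write_segments_summary_tsv(result: DetectionResult, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("segment_id\tstatus\tn_host_sites\tn_junctions\tepisomal_depth\n")
        for s in result.summaries:
            fh.write(f"{s.segment_id}\t{s.status}\t{s.n_host_sites}\t"
                     f"{s.n_junctions}\t{s.episomal_depth:.2f}\n")


def write_motifs_fasta(result: DetectionResult, path: str | Path) -> None:
    """One record per junction motif (the maximal shared flank sequence)."""
    with open(path, "w") as fh:
        for i, m in enumerate(result.mh_calls):
            c = m.cluster
            if not m.mh_seq:
                continue
            fh.write(f">motif{i + 1:03d} {c.segment_id}:{c.host_chrom}:"
                     f"{c.host_breakpoint}:{c.side} mh_len={m.mh_len}\n")
            fh.write(m.mh_seq + "\n")


def write_reads_bed(result: DetectionResult, path: str | Path) -> None:
    """BED of chimeric read placements on the host (0-based half-open)."""
    with open(path, "w") as fh:
        for r in sorted(result.chimeric_reads,
                        key=lambda r: (r.host_chrom, r.host_interval, r.read_id)):
            s, e = r.host_interval
            fh.write(f"{r.host_chrom}\t{s}\t{e}\t{r.read_id}|{r.segment_id}\t"
                     f"{r.overlap_len}\t{r.host_strand}\n")
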