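"""Cross-genome comparison of two segmented circular genomes.

Related ichnovirus genomes (e.g. sister-species isolates) share most of
their circles at high nucleotide identity while each carries a handful of
genome-specific segments.  This module scores every segment pair of two
genomes: the best strand and rotation of the second circle are found by
shared k-mer voting on circular diagonals, the rotated pair is globally
aligned, and identity is matches over alignment columns (gaps included in
the denominator).  Qualifying links (identity and coverage thresholds) are
marked reciprocal-best, segments without any qualifying link are reported
genome-specific, and summary identity statistics are taken over the
reciprocal-best links.

Bit-compatibility with BLAST-style local alignment is not claimed; identity
is reported at alignment resolution and should be compared at integer
percent.
"""

from __future__ import annotations

import json
import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import edlib

from .seqcore import CircularSegment, SegmentedGenome, revcomp

_CIG = re.compile(r"(\d+)([=XIDM])")


@dataclass(frozen=True)
class SimilarityLink:
    seg_a: str
    seg_b: str
    percent_identity: float
    aligned_bp: int  # columns aligned base-to-base (matches + mismatches)
    coverage_of_shorter: float
    reciprocal_best: bool = False


@dataclass
class CompareReport:
    genome_a: str
    genome_b: str
    links: list[SimilarityLink]
    specific_a: list[str]
    specific_b: list[str]
    mean_identity: float
    min_identity: float
    max_identity: float
    n_reciprocal: int


def _kmer_positions(seq: str, k: int, cap: int = 8) -> dict[str, list[int]]:
    pos: dict[str, list[int]] = {}
    for i in range(len(seq) - k + 1):
        lst = pos.setdefault(seq[i:i + k], [])
        if len(lst) < cap:
            lst.append(i)
    return pos


def _vote_rotation(pos_a: dict[str, list[int]], bseq: str, k: int,
                   ) -> tuple[int, int]:
    """(total shared k-mer hits, best rotation of b) against a's k-mer map."""
    votes: Counter[int] = Counter()
    Lb = len(bseq)
    d = bseq + bseq[:k - 1]  # circular k-mers of b
    for j in range(Lb):
        for i in pos_a.get(d[j:j + k], ()):
            votes[(i - j) % Lb] += 1
    if not votes:
        return 0, 0
    best_delta, _ = max(votes.items(), key=lambda kv: (kv[1], -kv[0]))
    return sum(votes.values()), (-best_delta) % Lb


def _cigar_stats(cigar: str) -> tuple[int, int]:
    """(match columns, total columns) from an extended cigar."""
    matches = columns = 0
    for n, op in _CIG.findall(cigar):
        n = int(n)
        columns += n
        if op == "=":
            matches += n
    return matches, columns


def pairwise_identity(seg_a: CircularSegment, seg_b: CircularSegment,
                      k: int = 13) -> SimilarityLink:
    """Percent identity of two circles after strand/rotation search.

    The strand of ``seg_b`` maximizing the shared k-mer count is chosen, its
    rotation is set by the modal circular diagonal of the shared k-mers, and
    the rotated pair is globally aligned.  Identity = matches / alignment
    columns (gaps included); symmetric to 4 decimals because the pair is
    ordered canonically before alignment.  No shared k-mers at all yields
    identity 0 with zero aligned bases.
    """
    a, b = seg_a, seg_b
    swapped = (len(a), a.seq, a.id) > (len(b), b.seq, b.id)
    if swapped:
        a, b = b, a
    pos_a = _kmer_positions(a.seq + a.seq[:k - 1], k)
    n_fwd, rot_fwd = _vote_rotation(pos_a, b.seq, k)
    rc = revcomp(b.seq)
    n_rev, rot_rev = _vote_rotation(pos_a, rc, k)
    if n_fwd == 0 and n_rev == 0:
        return SimilarityLink(seg_a.id, seg_b.id, 0.0, 0, 0.0)
    if n_fwd >= n_rev:
        bseq, rot = b.seq, rot_fwd
    else:
        bseq, rot = rc, rot_rev
    b_rot = bseq[rot:] + bseq[:rot]
    res = edlib.align(a.seq, b_rot, mode="NW", task="path")
    matches, columns = _cigar_stats(res["cigar"])
    identity = round(100.0 * matches / columns, 4) if columns else 0.0
    # columns aligned base-to-base = columns minus all gap columns
    gaps = sum(int(n) for n, op in _CIG.findall(res["cigar"]) if op in "ID")
    aligned = columns - gaps
    shorter = min(len(seg_a), len(seg_b))
    return SimilarityLink(seg_a.id, seg_b.id, identity, aligned,
                          round(aligned / shorter, 4))


def compare_genomes(genome_a: SegmentedGenome, genome_b: SegmentedGenome,
                    min_identity: float = 70.0, min_coverage: float = 0.5,
                    k: int = 13, min_shared_kmers: int = 20) -> CompareReport:
    """All-vs-all segment comparison with reciprocal-best marking.

    A link qualifies when identity >= ``min_identity`` percent and it covers
    at least ``min_coverage`` of the shorter segment.  Segments of either
    genome without a qualifying link are genome-specific.  Pairs sharing
    fewer than ``min_shared_kmers`` k-mers are screened out without
    alignment (their identity is far below any qualifying threshold).
    """
    sets_a = {s.id: _kmer_set(s.seq, k) for s in genome_a}
    sets_b = {s.id: _kmer_set(s.seq, k) | _kmer_set(revcomp(s.seq), k)
              for s in genome_b}
    links: list[SimilarityLink] = []
    for sa in genome_a:
        for sb in genome_b:
            if len(sets_a[sa.id] & sets_b[sb.id]) < min_shared_kmers:
                continue
            links.append(pairwise_identity(sa, sb, k=k))

    def qualifies(l: SimilarityLink) -> bool:
        return l.percent_identity >= min_identity and l.coverage_of_shorter >= min_coverage

    best_a: dict[str, SimilarityLink] = {}
    best_b: dict[str, SimilarityLink] = {}
    for l in links:
        if not qualifies(l):
            continue
        key = (l.percent_identity, l.aligned_bp)
        if l.seg_a not in best_a or key > (best_a[l.seg_a].percent_identity,
                                           best_a[l.seg_a].aligned_bp):
            best_a[l.seg_a] = l
        if l.seg_b not in best_b or key > (best_b[l.seg_b].percent_identity,
                                           best_b[l.seg_b].aligned_bp):
            best_b[l.seg_b] = l
    reciprocal = {id(l) for l in best_a.values()} & {id(l) for l in best_b.values()}
    links = [SimilarityLink(l.seg_a, l.seg_b, l.percent_identity, l.aligned_bp,
                            l.coverage_of_shorter, id(l) in reciprocal)
             for l in links]
    linked_a = {l.seg_a for l in links if qualifies(l)}
    linked_b = {l.seg_b for l in links if qualifies(l)}
    specific_a = [s.id for s in genome_a if s.id not in linked_a]
    specific_b = [s.id for s in genome_b if s.id not in linked_b]
    rb = [l for l in links if l.reciprocal_best]
    idents = [l.percent_identity for l in rb]
    links.sort(key=lambda l: (l.seg_a, -l.percent_identity, l.seg_b))
    return CompareReport(
        genome_a=genome_a.name, genome_b=genome_b.name, links=links,
        specific_a=specific_a, specific_b=specific_b,
        mean_identity=round(sum(idents) / len(idents), 4) if idents else 0.0,
        min_identity=min(idents) if idents else 0.0,
        max_identity=max(idents) if idents else 0.0,
        n_reciprocal=len(rb))


def _kmer_set(seq: str, k: int) -> set[str]:
    d = seq + seq[:k - 1]
    return {d[i:i + k] for i in range(len(seq))}


_LINK_HEADER = "seg_a\tstart_a\tend_a\tseg_b\tstart_b\tend_b\tidentity"


def write_links(report: CompareReport, path: str | Path,
                genome_a: SegmentedGenome | None = None,
                genome_b: SegmentedGenome | None = None,
                qualifying_only: bool = True) -> None:
    """Ribbon-plot link table: seg_a start_a end_a seg_b start_b end_b identity.

    Spans are whole segments (alignment is global over the best rotation);
    ordering is deterministic.
    """
    len_a = {s.id: len(s) for s in genome_a} if genome_a else {}
    len_b = {s.id: len(s) for s in genome_b} if genome_b else {}
    with open(path, "w") as fh:
        fh.write(_LINK_HEADER + "\n")
        for l in report.links:
            if qualifying_only and not l.reciprocal_best:
                continue
            fh.write(f"{l.seg_a}\t0\t{len_a.get(l.seg_a, l.aligned_bp)}\t"
                     f"{l.seg_b}\t0\t{len_b.get(l.seg_b, l.aligned_bp)}\t"
                     f"{l.percent_identity:.4f}\n")


def parse_links(path: str | Path) -> list[tuple[str, int, int, str, int, int, float]]:
    out = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if header != _LINK_HEADER:
            raise ValueError(f"unexpected link-table header: {header!r}")
        for line in fh:
            f = line.rstrip("\n").split("\t")
            out.append((f[0], int(f[1]), int(f[2]), f[3], int(f[4]), int(f[5]),
                        float(f[6])))
    return out


def write_compare_report(report: CompareReport, tsv_path: str | Path,
                         json_path: str | Path | None = None) -> None:
    with open(tsv_path, "w") as fh:
        fh.write("seg_a\tseg_b\tpercent_identity\taligned_bp\t"
                 "coverage_of_shorter\treciprocal_best\n")
        for l in report.links:
            fh.write(f"{l.seg_a}\t{l.seg_b}\t{l.percent_identity:.4f}\t"
                     f"{l.aligned_bp}\t{l.coverage_of_shorter:.4f}\t"
                     f"{int(l.reciprocal_best)}\n")
    if json_path is not None:
        with open(json_path, "w") as fh:
            json.dump({
                "genome_a": report.genome_a, "genome_b": report.genome_b,
                "n_links": len(report.links),
                "n_reciprocal_best": report.n_reciprocal,
                "mean_identity": report.mean_identity,
                "min_identity": report.min_identity,
                "max_identity": report.max_identity,
                "specific_a": report.specific_a,
                "specific_b": report.specific_b,
            }, fh, indent=2)
            fh.write("\n")
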