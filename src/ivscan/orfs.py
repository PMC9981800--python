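"""Open-reading-frame prediction on circular segments, with duplicate trimming.

Circles are scanned in all six frames on the doubled sequence so that an ORF
spanning the arbitrary linearization origin is found exactly once.  Nested
starts (an ATG in-frame inside a longer ORF sharing its stop) report only the
longest ORF, matching common ORF-finder behaviour.  Cross-segment duplicate
ORFs — identical nucleotide sequences, or near-identical up to a small edit
fraction — are collapsed to one representative, mirroring how segmented-virus
annotations trim genes that recur on different circles.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import edlib
from Bio.Seq import Seq

from .seqcore import CircularSegment, revcomp

_STOPS = {"TAA", "TAG", "TGA"}


@dataclass(frozen=True)
class ORFRecord:
    """One predicted ORF on a circular segment.

    ``start``/``end`` are 0-based half-open forward-strand circle coordinates;
    ``end`` may be numerically smaller than ``start`` when the ORF wraps the
    origin.  ``aa_len`` counts residues excluding the stop; the nucleotide
    span is ``3 * (aa_len + 1)`` including the stop codon.
    """

    segment_id: str
    start: int
    end: int
    strand: str
    frame: int
    aa_len: int
    nt_seq: str

    @property
    def nt_len(self) -> int:
        return 3 * (self.aa_len + 1)

    @property
    def protein(self) -> str:
        return str(Seq(self.nt_seq[:-3]).translate())


_ALT_STARTS = {"ATG", "GTG", "TTG"}


def find_orfs(seg: CircularSegment, min_aa: int = 75,
              alternative_starts: bool = False) -> list[ORFRecord]:
    """All ORFs of at least ``min_aa`` residues on a circle, both strands.

    Scans the doubled sequence in three frames per strand; each ORF is
    reported once even when it spans the origin, and an ORF can never be
    longer than the circle.  Only the longest ORF per stop codon is reported
    (internal in-frame ATGs are suppressed).
    """
    if min_aa < 1:
        raise ValueError("min_aa must be >= 1")
    L = len(seg)
    starts = _ALT_STARTS if alternative_starts else {"ATG"}
    # keyed by (strand, circular stop position): nested ORFs share a stop,
    # and only the longest per stop survives — even across the origin
    out: dict[tuple[str, int], ORFRecord] = {}
    for strand in "+-":
        t = seg.seq if strand == "+" else revcomp(seg.seq)
        d = t + t
        for frame in range(3):
            first_atg = -1  # first start codon since the last in-frame stop
            for p in range(frame, len(d) - 2, 3):
                codon = d[p:p + 3]
                if codon in _STOPS:
                    if first_atg >= 0:
                        nt = p + 3 - first_atg
                        aa = nt // 3 - 1
                        if aa >= min_aa and nt <= L and first_atg < L:
                            key = (strand, (first_atg + nt) % L)
                            prev = out.get(key)
                            if prev is None or aa > prev.aa_len:
                                out[key] = _make_record(seg.id, strand, frame,
                                                        first_atg, nt, L, d)
                    first_atg = -1
                elif codon in starts and first_atg < 0:
                    first_atg = p
    return sorted(out.values(), key=lambda r: (r.start, r.strand))


def _make_record(seg_id: str, strand: str, frame: int, p: int, nt: int, L: int,
                 doubled: str) -> ORFRecord:
    seq = doubled[p:p + nt]
    if strand == "+":
        start = p % L
    else:
        # oriented position p on the reverse strand maps to forward
        # coordinates [L - p - nt, L - p) modulo L
        start = (L - (p % L) - nt) % L
    end = start + nt
    if end > L:
        end -= L
    return ORFRecord(segment_id=seg_id, start=start, end=end, strand=strand,
                     frame=frame, aa_len=nt // 3 - 1, nt_seq=seq)


@dataclass(frozen=True)
class TrimReport:
    kept: tuple[ORFRecord, ...]
    trimmed: tuple[tuple[ORFRecord, ORFRecord], ...]  # (removed, representative)


def trim_duplicate_orfs(orfs: Sequence[ORFRecord],
                        max_mismatch_frac: float = 0.02) -> TrimReport:
    """Collapse ORFs whose sequences are identical or nearly so.

    Two ORFs are duplicates when their nucleotide sequences are within an
    edit distance of ``max_mismatch_frac`` of the longer length.  One
    representative per duplicate group is kept: the longest ORF, ties broken
    by lexicographically smallest segment id, then start.  The report lists
    every removed ORF with its kept representative.
    """
    n = len(orfs)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    order = sorted(range(n), key=lambda i: len(orfs[i].nt_seq))
    for a_idx in range(n):
        i = order[a_idx]
        for b_idx in range(a_idx + 1, n):
            j = order[b_idx]
            la, lb = len(orfs[i].nt_seq), len(orfs[j].nt_seq)
            d_max = int(max_mismatch_frac * max(la, lb))
            if lb - la > d_max:
                break  # sorted by length: no later ORF can qualify
            res = edlib.align(orfs[i].nt_seq, orfs[j].nt_seq, mode="NW",
                              task="distance", k=d_max)
            if res["editDistance"] != -1:
                parent[find(i)] = find(j)

    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    kept: list[ORFRecord] = []
    trimmed: list[tuple[ORFRecord, ORFRecord]] = []
    for members in groups.values():
        rep = min(members, key=lambda i: (-orfs[i].aa_len, orfs[i].segment_id,
                                          orfs[i].start))
        kept.append(orfs[rep])
        for i in members:
            if i != rep:
                trimmed.append((orfs[i], orfs[rep]))
    kept.sort(key=lambda r: (r.segment_id, r.start))
    trimmed.sort(key=lambda p: (p[0].segment_id, p[0].start))
    return TrimReport(kept=tuple(kept), trimmed=tuple(trimmed))


def write_gff3(orfs: Sequence[ORFRecord], segment_lengths: dict[str, int],
               path: str | Path) -> None:
    """GFF3 of predicted ORFs (1-based inclusive coordinates).

    An ORF wrapping the circle origin is written as two CDS parts sharing one
    ``ID`` attribute.
    """
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for k, r in enumerate(sorted(orfs, key=lambda r: (r.segment_id, r.start))):
            L = segment_lengths[r.segment_id]
            oid = f"orf{k + 1:04d}"
            attrs = f"ID={oid};aa_len={r.aa_len}"
            stop = r.start + r.nt_len
            if stop <= L:
                fh.write(f"{r.segment_id}\tivscan\tCDS\t{r.start + 1}\t{stop}\t.\t"
                         f"{r.strand}\t0\t{attrs}\n")
            else:
                fh.write(f"{r.segment_id}\tivscan\tCDS\t{r.start + 1}\t{L}\t.\t"
                         f"{r.strand}\t0\t{attrs};part=1\n")
                fh.write(f"{r.segment_id}\tivscan\tCDS\t1\t{stop - L}\t.\t"
                         f"{r.strand}\t0\t{attrs};part=2\n")


def write_proteins(orfs: Sequence[ORFRecord], path: str | Path) -> None:
    """FASTA of predicted protein sequences (stop codon removed)."""
    with open(path, "w") as fh:
        for k, r in enumerate(sorted(orfs, key=lambda r: (r.segment_id, r.start))):
            fh.write(f">orf{k + 1:04d} {r.segment_id}:{r.start}-{r.end}({r.strand})\n")
            prot = r.protein
            for i in range(0, len(prot), 60):
                fh.write(prot[i:i + 60] + "\n")
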