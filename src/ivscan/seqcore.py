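"""Sequence data model for segmented circular viral genomes and linear host chromosomes.

Ichnovirus encapsidated genomes are collections of covalently closed DNA
circles whose deposited linearization point is arbitrary, so circle identity
and coordinate arithmetic must be rotation- and strand-aware.  This module
provides the two sequence types (:class:`LinearSequence`,
:class:`CircularSegment`), a genome container, standard FASTA I/O and the
summary statistics reported for segmented genomes (segment count, aggregate
size, GC content, segment-length quantiles).

Coordinates are 0-based, half-open everywhere.  On circles, positions are
taken modulo the segment length and an extraction window may wrap the origin.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from statistics import median as _median
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_VALID = set("ACGTN")


def revcomp(seq: str) -> str:
    """Reverse complement of an upper-case DNA string over {A,C,G,T,N}."""
    return seq.translate(_COMPLEMENT)[::-1]


def normalize_alphabet(seq: str) -> str:
    """Upper-case ``seq`` and replace any symbol outside {A,C,G,T,N} with N."""
    s = seq.upper()
    if set(s) <= _VALID:
        return s
    return "".join(c if c in _VALID else "N" for c in s)


@dataclass(frozen=True)
class LinearSequence:
    """A linear reference sequence (e.g. a host chromosome)."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if len(self.seq) < 1:
            raise ValueError(f"sequence {self.id!r} is empty")

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def topology(self) -> str:
        return "linear"


@dataclass(frozen=True)
class CircularSegment:
    """One circular viral genome segment.

    Two segments represent the same circle iff their canonical rotations are
    equal; the canonical form is the lexicographically smallest string over
    all rotations of the sequence and of its reverse complement.
    """

    id: str
    seq: str

    def __post_init__(self) -> None:
        if len(self.seq) < 1:
            raise ValueError(f"segment {self.id!r} is empty")

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def topology(self) -> str:
        return "circular"

    def canonical(self) -> str:
        return canonical_rotation(self)

    def same_circle(self, other: "CircularSegment") -> bool:
        return self.canonical() == other.canonical()


@dataclass
class SegmentedGenome:
    """An ordered collection of circular segments with unique ids."""

    name: str
    segments: list[CircularSegment] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [s.id for s in self.segments]
        if len(ids) != len(set(ids)):
            dup = next(i for i in ids if ids.count(i) > 1)
            raise ValueError(f"duplicate segment id {dup!r} in genome {self.name!r}")

    def __len__(self) -> int:
        return len(self.segments)

    def __iter__(self):
        return iter(self.segments)

    def __getitem__(self, seg_id: str) -> CircularSegment:
        for s in self.segments:
            if s.id == seg_id:
                return s
        raise KeyError(seg_id)

    @property
    def total_bp(self) -> int:
        return sum(len(s) for s in self.segments)


@dataclass(frozen=True)
class GenomeStats:
    n_segments: int
    total_bp: int
    gc_percent: float
    min_kb: float
    max_kb: float
    median_kb: float


def _least_rotation(s: str) -> int:
    """Booth's algorithm: index of the lexicographically least rotation of s."""
    d = s + s
    n = len(d)
    f = [-1] * n
    k = 0
    for j in range(1, n):
        sj = d[j]
        i = f[j - k - 1]
        while i != -1 and sj != d[k + i + 1]:
            if sj < d[k + i + 1]:
                k = j - i - 1
            i = f[i]
        if sj != d[k + i + 1]:
            if sj < d[k]:
                k = j
            f[j - k] = -1
        else:
            f[j - k] = i + 1
    return k


def canonical_rotation(seg: CircularSegment | str) -> str:
    """Lexicographic minimum over all rotations of a circle and of its reverse
    complement.  Idempotent; invariant under rotation and strand flip."""
    s = seg.seq if isinstance(seg, CircularSegment) else seg
    if not s:
        raise ValueError("cannot canonicalize an empty sequence")
    rc = revcomp(s)
    i = _least_rotation(s)
    j = _least_rotation(rc)
    fwd = s[i:] + s[:i]
    rev = rc[j:] + rc[:j]
    return min(fwd, rev)


def _round2(x: float) -> float:
    return float(Decimal(repr(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def genome_stats(genome: SegmentedGenome) -> GenomeStats:
    """Summary statistics of a segmented genome.

    GC percent is 100*(G+C)/(A+C+G+T) pooled over all segments; N bases are
    excluded from the denominator (an all-N segment contributes nothing, with
    a warning).  Kilobase values are rounded half-up to 2 decimals; the median
    is the middle order statistic (mean of the two middles for even counts).
    """
    if len(genome) == 0:
        raise ValueError("genome has no segments")
    gc = at = 0
    for seg in genome:
        g = seg.seq.count("G") + seg.seq.count("C")
        a = seg.seq.count("A") + seg.seq.count("T")
        if g + a == 0:
            warnings.warn(f"segment {seg.id} is all N; excluded from GC", stacklevel=2)
            continue
        gc += g
        at += a
    lengths_kb = [len(s) / 1000.0 for s in genome]
    return GenomeStats(
        n_segments=len(genome),
        total_bp=genome.total_bp,
        gc_percent=100.0 * gc / (gc + at) if gc + at else float("nan"),
        min_kb=_round2(min(lengths_kb)),
        max_kb=_round2(max(lengths_kb)),
        median_kb=_round2(_median(lengths_kb)),
    )


def fetch_extract(ref: LinearSequence | CircularSegment, start: int, end: int,
                  strand: str = "+") -> str:
    """Extract ``[start, end)`` from a reference, reverse-complemented for "-".

    On circles, coordinates are interpreted modulo the length and the window
    may wrap the origin (``end`` numerically <= ``start`` means the span
    crosses position 0).  On linear sequences out-of-range coordinates are an
    error.
    """
    if strand not in "+-":
        raise ValueError(f"strand must be + or -, got {strand!r}")
    n = len(ref)
    if ref.topology == "circular":
        span = end - start
        if span < 0:
            span %= n
        if span > n:
            raise ValueError(f"window of {span} bp exceeds circle length {n}")
        s = start % n
        doubled = ref.seq + ref.seq
        out = doubled[s:s + span]
    else:
        if not (0 <= start <= end <= n):
            raise ValueError(
                f"coordinates [{start}, {end}) out of range for linear "
                f"sequence {ref.id!r} of length {n}")
        out = ref.seq[start:end]
    return revcomp(out) if strand == "-" else out


def read_fasta(path: str | Path, topology: str = "linear"):
    """Read a multi-record FASTA.

    Returns a :class:`SegmentedGenome` for ``topology="circular"`` or a list
    of :class:`LinearSequence` for ``topology="linear"``.  Record ids are the
    first whitespace-delimited header token; input order is preserved;
    lowercase bases are upper-cased and non-ACGTN symbols become N.
    """
    if topology not in ("circular", "linear"):
        raise ValueError(f"topology must be 'circular' or 'linear', got {topology!r}")
    path = Path(path)
    records = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append((rec.id, normalize_alphabet(str(rec.seq))))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    if topology == "circular":
        return SegmentedGenome(name=path.stem,
                               segments=[CircularSegment(i, s) for i, s in records])
    return [LinearSequence(i, s) for i, s in records]


def write_fasta(records: Iterable[LinearSequence | CircularSegment] | SegmentedGenome,
                path: str | Path, width: int = 60) -> None:
    """Write records to FASTA wrapped at ``width`` columns."""
    recs = list(records)
    with open(path, "w") as fh:
        for r in recs:
            fh.write(f">{r.id}\n")
            for i in range(0, len(r.seq), width):
                fh.write(r.seq[i:i + width] + "\n")


def read_genbank(path: str | Path) -> SegmentedGenome | list[LinearSequence]:
    """Read a GenBank flat file, honouring the LOCUS circular flag.

    All records in the file must share one topology; circular records come
    back as a :class:`SegmentedGenome`.
    """
    path = Path(path)
    circ: list[CircularSegment] = []
    lin: list[LinearSequence] = []
    for rec in SeqIO.parse(str(path), "genbank"):
        seq = normalize_alphabet(str(rec.seq))
        if rec.annotations.get("topology") == "circular":
            circ.append(CircularSegment(rec.id, seq))
        else:
            lin.append(LinearSequence(rec.id, seq))
    if circ and lin:
        raise ValueError(f"{path} mixes circular and linear records")
    if circ:
        return SegmentedGenome(name=path.stem, segments=circ)
    if lin:
        return lin
    raise ValueError(f"no GenBank records in {path}")


def stats_report(stats: GenomeStats) -> str:
    """TSV report of genome summary statistics (GC rounded to an integer)."""
    header = "n_segments\ttotal_bp\tgc_percent\tmin_kb\tmax_kb\tmedian_kb"
    row = (f"{stats.n_segments}\t{stats.total_bp}\t"
           f"{int(Decimal(repr(stats.gc_percent)).quantize(0, rounding=ROUND_HALF_UP))}\t"
           f"{stats.min_kb:.2f}\t{stats.max_kb:.2f}\t{stats.median_kb:.2f}")
    return header + "\n" + row + "\n"
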