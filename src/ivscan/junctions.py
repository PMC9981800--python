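"""Chimeric-read detection between circular viral segments and host chromosomes.

A self-contained exact-match k-mer anchor mapper stands in for an external
aligner: references are indexed by 2-bit-encoded k-mers (circles on their
doubled sequence so anchors wrap the origin), reads are mapped to maximal
exact anchor runs, and a read whose best viral and best host runs sit on
opposite flanks is called chimeric.  The overlap of the two runs on the read
is the microhomology candidate — a homology arm present in both genomes maps
to both references, so the anchors overlap by exactly the shared region.

Chimeric reads are clustered per (segment, chromosome, junction side) by
single linkage on the host breakpoint, support-counted, and filtered at a
minimum supporting-read threshold (default 15 reads).

Side convention, reading the host forward strand: a "left" junction is a
host-to-viral transition (breakpoint at the end of the host anchor) and a
"right" junction is viral-to-host (breakpoint at the start of the host
anchor).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .seqcore import CircularSegment, LinearSequence, revcomp

_LUT = np.full(256, 255, dtype=np.uint8)
for _i, _c in enumerate(b"ACGT"):
    _LUT[_c] = _i


def encode_kmers(seq: str, k: int) -> np.ndarray:
    """2-bit k-mer codes for every window of ``seq``; -1 where a window
    contains a non-ACGT symbol."""
    arr = _LUT[np.frombuffer(seq.encode(), dtype=np.uint8)]
    n = len(arr) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    win = sliding_window_view(arr, k)
    powers = (4 ** np.arange(k - 1, -1, -1)).astype(np.int64)
    codes = win.astype(np.int64) @ powers
    bad = (win == 255).any(axis=1)
    if bad.any():
        codes[bad] = -1
    return codes


@dataclass
class _Ref:
    id: str
    seq: str
    circular: bool

    def __post_init__(self) -> None:
        self.length = len(self.seq)
        # circles are searched on the doubled string so runs cross the origin
        self.search = self.seq + self.seq if self.circular else self.seq


class AnchorIndex:
    """Exact k-mer index over a mixed set of circular and linear references.

    Circular references are indexed on their doubled sequence with offsets
    reported modulo the length; only the forward strand is stored, and
    queries probe both the read and its reverse complement.
    """

    def __init__(self, references: Sequence[LinearSequence | CircularSegment],
                 k: int = 21):
        if k % 2 == 0:
            raise ValueError("k must be odd")
        shortest = min(len(r) for r in references)
        if k > shortest:
            raise ValueError(f"k={k} exceeds the shortest reference ({shortest} bp)")
        self.k = k
        self.refs = [_Ref(r.id, r.seq, r.topology == "circular") for r in references]
        self._index: dict[int, int | list[int]] = {}
        for ri, ref in enumerate(self.refs):
            if ref.circular:
                codes = encode_kmers(ref.search[:ref.length + k - 1], k)
            else:
                codes = encode_kmers(ref.seq, k)
            idx = self._index
            for pos, code in enumerate(codes.tolist()):
                if code < 0:
                    continue
                packed = (ri << 32) | pos
                cur = idx.get(code)
                if cur is None:
                    idx[code] = packed
                elif isinstance(cur, int):
                    idx[code] = [cur, packed]
                else:
                    cur.append(packed)

    def lookup(self, code: int) -> list[tuple[int, int]]:
        """Hits for a k-mer code as (ref_index, offset) pairs."""
        cur = self._index.get(code)
        if cur is None:
            return []
        if isinstance(cur, int):
            return [(cur >> 32, cur & 0xFFFFFFFF)]
        return [(p >> 32, p & 0xFFFFFFFF) for p in cur]


@dataclass(frozen=True)
class Run:
    """A maximal exact anchor run of a read against one reference."""

    read_start: int
    read_end: int
    ref_id: str
    ref_start: int  # modulo length on circles; ref_end may exceed the length
    ref_end: int
    strand: str
    circular: bool

    @property
    def length(self) -> int:
        return self.read_end - self.read_start


_MAX_HITS = 64


def _oriented_runs(q: str, index: AnchorIndex, max_hits: int = _MAX_HITS,
                   ) -> list[tuple[int, int, int, int]]:
    """Maximal exact runs of oriented query ``q`` as (ref_idx, qs, qe, ps).

    A substitution splits a reference match into two runs on the same
    diagonal, so each (ref, diagonal) holds a list of read-disjoint runs.  On
    circles the diagonal is taken modulo the length, which merges the
    left-truncated image of an origin-crossing run with its full image on the
    doubled sequence (the longer run wins).
    """
    k = index.k
    codes = encode_kmers(q, k)
    runs: dict[tuple[int, int], list[tuple[int, int, int]]] = {}
    for i, code in enumerate(codes.tolist()):
        if code < 0:
            continue
        cur = index._index.get(code)
        if cur is None:
            continue
        hits = ([(cur >> 32, cur & 0xFFFFFFFF)] if isinstance(cur, int)
                else [(p >> 32, p & 0xFFFFFFFF) for p in cur[:max_hits]])
        for ri, p in hits:
            ref = index.refs[ri]
            diag = (p - i) % ref.length if ref.circular else p - i
            lst = runs.setdefault((ri, diag), [])
            if any(qs <= i and i + k <= qe for qs, qe, _ in lst):
                continue
            text = ref.search
            qs, ps = i, p
            while qs > 0 and ps > 0 and q[qs - 1] == text[ps - 1]:
                qs -= 1
                ps -= 1
            qe, pe = i + k, p + k
            nt, nq = len(text), len(q)
            while qe < nq and pe < nt and q[qe] == text[pe]:
                qe += 1
                pe += 1
            # drop read-overlapping runs on this diagonal (circular truncation
            # images); disjoint runs (substitution splits) are kept
            lst[:] = [r for r in lst if r[1] <= qs or r[0] >= qe]
            lst.append((qs, qe, ps))
    return [(ri, qs, qe, ps)
            for (ri, _d), lst in runs.items() for qs, qe, ps in lst]


def map_read(read: str, index: AnchorIndex) -> list[Run]:
    """Maximal exact anchor runs of a read on both strands of all references.

    Runs are sorted by read offset, ties broken by length (longest first)
    then reference id.  A read shorter than k maps nowhere.
    """
    n = len(read)
    if n < index.k:
        return []
    out: list[Run] = []
    for strand, q in (("+", read), ("-", revcomp(read))):
        for ri, qs, qe, ps in _oriented_runs(q, index):
            ref = index.refs[ri]
            rstart = ps % ref.length if ref.circular else ps
            run_len = qe - qs
            if strand == "+":
                rs, re = qs, qe
            else:
                rs, re = n - qe, n - qs
            out.append(Run(read_start=rs, read_end=re, ref_id=ref.id,
                           ref_start=rstart, ref_end=rstart + run_len,
                           strand=strand, circular=ref.circular))
    out.sort(key=lambda r: (r.read_start, -r.length, r.ref_id, r.strand))
    return out


def map_read_fast(read: str, index: AnchorIndex) -> list[Run]:
    """``map_read`` with a fast path for reads that match one reference
    end-to-end (the overwhelming majority in resequencing data)."""
    n = len(read)
    k = index.k
    if n < k:
        return []
    for strand, q in (("+", read), ("-", revcomp(read))):
        code = _encode_one(q[:k])
        if code < 0:
            continue
        for ri, p in index.lookup(code):
            ref = index.refs[ri]
            if ref.search[p:p + n] == q:
                rstart = p % ref.length if ref.circular else p
                return [Run(read_start=0, read_end=n, ref_id=ref.id,
                            ref_start=rstart, ref_end=rstart + n,
                            strand=strand, circular=ref.circular)]
    return map_read(read, index)


def _encode_one(kmer: str) -> int:
    code = 0
    for c in kmer:
        v = _LUT[ord(c)]
        if v == 255:
            return -1
        code = (code << 2) | int(v)
    return code


@dataclass(frozen=True)
class ChimericRead:
    """A read split between a viral circle and a host chromosome."""

    read_id: str
    segment_id: str
    viral_interval: tuple[int, int]
    viral_strand: str
    host_chrom: str
    host_interval: tuple[int, int]
    host_strand: str
    read_breakpoint: int
    overlap_len: int
    side: str  # "left" (host->viral) or "right" (viral->host), host forward
    host_breakpoint: int
    viral_breakpoint: int
    rel_strand: str  # viral strand relative to host forward at this junction


def call_chimeric(read_id: str, runs: Sequence[Run], read_len: int,
                  min_anchor: int = 25, max_unaligned: int = 10,
                  circle_lengths: dict[str, int] | None = None,
                  ) -> ChimericRead | None:
    """Call a read chimeric from its anchor runs, or return None.

    Requires the best viral and best host run to each span at least
    ``min_anchor`` bases, to sit on opposite flanks of the read (neither
    containing the other), and to jointly cover the read up to
    ``max_unaligned`` slack.  The overlap of the two runs on the read is the
    microhomology candidate.
    """
    viral = [r for r in runs if r.circular]
    host = [r for r in runs if not r.circular]
    if not viral or not host:
        return None
    bv = max(viral, key=lambda r: (r.length, r.ref_id))
    bh = max(host, key=lambda r: (r.length, r.ref_id))
    if bv.length < min_anchor or bh.length < min_anchor:
        return None
    sv, ev = bv.read_start, bv.read_end
    sh, eh = bh.read_start, bh.read_end
    if (sh <= sv and ev <= eh) or (sv <= sh and eh <= ev):
        return None  # containment: the read is explained by one reference
    if not ((sh < sv and eh < ev) or (sv < sh and ev < eh)):
        return None
    overlap = max(0, min(ev, eh) - max(sv, sh))
    union = (ev - sv) + (eh - sh) - overlap
    if union < read_len - max_unaligned:
        return None
    host_first = sh < sv
    b = eh if host_first else sh  # junction edge of the host anchor, read coords
    # host-side breakpoint in host forward coordinates
    if bh.strand == "+":
        h_bp = bh.ref_start + (b - sh)
    else:
        h_bp = bh.ref_end - (b - sh)
    side = "left" if (bh.strand == "+") == host_first else "right"
    # viral breakpoint: circle coordinate aligned to the same read edge
    if bv.strand == "+":
        v_bp = bv.ref_start + (b - sv)
    else:
        v_bp = bv.ref_end - (b - sv)
    if circle_lengths and bv.ref_id in circle_lengths:
        v_bp %= circle_lengths[bv.ref_id]
    return ChimericRead(
        read_id=read_id, segment_id=bv.ref_id,
        viral_interval=(bv.ref_start, bv.ref_end), viral_strand=bv.strand,
        host_chrom=bh.ref_id, host_interval=(bh.ref_start, bh.ref_end),
        host_strand=bh.strand, read_breakpoint=b, overlap_len=overlap,
        side=side, host_breakpoint=h_bp, viral_breakpoint=v_bp,
        rel_strand="+" if bv.strand == bh.strand else "-")


@dataclass
class JunctionCluster:
    """A support-counted junction: chimeric reads sharing segment, chromosome,
    side and (within tolerance) host breakpoint."""

    segment_id: str
    host_chrom: str
    side: str
    host_breakpoint: int
    viral_breakpoint: int
    rel_strand: str
    support: int
    read_ids: tuple[str, ...] = ()


def _median_low(values: list[int]) -> int:
    s = sorted(values)
    n = len(s)
    return s[(n - 1) // 2]  # lower middle: smallest coordinate wins ties


def cluster_junctions(reads: Iterable[ChimericRead],
                      cluster_tol: int = 5) -> list[JunctionCluster]:
    """Single-linkage clustering of chimeric reads on the host breakpoint
    within (segment, chromosome, side); consensus = median breakpoint."""
    groups: dict[tuple[str, str, str], list[ChimericRead]] = {}
    for r in reads:
        groups.setdefault((r.segment_id, r.host_chrom, r.side), []).append(r)
    clusters: list[JunctionCluster] = []
    for (seg, chrom, side), members in sorted(groups.items()):
        members.sort(key=lambda r: (r.host_breakpoint, r.read_id))
        block: list[ChimericRead] = []
        for r in members:
            if block and r.host_breakpoint - block[-1].host_breakpoint > cluster_tol:
                clusters.append(_finalize(seg, chrom, side, block))
                block = []
            block.append(r)
        if block:
            clusters.append(_finalize(seg, chrom, side, block))
    clusters.sort(key=lambda c: (c.host_chrom, c.host_breakpoint, c.segment_id, c.side))
    return clusters


def _finalize(seg: str, chrom: str, side: str,
              members: list[ChimericRead]) -> JunctionCluster:
    plus = sum(1 for m in members if m.rel_strand == "+")
    return JunctionCluster(
        segment_id=seg, host_chrom=chrom, side=side,
        host_breakpoint=_median_low([m.host_breakpoint for m in members]),
        viral_breakpoint=_median_low([m.viral_breakpoint for m in members]),
        rel_strand="+" if plus * 2 >= len(members) else "-",
        support=len(members),
        read_ids=tuple(m.read_id for m in members))


def filter_support(clusters: Sequence[JunctionCluster], min_support: int = 15,
                   ) -> tuple[list[JunctionCluster], list[tuple[JunctionCluster, str]]]:
    """Keep clusters with at least ``min_support`` reads; the second return
    value lists removed clusters with the reason."""
    kept, removed = [], []
    for c in clusters:
        if c.support >= min_support:
            kept.append(c)
        else:
            removed.append((c, f"support {c.support} < {min_support}"))
    return kept, removed
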