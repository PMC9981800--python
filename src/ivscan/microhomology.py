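"""Microhomology measurement at junction clusters and integration-call assembly.

At each junction the host flank and the viral flank share a stretch of
identical sequence — the homology arm that mediated the single-crossover
integration of the circle.  The measured microhomology is the maximal exact
match between the two flanks anchored at the consensus breakpoints, computed
on the junction's oriented strands with circular fetches on the viral side.
Fixed motif windows (10, 20 and 50 bp around the breakpoint) are also
scanned and reported for comparability with window-based breakpoint surveys,
though the maximal match supersedes them.

Left and right junction clusters for the same segment and chromosome are
then paired into :class:`IntegrationCall` records; an unpaired junction is
reported as a "partial" call, never dropped.  Segments without any surviving
junction are reported "not integrated", alongside their episomal read depth
(circles persist extrachromosomally, so depth without junctions is the
expected signature of a free segment).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .junctions import JunctionCluster
from .seqcore import CircularSegment, LinearSequence, SegmentedGenome, fetch_extract

DEFAULT_MOTIF_WINDOWS = (10, 20, 50)


@dataclass(frozen=True)
class MicrohomologyCall:
    """Maximal exact shared flank at one junction cluster.

    ``mh_seq`` is the shared string (host orientation); ``window_hits`` maps
    each motif window length to the longest exact common substring of the two
    windows centred on the breakpoint.  ``capped`` flags a breakpoint closer
    to a host contig end than the search limit.
    """

    cluster: JunctionCluster
    mh_len: int
    mh_seq: str
    window_hits: dict[int, int] = field(default_factory=dict)
    capped: bool = False


def _viral_bases(circle: CircularSegment, v_bp: int, lo: int, hi: int,
                 rel_strand: str) -> str:
    """Oriented circle bases on offsets [lo, hi) around the junction
    coordinate, in the frame where the junction reads like the host forward
    strand."""
    if rel_strand == "+":
        return fetch_extract(circle, v_bp + lo, v_bp + hi, "+")
    return fetch_extract(circle, v_bp - hi, v_bp - lo, "-")


def _longest_common_substring(a: str, b: str) -> int:
    if not a or not b:
        return 0
    best = 0
    subs: set[str] = set()
    for ln in range(len(a), 0, -1):
        subs = {a[i:i + ln] for i in range(len(a) - ln + 1)}
        if any(b[j:j + ln] in subs for j in range(len(b) - ln + 1)):
            return ln
    return best


def measure_microhomology(cluster: JunctionCluster, viral_seg: CircularSegment,
                          host_seq: LinearSequence, max_mh: int = 100,
                          windows: Sequence[int] = DEFAULT_MOTIF_WINDOWS,
                          ) -> MicrohomologyCall:
    """Maximal exact match between host and viral flanks at a junction.

    For a left junction (host-to-viral) the match is the largest L such that
    the L host bases ending at the host breakpoint equal the L oriented
    circle bases ending at the viral breakpoint; for a right junction the
    flanks start at the breakpoints instead.  L is capped at ``max_mh`` and
    at the distance to the host contig end (flagged ``capped``).
    """
    h_bp = cluster.host_breakpoint
    v_bp = cluster.viral_breakpoint
    rel = cluster.rel_strand
    n = len(host_seq)
    limit = min(max_mh, len(viral_seg))
    capped = False
    if cluster.side == "left":
        if h_bp < limit:
            limit, capped = h_bp, True

        def host_bases(L: int) -> str:
            return host_seq.seq[h_bp - L:h_bp]

        def viral(L: int) -> str:
            return _viral_bases(viral_seg, v_bp, -L, 0, rel)
    else:
        if n - h_bp < limit:
            limit, capped = n - h_bp, True

        def host_bases(L: int) -> str:
            return host_seq.seq[h_bp:h_bp + L]

        def viral(L: int) -> str:
            return _viral_bases(viral_seg, v_bp, 0, L, rel)

    mh_len, mh_seq = 0, ""
    for L in range(limit, 0, -1):
        h = host_bases(L)
        if h == viral(L):
            mh_len, mh_seq = L, h
            break

    hits: dict[int, int] = {}
    for w in windows:
        half = w // 2
        lo = max(0, h_bp - half)
        host_win = host_seq.seq[lo:min(n, lo + w)]
        viral_win = _viral_bases(viral_seg, v_bp, -half, -half + w, rel)
        hits[w] = _longest_common_substring(host_win, viral_win)
    return MicrohomologyCall(cluster=cluster, mh_len=mh_len, mh_seq=mh_seq,
                             window_hits=hits, capped=capped)


@dataclass(frozen=True)
class IntegrationCall:
    """One reported integration locus of a viral segment in the host genome."""

    segment_id: str
    host_chrom: str
    left_pos: int | None
    right_pos: int | None
    support: int
    mh_len_left: int | None
    mh_len_right: int | None
    motif_seq: str
    status: str  # "full" or "partial"
    n_host_sites: int = 1

    @property
    def mh_len(self) -> int:
        """Consensus microhomology length: the junctions agree in clean data;
        the maximum is reported when only one side survived filtering."""
        return max(v for v in (self.mh_len_left, self.mh_len_right)
                   if v is not None)


@dataclass(frozen=True)
class SegmentSummary:
    segment_id: str
    status: str  # "integrated" or "not integrated"
    n_host_sites: int
    n_junctions: int
    episomal_depth: float


def assemble_calls(mh_calls: Sequence[MicrohomologyCall],
                   viral: SegmentedGenome,
                   max_span: int | None = None,
                   segment_depth: Mapping[str, float] | None = None,
                   ) -> tuple[list[IntegrationCall], list[SegmentSummary]]:
    """Pair left/right junctions into per-locus integration calls.

    A left and a right junction of the same segment on the same chromosome
    within ``max_span`` (default: segment length plus 200 bp) form one locus;
    unpaired junctions become "partial" calls.  Per-segment host-site counts
    and a summary row for every viral segment (including the non-integrated
    ones, with their episomal depth) are returned alongside the calls.
    """
    depth = dict(segment_depth or {})
    by_locus: dict[tuple[str, str], list[MicrohomologyCall]] = {}
    for m in mh_calls:
        key = (m.cluster.segment_id, m.cluster.host_chrom)
        by_locus.setdefault(key, []).append(m)

    calls: list[IntegrationCall] = []
    for (seg_id, chrom), group in sorted(by_locus.items()):
        span = max_span if max_span is not None else len(viral[seg_id]) + 200
        lefts = sorted((m for m in group if m.cluster.side == "left"),
                       key=lambda m: m.cluster.host_breakpoint)
        rights = sorted((m for m in group if m.cluster.side == "right"),
                        key=lambda m: m.cluster.host_breakpoint)
        used: set[int] = set()
        for lm in lefts:
            best_j, best_d = None, None
            for j, rm in enumerate(rights):
                if j in used:
                    continue
                d = abs(lm.cluster.host_breakpoint - rm.cluster.host_breakpoint)
                if d <= span and (best_d is None or d < best_d):
                    best_j, best_d = j, d
            if best_j is not None:
                used.add(best_j)
                rm = rights[best_j]
                calls.append(IntegrationCall(
                    segment_id=seg_id, host_chrom=chrom,
                    left_pos=lm.cluster.host_breakpoint,
                    right_pos=rm.cluster.host_breakpoint,
                    support=lm.cluster.support + rm.cluster.support,
                    mh_len_left=lm.mh_len, mh_len_right=rm.mh_len,
                    motif_seq=max(lm.mh_seq, rm.mh_seq, key=len),
                    status="full"))
            else:
                calls.append(_partial(seg_id, chrom, lm))
        for j, rm in enumerate(rights):
            if j not in used:
                calls.append(_partial(seg_id, chrom, rm))

    site_counts: dict[str, int] = {}
    for c in calls:
        site_counts[c.segment_id] = site_counts.get(c.segment_id, 0) + 1
    calls = [IntegrationCall(**{**c.__dict__, "n_host_sites":
                                site_counts[c.segment_id]}) for c in calls]
    calls.sort(key=lambda c: (c.segment_id, c.host_chrom,
                              c.left_pos if c.left_pos is not None else c.right_pos))

    n_junctions: dict[str, int] = {}
    for m in mh_calls:
        sid = m.cluster.segment_id
        n_junctions[sid] = n_junctions.get(sid, 0) + 1
    summaries = [SegmentSummary(
        segment_id=s.id,
        status="integrated" if site_counts.get(s.id) else "not integrated",
        n_host_sites=site_counts.get(s.id, 0),
        n_junctions=n_junctions.get(s.id, 0),
        episomal_depth=round(depth.get(s.id, 0.0), 2)) for s in viral]
    return calls, summaries


def _partial(seg_id: str, chrom: str, m: MicrohomologyCall) -> IntegrationCall:
    left = m.cluster.side == "left"
    return IntegrationCall(
        segment_id=seg_id, host_chrom=chrom,
        left_pos=m.cluster.host_breakpoint if left else None,
        right_pos=None if left else m.cluster.host_breakpoint,
        support=m.cluster.support,
        mh_len_left=m.mh_len if left else None,
        mh_len_right=None if left else m.mh_len,
        motif_seq=m.mh_seq, status="partial")
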