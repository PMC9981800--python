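"""Synthetic parasitized-host sequencing datasets with a known integration truth table.

The generator emulates the data a circle-integration survey consumes:

* a multi-chromosome lepidopteran-style host genome (random sequence, GC ~0.40);
* a segmented circular ichnovirus-style genome (default 62 circles of
  1.5-8.2 kb, GC ~0.43) carrying a gene-family census of ORF-shaped,
  stop-free coding intervals and one unique 60-mer barcode per segment;
* Campbell-style single-crossover integrations of chosen circles into the
  host: a homology arm (default 36-46 bp) is planted in both the circle and
  the host locus, then the circle is opened at the arm and inserted so the
  arm is duplicated at the two junctions;
* paired-end reads drawn from the parasitized chromosomes plus the free
  (episomal) circles, with i.i.d. substitution errors.

Every event is recorded in an :class:`IntegrationTruth` row so detection
output can be scored exactly.  All randomness flows through one
``numpy.random.Generator`` seeded from the config, and every output file is
byte-identical across runs with the same config.

Arm flanks are guarded: the bases immediately adjacent to each planted arm
copy differ between host and circle, so the maximal exact shared region at a
junction equals the planted arm exactly.  Without the guard, one-in-four
junctions would extend the shared region by chance, and measured
microhomology lengths would no longer reproduce the planted arm-length
distribution.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from .seqcore import (CircularSegment, LinearSequence, SegmentedGenome,
                      revcomp, write_fasta)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_STOPS = {"TAA", "TAG", "TGA"}
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: Gene-family census used to label planted ORFs (123 genes total).
DEFAULT_CENSUS: dict[str, int] = {
    "rep": 41,
    "cys": 10,
    "vankyrin": 9,
    "prrp": 7,
    "vinnexin": 6,
    "n_gene": 3,
    "neuromodulin": 2,
    "hypothetical": 45,
}

# Rough protein-size regimes per family (aa), used only to shape planted ORFs.
_FAMILY_AA_RANGE: dict[str, tuple[int, int]] = {
    "rep": (120, 250),
    "cys": (90, 160),
    "vankyrin": (140, 200),
    "prrp": (180, 300),
    "vinnexin": (300, 400),
    "n_gene": (80, 130),
    "neuromodulin": (180, 260),
    "hypothetical": (80, 200),
}

_SEGMENT_GROUPS = [("A", 5), ("B", 9), ("C", 15), ("D", 23), ("E", 7), ("F", 3)]


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic dataset.

    Defaults encode the surveyed system: a ~1 Mb five-chromosome host, a
    62-segment circular viral genome with segment lengths in [1500, 8200] bp
    at 43% GC, three integrated segments, homology arms uniform on [36, 46]
    bp, 30x coverage of 150 bp paired reads.
    """

    seed: int = 0
    n_host_chroms: int = 5
    host_chrom_bp: int = 200_000
    host_gc: float = 0.40
    n_segments: int = 62
    segment_len_range: tuple[int, int] = (1500, 8200)
    target_gc: float = 0.43
    integrated_segment_ids: Sequence[str] | None = None  # None -> 3 drawn at random
    sites_per_segment: int | Mapping[str, int] = 1
    arm_len_range: tuple[int, int] = (36, 46)
    orientation_random: bool = True
    coverage: float = 30.0
    read_len: int = 150
    fragment_mean: float = 400.0
    fragment_sd: float = 40.0
    error_rate: float = 0.002
    indel_rate: float = 0.0  # off by default; 1 bp indels when > 0
    episome_ratio: float = 1.0  # fold-coverage of free circles relative to host

    def validate(self) -> None:
        if self.n_host_chroms < 1 or self.host_chrom_bp < 1000:
            raise ValueError("host must have >=1 chromosome of >=1 kb")
        lo, hi = self.segment_len_range
        if not (0 < lo <= hi):
            raise ValueError("segment_len_range must be a non-empty range")
        a_lo, a_hi = self.arm_len_range
        if not (1 <= a_lo <= a_hi <= self.read_len - 20):
            raise ValueError(
                f"arm_len_range must lie in [1, read_len-20]={self.read_len - 20} "
                "so junctions are detectable within a read")
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")
        if not (0 <= self.error_rate < 0.5):
            raise ValueError("error_rate must be in [0, 0.5)")

    def rng(self, stage: int | None = None) -> np.random.Generator:
        # stage-tagged streams keep standalone stage calls statistically
        # independent; simulate_dataset threads one master stream instead
        if stage is None:
            return np.random.default_rng(self.seed)
        return np.random.default_rng([self.seed, stage])


@dataclass(frozen=True)
class IntegrationTruth:
    """One planted integration event.

    ``arm_start``/``arm_len`` locate the host copy of the homology arm in the
    emitted (pre-integration) ``host.fasta`` coordinates.  The two junction
    breakpoints that detection should recover are ``left_junction_pos`` (the
    host->viral transition, at the arm end) and ``right_junction_pos`` (the
    viral->host transition, at the arm start).  ``viral_breakpoint`` is the
    arm start in the stored (emitted) circle coordinates.
    """

    segment_id: str
    host_chrom: str
    arm_start: int
    arm_len: int
    arm_seq: str
    viral_breakpoint: int
    orientation: str  # "+" or "-"

    @property
    def left_junction_pos(self) -> int:
        return self.arm_start + self.arm_len

    @property
    def right_junction_pos(self) -> int:
        return self.arm_start


@dataclass
class GeneAnnotation:
    segment_id: str
    start: int
    end: int
    strand: str
    family: str
    name: str


def random_dna(rng: np.random.Generator, n: int, gc: float) -> str:
    """Random DNA of length ``n`` with i.i.d. per-base GC fraction ``gc``."""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    idx = rng.choice(4, size=n, p=p)
    return _BASES[idx].tobytes().decode()


def make_host(cfg: GeneratorConfig,
              rng: np.random.Generator | None = None) -> list[LinearSequence]:
    """Host chromosomes: i.i.d. sequence at the configured GC."""
    cfg.validate()
    rng = rng if rng is not None else cfg.rng(stage=0)
    return [LinearSequence(f"chr{i + 1}", random_dna(rng, cfg.host_chrom_bp, cfg.host_gc))
            for i in range(cfg.n_host_chroms)]


def default_segment_ids(n: int) -> list[str]:
    """Segment labels; the canonical lettered groups when n matches them."""
    if n == sum(k for _, k in _SEGMENT_GROUPS):
        return [f"{g}{i + 1}" for g, k in _SEGMENT_GROUPS for i in range(k)]
    return [f"seg{i + 1:03d}" for i in range(n)]


def _random_orf(rng: np.random.Generator, aa_len: int, gc: float) -> str:
    """ATG + ``aa_len - 1`` stop-free codons + a stop codon."""
    codons = ["ATG"]
    while len(codons) < aa_len:
        c = random_dna(rng, 3, gc)
        if c in _STOPS:
            continue
        codons.append(c)
    stop = ["TAA", "TAG", "TGA"][int(rng.integers(0, 3))]
    return "".join(codons) + stop


def _scaled_census(cfg: GeneratorConfig) -> dict[str, int]:
    """Default census scaled to genome capacity.

    The full 123-gene census presumes the default ~300 kb genome; smaller
    synthetic genomes get proportionally fewer genes per family so placement
    stays feasible.  At the default dimensions the census is unchanged.
    """
    lo, hi = cfg.segment_len_range
    expected_bp = cfg.n_segments * (lo + hi) / 2
    factor = min(1.0, expected_bp / 300_000.0)
    return {fam: round(c * factor) for fam, c in DEFAULT_CENSUS.items()
            if round(c * factor) > 0}


def make_viral_genome(cfg: GeneratorConfig,
                      census: Mapping[str, int] | None = None,
                      rng: np.random.Generator | None = None,
                      ) -> tuple[SegmentedGenome, list[GeneAnnotation]]:
    """Segmented circular viral genome plus its planted gene annotation.

    Segment lengths are uniform over ``segment_len_range``; each segment
    carries a unique 60-mer barcode; census genes are written in as
    non-overlapping ORF-shaped intervals (ATG start, stop-free body, stop
    codon), on either strand, never wrapping the origin.
    """
    cfg.validate()
    rng = rng if rng is not None else cfg.rng(stage=1)
    if census is None:
        census = _scaled_census(cfg)
    census = dict(census)
    lo, hi = cfg.segment_len_range
    ids = default_segment_ids(cfg.n_segments)
    lengths = rng.integers(lo, hi + 1, size=cfg.n_segments)
    seqs = [bytearray(random_dna(rng, int(L), cfg.target_gc), "ascii") for L in lengths]

    # one unique 60-mer barcode per segment, placed at a random offset
    occupied: list[list[tuple[int, int]]] = [[] for _ in seqs]
    barcodes: set[str] = set()
    for i, s in enumerate(seqs):
        while True:
            bc = random_dna(rng, 60, cfg.target_gc)
            if bc not in barcodes and revcomp(bc) not in barcodes:
                barcodes.add(bc)
                break
        p = int(rng.integers(0, len(s) - 60))
        s[p:p + 60] = bc.encode()
        occupied[i].append((p, p + 60))

    genes: list[tuple[str, str]] = []  # (family, name)
    for fam in sorted(census):
        for j in range(census[fam]):
            genes.append((fam, f"{fam}{j + 1}"))
    order = rng.permutation(len(genes))

    annotations: list[GeneAnnotation] = []
    weights = lengths / lengths.sum()
    for gi in order:
        fam, name = genes[gi]
        aa_lo, aa_hi = _FAMILY_AA_RANGE.get(fam, (80, 200))
        aa = int(rng.integers(aa_lo, aa_hi + 1))
        orf = _random_orf(rng, aa, cfg.target_gc)
        placed = False
        for _attempt in range(300):
            si = int(rng.choice(cfg.n_segments, p=weights))
            L = len(seqs[si])
            if L < len(orf) + 2:
                continue
            start = int(rng.integers(0, L - len(orf)))
            end = start + len(orf)
            if any(start < e and s < end for s, e in occupied[si]):
                continue
            strand = "+" if rng.random() < 0.5 else "-"
            seqs[si][start:end] = (orf if strand == "+" else revcomp(orf)).encode()
            occupied[si].append((start, end))
            annotations.append(GeneAnnotation(ids[si], start, end, strand, fam, name))
            placed = True
            break
        if not placed:
            raise ValueError(
                f"could not place gene {name} ({len(orf)} bp) without overlap; "
                "increase segment lengths or count")
    annotations.sort(key=lambda a: (a.segment_id, a.start))
    genome = SegmentedGenome(
        name="viral",
        segments=[CircularSegment(i, bytes(s).decode()) for i, s in zip(ids, seqs)])
    return genome, annotations


def _occurs(needle: str, haystacks: Sequence[str]) -> bool:
    rc = revcomp(needle)
    return any(needle in h or rc in h for h in haystacks)


def plant_integrations(host: Sequence[LinearSequence], viral: SegmentedGenome,
                       cfg: GeneratorConfig, rng: np.random.Generator | None = None,
                       ) -> tuple[list[LinearSequence], SegmentedGenome,
                                  list[LinearSequence], list[IntegrationTruth]]:
    """Plant Campbell-style integrations; returns references and truth.

    Returns ``(host_ref, viral_ref, parasitized, truth)`` where ``host_ref``
    and ``viral_ref`` are the input genomes with the homology arms written in
    (each arm inserted once into the target circle and once into the host
    locus, flanked by guard-mismatched bases), and ``parasitized`` is
    ``host_ref`` with each arm occurrence replaced by
    ``arm + opened_circle_minus_arm + arm`` (single crossover, arm duplicated
    at both junctions).  Truth coordinates refer to ``host_ref``/``viral_ref``.
    """
    cfg.validate()
    rng = rng if rng is not None else cfg.rng(stage=2)
    a_lo, a_hi = cfg.arm_len_range

    if cfg.integrated_segment_ids is None:
        n_pick = min(3, len(viral))
        idx = rng.choice(len(viral), size=n_pick, replace=False)
        chosen = [viral.segments[int(i)].id for i in sorted(idx)]
    else:
        chosen = list(cfg.integrated_segment_ids)
        for cid in chosen:
            viral[cid]  # raises KeyError if absent
    sites = cfg.sites_per_segment
    n_sites = {cid: (sites[cid] if isinstance(sites, Mapping) and cid in sites
                     else sites if isinstance(sites, int) else 1)
               for cid in chosen}

    host_seqs = {h.id: h.seq for h in host}
    viral_seqs = {s.id: s.seq for s in viral}
    margin = max(1000, int(2 * cfg.fragment_mean))
    min_sep = 2000

    # planned per-event records before any coordinate shifting
    events = []  # dicts: seg, chrom, hpos (pre-insert), vpos (pre-insert), arm, orient
    host_positions: dict[str, list[int]] = {h.id: [] for h in host}
    viral_positions: dict[str, list[int]] = {s.id: [] for s in viral}
    chrom_ids = [h.id for h in host]
    chrom_w = np.array([len(host_seqs[c]) for c in chrom_ids], dtype=float)
    chrom_w /= chrom_w.sum()

    for seg_id in chosen:
        seg_seq = viral_seqs[seg_id]
        if a_hi > len(seg_seq) / 10:
            raise ValueError(
                f"arm length {a_hi} exceeds a tenth of segment {seg_id} "
                f"({len(seg_seq)} bp)")
        for _site in range(n_sites[seg_id]):
            arm_len = int(rng.integers(a_lo, a_hi + 1))
            for _try in range(200):
                arm = random_dna(rng, arm_len, cfg.host_gc)
                if _occurs(arm, list(host_seqs.values()) + list(viral_seqs.values())):
                    continue  # uniqueness guard: redraw
                vpos = int(rng.integers(100, len(seg_seq) - 100))
                if any(abs(vpos - p) < 150 for p in viral_positions[seg_id]):
                    continue
                chrom = chrom_ids[int(rng.choice(len(chrom_ids), p=chrom_w))]
                hseq = host_seqs[chrom]
                hpos = int(rng.integers(margin, len(hseq) - margin))
                if any(abs(hpos - p) < min_sep for p in host_positions[chrom]):
                    continue
                orient = ("+" if (not cfg.orientation_random or rng.random() < 0.5)
                          else "-")
                # flank guard: the base on either side of the arm must differ
                # between host and oriented circle, so the maximal shared
                # region at each junction is exactly the arm
                if orient == "+":
                    v_left, v_right = seg_seq[vpos - 1], seg_seq[vpos]
                else:
                    v_left, v_right = _COMP[seg_seq[vpos]], _COMP[seg_seq[vpos - 1]]
                if hseq[hpos - 1] == v_left or hseq[hpos] == v_right:
                    continue
                host_positions[chrom].append(hpos)
                viral_positions[seg_id].append(vpos)
                events.append(dict(seg=seg_id, chrom=chrom, hpos=hpos, vpos=vpos,
                                   arm=arm, orient=orient))
                break
            else:
                raise RuntimeError(
                    "failed to place an integration event after 200 attempts")

    # write arms into the circles (ascending, tracking the shift)
    viral_mod: dict[str, str] = dict(viral_seqs)
    viral_arm_at: dict[tuple[str, int], int] = {}  # (seg, pre-insert vpos) -> final pos
    for seg_id in viral_seqs:
        evs = sorted([e for e in events if e["seg"] == seg_id], key=lambda e: e["vpos"])
        if not evs:
            continue
        s = viral_seqs[seg_id]
        parts, prev, shift = [], 0, 0
        for e in evs:
            ins = e["arm"] if e["orient"] == "+" else revcomp(e["arm"])
            parts.append(s[prev:e["vpos"]])
            viral_arm_at[(seg_id, e["vpos"])] = e["vpos"] + shift
            parts.append(ins)
            shift += len(ins)
            prev = e["vpos"]
        parts.append(s[prev:])
        viral_mod[seg_id] = "".join(parts)

    # write arms into the host (ascending, tracking the shift)
    host_mod: dict[str, str] = dict(host_seqs)
    host_arm_at: dict[tuple[str, int], int] = {}
    for chrom in host_seqs:
        evs = sorted([e for e in events if e["chrom"] == chrom], key=lambda e: e["hpos"])
        if not evs:
            continue
        s = host_seqs[chrom]
        parts, prev, shift = [], 0, 0
        for e in evs:
            parts.append(s[prev:e["hpos"]])
            host_arm_at[(chrom, e["hpos"])] = e["hpos"] + shift
            parts.append(e["arm"])
            shift += len(e["arm"])
            prev = e["hpos"]
        parts.append(s[prev:])
        host_mod[chrom] = "".join(parts)

    truth: list[IntegrationTruth] = []
    for e in events:
        truth.append(IntegrationTruth(
            segment_id=e["seg"], host_chrom=e["chrom"],
            arm_start=host_arm_at[(e["chrom"], e["hpos"])], arm_len=len(e["arm"]),
            arm_seq=e["arm"],
            viral_breakpoint=viral_arm_at[(e["seg"], e["vpos"])],
            orientation=e["orient"]))

    # integrate: replace each host arm copy with arm + opened circle + arm
    para: dict[str, str] = dict(host_mod)
    for chrom in host_mod:
        rows = sorted([t for t in truth if t.host_chrom == chrom],
                      key=lambda t: t.arm_start)
        if not rows:
            continue
        s = host_mod[chrom]
        parts, prev = [], 0
        for t in rows:
            circ = viral_mod[t.segment_id]
            a = t.arm_len
            if t.orientation == "+":
                q = t.viral_breakpoint
                oriented = circ
            else:
                oriented = revcomp(circ)
                q = len(circ) - t.viral_breakpoint - a
            opened = oriented[q + a:] + oriented[:q]  # circle minus its arm
            parts.append(s[prev:t.arm_start])
            parts.append(t.arm_seq + opened + t.arm_seq)
            prev = t.arm_start + a
        parts.append(s[prev:])
        para[chrom] = "".join(parts)

    host_ref = [LinearSequence(h.id, host_mod[h.id]) for h in host]
    viral_ref = SegmentedGenome(
        name=viral.name,
        segments=[CircularSegment(s.id, viral_mod[s.id]) for s in viral])
    parasitized = [LinearSequence(h.id, para[h.id]) for h in host]
    truth.sort(key=lambda t: (t.host_chrom, t.arm_start))
    return host_ref, viral_ref, parasitized, truth


def simulate_reads(references: Sequence[LinearSequence | CircularSegment],
                   cfg: GeneratorConfig, r1_path: str | Path, r2_path: str | Path,
                   rng: np.random.Generator | None = None,
                   coverages: Sequence[float] | None = None) -> int:
    """Paired-end reads over ``references``; returns the number of pairs.

    Fragment counts are proportional to reference length (optionally scaled
    per-reference by ``coverages``); fragment lengths are
    Normal(mean, sd) truncated to at least ``2*read_len - 50``; R1 is the 5'
    ``read_len`` bases and R2 the reverse complement of the 3' ``read_len``
    bases; substitution errors are i.i.d. at ``error_rate``.  Total pairs =
    round(coverage * total_bp / (2 * read_len)).  Read names encode the
    source fragment for debugging.
    """
    cfg.validate()
    if not references:
        raise ValueError("no references to simulate from")
    rng = rng if rng is not None else cfg.rng(stage=3)
    rl = cfg.read_len
    min_frag = max(2 * rl - 50, rl)
    covs = ([cfg.coverage] * len(references) if coverages is None else list(coverages))
    if len(covs) != len(references):
        raise ValueError("coverages must match references")
    lens = np.array([len(r) for r in references], dtype=float)
    eff = lens * np.array(covs)
    total_pairs = int(round(eff.sum() / (2 * rl)))
    if total_pairs < 1:
        raise ValueError("coverage too low: zero read pairs")
    probs = eff / eff.sum()
    doubled = [r.seq + r.seq if r.topology == "circular" else r.seq
               for r in references]
    circular = [r.topology == "circular" for r in references]

    ref_idx = rng.choice(len(references), size=total_pairs, p=probs)
    flens = rng.normal(cfg.fragment_mean, cfg.fragment_sd, size=total_pairs)
    flens = np.maximum(np.rint(flens).astype(int), min_frag)
    u = rng.random(total_pairs)

    with open(r1_path, "w") as f1, open(r2_path, "w") as f2:
        buf1: list[str] = []
        buf2: list[str] = []
        qual = "I" * rl
        for i in range(total_pairs):
            ri = int(ref_idx[i])
            L = int(lens[ri])
            flen = min(int(flens[i]), L)
            if circular[ri]:
                start = int(u[i] * L)
            else:
                start = int(u[i] * (L - flen + 1))
            frag = doubled[ri][start:start + flen]
            r1 = frag[:rl]
            r2 = revcomp(frag[-rl:])
            if cfg.error_rate > 0 or cfg.indel_rate > 0:
                r1 = _mutate(r1, cfg, rng)
                r2 = _mutate(r2, cfg, rng)
            name = f"frag{i:08d}:{references[ri].id}:{start}:{flen}"
            buf1.append(f"@{name}/1\n{r1}\n+\n{qual[:len(r1)]}\n")
            buf2.append(f"@{name}/2\n{r2}\n+\n{qual[:len(r2)]}\n")
            if len(buf1) >= 20000:
                f1.write("".join(buf1)); f2.write("".join(buf2))
                buf1, buf2 = [], []
        f1.write("".join(buf1)); f2.write("".join(buf2))
    return total_pairs


def _mutate(read: str, cfg: GeneratorConfig, rng: np.random.Generator) -> str:
    n_err = rng.binomial(len(read), cfg.error_rate)
    if n_err:
        b = bytearray(read, "ascii")
        for p in rng.integers(0, len(read), size=n_err):
            cur = chr(b[p])
            alts = [c for c in "ACGT" if c != cur]
            b[p] = ord(alts[rng.integers(0, 3)])
        read = bytes(b).decode()
    if cfg.indel_rate > 0:
        n_ind = rng.binomial(len(read), cfg.indel_rate)
        for _ in range(n_ind):
            p = int(rng.integers(0, len(read)))
            if rng.random() < 0.5 and len(read) > 1:
                read = read[:p] + read[p + 1:]
            else:
                ins = "ACGT"[rng.integers(0, 4)]
                read = read[:p] + ins + read[p:]
    return read


def write_truth(truth: Sequence[IntegrationTruth], tsv_path: str | Path,
                bed_path: str | Path | None = None) -> None:
    """Truth table as TSV (all fields) and BED of junction intervals."""
    with open(tsv_path, "w") as fh:
        fh.write("segment_id\thost_chrom\tarm_start\tarm_len\t"
                 "left_junction_pos\tright_junction_pos\tviral_breakpoint\t"
                 "orientation\tarm_seq\n")
        for t in truth:
            fh.write(f"{t.segment_id}\t{t.host_chrom}\t{t.arm_start}\t{t.arm_len}\t"
                     f"{t.left_junction_pos}\t{t.right_junction_pos}\t"
                     f"{t.viral_breakpoint}\t{t.orientation}\t{t.arm_seq}\n")
    if bed_path is not None:
        with open(bed_path, "w") as fh:
            for t in truth:
                fh.write(f"{t.host_chrom}\t{t.arm_start}\t"
                         f"{t.arm_start + t.arm_len}\t{t.segment_id}\t"
                         f"{t.arm_len}\t{t.orientation}\n")


def read_truth(tsv_path: str | Path) -> list[IntegrationTruth]:
    rows = []
    with open(tsv_path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        col = {c: i for i, c in enumerate(header)}
        for line in fh:
            f = line.rstrip("\n").split("\t")
            rows.append(IntegrationTruth(
                segment_id=f[col["segment_id"]], host_chrom=f[col["host_chrom"]],
                arm_start=int(f[col["arm_start"]]), arm_len=int(f[col["arm_len"]]),
                arm_seq=f[col["arm_seq"]],
                viral_breakpoint=int(f[col["viral_breakpoint"]]),
                orientation=f[col["orientation"]]))
    return rows


def write_annotation_bed(annotations: Sequence[GeneAnnotation],
                         path: str | Path) -> None:
    with open(path, "w") as fh:
        for a in annotations:
            fh.write(f"{a.segment_id}\t{a.start}\t{a.end}\t{a.family}:{a.name}\t"
                     f"0\t{a.strand}\n")


def simulate_dataset(cfg: GeneratorConfig, outdir: str | Path,
                     census: Mapping[str, int] | None = None) -> dict[str, Path]:
    """Run the whole generator and write the dataset directory.

    Reads are drawn from the parasitized chromosomes plus the free
    (episomal) viral circles; the circles' coverage is
    ``coverage * episome_ratio``.  Returns a manifest of output paths.
    """
    cfg.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = cfg.rng()
    host = make_host(cfg, rng)
    viral, annotations = make_viral_genome(cfg, census, rng)
    host_ref, viral_ref, parasitized, truth = plant_integrations(host, viral, cfg, rng)

    paths = {k: outdir / v for k, v in dict(
        host="host.fasta", viral="viral.fasta", parasitized="parasitized.fasta",
        r1="reads_R1.fastq", r2="reads_R2.fastq", truth="truth.tsv",
        truth_bed="truth.bed", annotation="viral_genes.bed",
        config="config.yaml").items()}
    write_fasta(host_ref, paths["host"])
    write_fasta(viral_ref, paths["viral"])
    write_fasta(parasitized, paths["parasitized"])
    refs = list(parasitized) + list(viral_ref.segments)
    covs = ([cfg.coverage] * len(parasitized)
            + [cfg.coverage * cfg.episome_ratio] * len(viral_ref))
    simulate_reads(refs, cfg, paths["r1"], paths["r2"], rng, coverages=covs)
    write_truth(truth, paths["truth"], paths["truth_bed"])
    write_annotation_bed(annotations, paths["annotation"])
    with open(paths["config"], "w") as fh:
        yaml.safe_dump(dataclasses.asdict(cfg), fh, sort_keys=True)
    return paths
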