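# Methods

This note documents the models and procedures implemented in `ivscan`, the
parameters that matter, the numerical choices made where the design was
open, and what the synthetic benchmark does and does not demonstrate.

## Integration model

The generator and the detector share one mechanistic model: Campbell-style
integration of a circular viral segment into a linear host chromosome by a
single homologous crossover. Both genomes carry one copy of a homology arm
`A` (the integration motif). The crossover opens the circle at its arm and
inserts it into the host locus, so the post-integration locus reads

```
host_left + A + (circle opened at A, minus its arm) + A + host_right
```

with the arm duplicated at the two junctions. Consequences used throughout:

* the detectable microhomology at each junction equals the arm length;
* the two junction breakpoints on the host reference are the arm end
  (host→viral, "left") and the arm start (viral→host, "right"), so a full
  call's `left_pos - right_pos` equals the arm length;
* excising the inserted block between the duplicated arms restores the
  pre-integration chromosome exactly (tested as a string-surgery oracle).

The circle may insert in either orientation; a "−" event inserts the
reverse complement of the opened circle and the arm in the circle is stored
reverse-complemented. Replication of integrated segments in the host is not
modelled: integrated copies are present at the same copy number as the
locus, and free circles persist episomally at their own coverage.

## Synthetic data generator (`ivscan.synthetic`)

Defaults encode the study conditions the pipeline is meant for:

| parameter | default | meaning |
|---|---|---|
| `n_host_chroms` × `host_chrom_bp` | 5 × 200 kb | host genome (i.i.d. bases, GC 0.40) |
| `n_segments`, `segment_len_range` | 62, [1500, 8200] bp | circular segments, lengths uniform |
| `target_gc` | 0.43 | viral GC fraction |
| `integrated_segment_ids` | 3 drawn at random | segments that integrate |
| `sites_per_segment` | 1 (mapping allowed, e.g. one segment at 5 sites) | loci per segment |
| `arm_len_range` | [36, 46] bp | homology arm, uniform |
| `coverage`, `read_len` | 30×, 150 bp | fold coverage per reference pool |
| `fragment_mean/sd` | 400 / 40 bp | Normal fragment length, truncated ≥ 2·read_len − 50 |
| `error_rate` | 0.002 | i.i.d. substitutions; 1 bp indel mode exists, off by default |
| `episome_ratio` | 1.0 | coverage of free circles relative to host |

Segment labels follow the lettered convention (A1–A5 … F1–F3) when
`n_segments` is 62, generic `segNNN` otherwise. Each segment carries a
unique 60-mer barcode so circles are mutually distinguishable even at equal
length. The 123-gene family census (41 rep, 10 cys, 9 vankyrin, 7 PRRP,
6 vinnexin, 3 N-gene, 2 neuromodulin, 45 hypothetical) is written in as
ORF-shaped intervals (ATG start, stop-free body, stop codon, either strand,
never wrapping the origin); for genomes much smaller than the default
~300 kb the census is scaled down proportionally so placement stays
feasible — at the default dimensions it is exactly 123.

Two generator guards matter for interpretation:

* **Arm uniqueness.** Each arm is redrawn until neither it nor its reverse
  complement occurs anywhere in the host or viral genome, so a junction is
  attributable to exactly one event.
* **Flank guard.** The bases immediately flanking each planted arm copy are
  required to differ between host and oriented circle. Without this, one in
  four junctions would extend the shared region past the arm by chance and
  measured microhomology would overshoot the planted length by one or more
  bases. With the guard, the maximal exact shared flank equals the planted
  arm exactly, which is what the fidelity checks assert.

Reads are drawn from the parasitized chromosomes plus the free circles
(fragment counts proportional to reference length within each pool), R1 from
the 5′ end and R2 as the reverse complement of the 3′ end of each fragment.
Read names encode the source fragment for debugging only; the pipeline never
reads them. All randomness flows through one seeded `numpy` generator and
every output file is byte-identical for a given config. Stage functions
called standalone derive stage-tagged streams from the seed so that, e.g.,
an arm drawn in `plant_integrations` cannot replay the base stream that
generated the host.

## Detection pipeline (`ivscan.junctions`, `ivscan.microhomology`)

**Mapping.** References (host chromosomes + viral circles) are indexed by
2-bit-encoded k-mers, k = 21 by default (odd, to avoid palindromic k-mers);
circles are indexed on their doubled sequence with offsets reported modulo
the length, so anchors cross the origin. A read is mapped on both strands to
maximal exact anchor runs: each k-mer hit is extended base-by-base in both
directions; a substitution splits a match into two runs on the same
diagonal. Reads that match one reference end-to-end take a fast path (one
lookup, one string compare), which covers the overwhelming majority of
resequencing reads.

**Chimera calling.** A read is chimeric when its best viral run and best
host run each span ≥ `min_anchor` (25 bp), sit staggered on opposite flanks
of the read (neither containing the other — a read fully explained by one
reference is never chimeric, which keeps episomal circle reads out), and
jointly cover the read up to `max_unaligned` (10 bp) slack. The overlap of
the two runs on the read is the microhomology candidate, since a homology
arm maps to both references. Junction side and breakpoints are reported in
host-forward convention; the viral breakpoint is the circle coordinate
aligned to the junction edge of the host anchor. Read pairs with one mate
fully viral and the other fully host are tallied separately as
discordant-pair evidence and never counted as junction support.

**Duplicate removal.** Fragments whose two mates have identical best
placements are counted once (library-duplicate removal at fragment level;
keying on single-read placement instead would collapse ~10% of legitimate
support at 30×, because junction-spanning windows are only ~110 bp wide).

**Clustering and support.** Chimeric reads sharing (segment, chromosome,
side) are single-linkage clustered on the host breakpoint within
`cluster_tol` (5 bp); the consensus is the median (lower middle on ties, so
the smallest coordinate wins) and support is the member count. Clusters
with support < `min_support` (15 reads, the survey's filter) are removed
but listed with the reason. Expected support per junction under the model
is `coverage · (read_len − arm_len − 2) / read_len` ≈ 22 at 30× with 41 bp
arms — a read supports a junction only if it spans the full duplicated arm
with at least one base on each side and both anchors pass — and observed
supports are tested against that expectation within 3σ Poisson.

**Microhomology.** For each surviving cluster the maximal exact shared
flank is measured against the references (not the reads): the largest
L ≤ `max_mh` (100) such that the L host bases ending at (left) or starting
at (right) the host breakpoint equal the corresponding oriented circle
bases at the viral breakpoint, with circular fetches on the viral side and
capping (flagged) at host contig ends. Fixed windows of 10, 20 and 50 bp
centred on the breakpoint are also scanned for their longest exact common
substring; the maximal match supersedes them but they are reported for
comparability with window-based surveys. Matching is exact; a fuzzy mode
was considered and rejected as the default because the generator plants
identical arm copies and real divergence estimates were unavailable.

**Calls.** Left and right clusters of one segment on one chromosome within
`max_pair_span` (segment length + 200 bp by default) pair into a "full"
call; an unpaired junction becomes a "partial" call, never silently
dropped. A call's `mh_len` is the junction consensus (the maximum when only
one side survived). Per-segment summaries report integration status, host
site counts and episomal depth — mean fully-viral read depth over the
segment. Note the depth channel counts all fully-viral reads, so integrated
segments show elevated depth (episomal plus integrated copies); it is a
sanity channel, not a copy-number estimate.

## ORF annotation (`ivscan.orfs`)

Six frames are scanned on the doubled sequence of each circle so an ORF
spanning the linearization origin is found exactly once; candidates are
keyed by circular stop position and only the longest ORF per stop survives
(nested in-frame starts suppressed), which also makes the output invariant
under rotation and strand flip — both properties are tested against a
brute-force enumeration oracle. `min_aa` defaults to 75 (comfortably below
the smallest annotated ichnovirus proteins, ~79 aa); alternative starts
(GTG/TTG) are off by default; the standard genetic code only. ORFs longer
than the circle are impossible by construction. Cross-segment duplicates —
nucleotide sequences within an edit distance of 2% of the longer length,
operationalizing "identical or slightly modified" — are collapsed via
union-find to one representative (longest, then lexicographic segment id),
with a report of what was trimmed against what. GFF3 output is 1-based
inclusive; origin-wrapping ORFs are written as two CDS parts sharing an ID.

## Cross-genome comparison (`ivscan.compare`)

For each segment pair, the strand of the second circle is chosen by total
shared k-mer count (k = 13) and its rotation by the modal circular diagonal
of the shared k-mers; the rotated pair is then globally aligned (edlib) and
identity is matches over all alignment columns, gaps included in the
denominator. The pair is ordered canonically before alignment so identity
is symmetric to 4 decimals. Pairs sharing fewer than 20 k-mers are scored
identity 0 without alignment. A link qualifies at ≥ 70% identity covering
≥ 0.5 of the shorter segment — thresholds chosen so that the 76–98%
identity band seen between sister-species isolates qualifies while
unrelated random segments never do. Reciprocal-best links are marked,
summary identity statistics are taken over them, and segments of either
genome with no qualifying link are reported genome-specific. This is a
global-alignment identity, not a BLAST HSP identity; agreement with
BLAST-style numbers should only be expected at integer-percent resolution.

## What the synthetic benchmark shows — and does not

The generator produces i.i.d. random sequence. Real host genomes contain
repeats, low-complexity tracts and segmental duplications that an exact-
match anchor mapper will handle worse than the clean benchmark suggests;
real viral segments share internal homology beyond the planted arms; real
homology arms may have diverged between the genomes, which exact
microhomology measurement would undercount. Passing the truth-recovery
checks therefore demonstrates correctness of the junction logic and
bookkeeping under the stated model, not field performance on arbitrary
genomes. Quality scores are constant, there are no PCR duplicates beyond
exact fragment collisions, and no structural variation other than the
planted integrations.

Problem sizes used by the test-suite and the acceptance script were chosen
as the smallest that exercise the claims: the survey-scale checks use the
full default dataset (1 Mb host, 62 segments, ~130 k read pairs) and a
205-event variant (~230 k pairs); oracle-equivalence suites run on ≤ 50 kb
references. Deposited-accession checks (genome summary of the real segment
set; identity between two real isolates) require downloads, so the
test-suite exercises the same code paths on synthetic reconstructions that
encode the published characteristics (62 segments, 247 kb, 43% GC,
1.5–8.2 kb with median 3.77 kb; planted 85–96% identity band with mean 90%
and 9 + 2 genome-specific segments); conclusions about the real records
require running `ivscan stats` / `ivscan compare` on the downloaded FASTA.

## Determinism and tolerances

Every simulation is reproducible byte-for-byte from its config (seed
included). Detection is deterministic given its inputs: clustering uses
order-independent tie rules and all reported tables are sorted. Floating
point appears only in identity percentages (rounded to 4 decimals), GC
percent and depth (reported to 2 decimals); genome statistics in kb are
rounded half-up to 2 decimals to match conventional reporting.
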