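"""Internal architecture of the 45S intergenic spacer.

Segments an IGS into tandem-repeat blocks, unique regions, a 5S insertion
(with orientation relative to the unit, distance to the 28S gene, a polyA
linker and the conserved 5' flank) — the annotation layer behind the
unit-diagram view of an rDNA repeat.

Tandem repeats are found by self-comparison at every candidate period: a
shift-by-p match profile is segmented into maximal arrays whose match
fraction clears ``min_match`` (scored Kadane-style so isolated mismatches
are tolerated), nested periods resolving to the smallest one covering the
region.  Coordinates throughout are IGS-local, 0-based, in unit
(transcription) orientation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .align import pairwise_identity
from .scan import HomologyHit, RdnaUnit
from .types import FORWARD, REVERSE, GenomicInterval, SequenceRecord, revcomp

logger = logging.getLogger("nor5s")


@dataclass(frozen=True)
class RepeatParams:
    min_period: int = 5
    max_period: int = 2000
    min_copies: float = 2.5
    min_match: float = 0.8


@dataclass(frozen=True)
class RepeatBlock:
    """A tandem array: location, period, copy number and monomer consensus."""

    location: GenomicInterval
    period: int
    copy_number: float
    monomer_consensus: str
    label: str

    def __post_init__(self) -> None:
        if self.period != len(self.monomer_consensus):
            raise ValueError("period must equal monomer length")
        if self.copy_number < 1:
            raise ValueError("copy_number must be >= 1")


@dataclass(frozen=True)
class Segment:
    interval: GenomicInterval
    seg_class: str  # repeat | unique | polyA | fiveS_insert
    block_label: str = ""


@dataclass
class IgsAnnotation:
    """Ordered, non-overlapping segmentation tiling one IGS."""

    igs_length: int
    segments: list[Segment]

    def __post_init__(self) -> None:
        pos = 0
        for seg in self.segments:
            if seg.interval.start != pos:
                raise ValueError("segments must tile the IGS without gaps")
            pos = seg.interval.end
        if pos != self.igs_length:
            raise ValueError("segments do not cover the IGS")


@dataclass(frozen=True)
class FiveSInsert:
    """The 5S gene copy found inside an IGS, in unit-relative terms."""

    location: GenomicInterval  # genomic
    orientation_vs_unit: str  # "same" | "opposite"
    distance_to_28S: int
    upstream_flank: str  # gene-proximal-first (see conserved_prefix)
    polyA: Optional[GenomicInterval]  # genomic, gene strand
    adjacent_block: str  # label of the repeat block bordering the 3' side, or ""


@dataclass(frozen=True)
class FlankConservationResult:
    """Cross-sample conservation of the sequence 5' of the insert.

    Flank strings are stored gene-proximal-first: position 1 is the
    nucleotide immediately adjacent to the gene's 5' end, so the conserved
    prefix measures conservation anchored at the gene boundary.
    """

    flanks: tuple[str, ...]
    conserved_prefix_length: int
    agreement_profile: tuple[float, ...]


def extract_igs(unit: RdnaUnit, contig: SequenceRecord) -> tuple[str, GenomicInterval]:
    """The IGS sequence in unit transcription orientation, plus its interval."""
    if unit.igs_span is None:
        raise ValueError(
            f"unit at {unit.transcribed_span.start}-{unit.transcribed_span.end} "
            "has no (or zero-length) IGS span"
        )
    return unit.igs_span.slice(contig.residues), unit.igs_span


def detect_tandem_repeats(
    sequence: str,
    params: RepeatParams = RepeatParams(),
    contig_id: str = "seq",
) -> list[RepeatBlock]:
    """Find tandem arrays by shift-self-comparison over candidate periods."""
    n = len(sequence)
    if n < 2 * params.min_period:
        raise ValueError("sequence shorter than two minimum periods")
    s = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    penalty = params.min_match / (1.0 - params.min_match)
    candidates: list[tuple[int, int, int]] = []  # (period, start, end) in eq-space
    for p in range(params.min_period, min(params.max_period, n // 2) + 1):
        eq = s[p:] == s[:-p]
        min_run = (params.min_copies - 1.0) * p
        score = np.where(eq, 1.0, -penalty)
        # Kadane-style segmentation into maximal positive-average runs
        i = 0
        total = 0.0
        best = 0.0
        best_end = -1
        start = 0
        for j, v in enumerate(score):
            if total <= 0.0:
                total = 0.0
                if best_end >= 0 and best_end + 1 - start >= min_run:
                    candidates.append((p, start, best_end + 1))
                start = j
                best = 0.0
                best_end = -1
            total += v
            if total > best:
                best = total
                best_end = j
        if best_end >= 0 and best_end + 1 - start >= min_run:
            candidates.append((p, start, best_end + 1))

    blocks: list[RepeatBlock] = []
    occupied: list[tuple[int, int]] = []
    for p, a, b in sorted(candidates, key=lambda c: (c[0], c[1])):
        start, end = a, b + p  # array spans one extra period beyond eq run
        overlap = sum(
            max(0, min(end, oe) - max(start, os)) for os, oe in occupied
        )
        if overlap > 0.5 * (end - start):
            continue
        monomer = _monomer_consensus(sequence, start, end, p)
        if len(set(monomer)) == 1:
            # homopolymer: degenerate period-1 array (polyA runs are the
            # caller's business, see detect_polyA)
            p, monomer = 1, monomer[0]
        blocks.append(
            RepeatBlock(
                GenomicInterval(contig_id, start, end),
                p,
                round((end - start) / p, 2),
                monomer,
                label="",
            )
        )
        occupied.append((start, end))
    blocks.sort(key=lambda blk: blk.location.start)
    return [
        RepeatBlock(b.location, b.period, b.copy_number, b.monomer_consensus, f"R{i+1}")
        for i, b in enumerate(blocks)
    ]


def _monomer_consensus(sequence: str, start: int, end: int, period: int) -> str:
    cols = []
    for c in range(period):
        bases = [sequence[i] for i in range(start + c, end, period)]
        cols.append(max(set(bases), key=lambda x: (bases.count(x), x)))
    return "".join(cols)


def detect_polyA(
    sequence: str, window: int = 30, min_run: int = 8
) -> Optional[tuple[int, int]]:
    """Longest A-run of length >= min_run within ``sequence[:window]``.

    At most one non-A per 10 positions of the run is tolerated.  Returns a
    half-open (start, end) within the sequence, or None.
    """
    region = sequence[: window if window else len(sequence)]
    best: Optional[tuple[int, int]] = None
    n = len(region)
    for i in range(n):
        if region[i] != "A":
            continue
        non_a = 0
        last_a = i
        for j in range(i, n):
            if region[j] == "A":
                last_a = j
            else:
                non_a += 1
                if non_a > (j - i + 10) // 10:  # ceil(run_length / 10)
                    break
        length = last_a - i + 1
        if length >= min_run and (best is None or length > best[1] - best[0]):
            best = (i, last_a + 1)
    return best


def annotate_igs(
    igs_sequence: str,
    fives_intervals: Sequence[GenomicInterval],
    blocks: Sequence[RepeatBlock],
    polyA_window: int = 30,
    polyA_min_run: int = 8,
    igs_id: str = "IGS",
) -> IgsAnnotation:
    """Tile the IGS with repeat / unique / polyA / fiveS_insert segments.

    ``fives_intervals`` are IGS-local (unit orientation); their strand is
    the gene strand relative to the unit.  Inserts win over overlapping
    repeat blocks, which are truncated with a warning.
    """
    n = len(igs_sequence)
    fixed: list[Segment] = []
    for iv in fives_intervals:
        fixed.append(Segment(GenomicInterval(igs_id, iv.start, iv.end, iv.strand), "fiveS_insert"))
        pa = polyA_downstream(igs_sequence, iv, polyA_window, polyA_min_run)
        if pa is not None:
            fixed.append(Segment(GenomicInterval(igs_id, pa[0], pa[1], iv.strand), "polyA"))
    fixed.sort(key=lambda seg: seg.interval.start)

    segments: list[Segment] = list(fixed)
    for block in blocks:
        pieces = [(block.location.start, block.location.end)]
        for seg in fixed:
            pieces = [
                part
                for s, e in pieces
                for part in ((s, min(e, seg.interval.start)), (max(s, seg.interval.end), e))
                if part[0] < part[1]
            ]
        if pieces != [(block.location.start, block.location.end)]:
            logger.warning("block %s truncated by 5S insert", block.label or block.period)
        for s, e in pieces:
            segments.append(Segment(GenomicInterval(igs_id, s, e), "repeat", block.label))
    segments.sort(key=lambda seg: seg.interval.start)

    tiled: list[Segment] = []
    pos = 0
    for seg in segments:
        if seg.interval.start > pos:
            tiled.append(Segment(GenomicInterval(igs_id, pos, seg.interval.start), "unique"))
        tiled.append(seg)
        pos = seg.interval.end
    if pos < n:
        tiled.append(Segment(GenomicInterval(igs_id, pos, n), "unique"))
    return IgsAnnotation(n, tiled)


def polyA_downstream(
    igs_sequence: str,
    gene_iv: GenomicInterval,
    window: int = 30,
    min_run: int = 8,
) -> Optional[tuple[int, int]]:
    """Locate a polyA linker just 3' of the gene, in gene orientation.

    Returns IGS-local half-open coordinates, or None.
    """
    if gene_iv.strand == FORWARD:
        region = igs_sequence[gene_iv.end : gene_iv.end + window]
        hit = detect_polyA(region, window, min_run)
        if hit is None:
            return None
        return gene_iv.end + hit[0], gene_iv.end + hit[1]
    region = revcomp(igs_sequence[max(0, gene_iv.start - window) : gene_iv.start])
    hit = detect_polyA(region, window, min_run)
    if hit is None:
        return None
    return gene_iv.start - hit[1], gene_iv.start - hit[0]


def to_igs_local(iv: GenomicInterval, igs_span: GenomicInterval) -> GenomicInterval:
    """Map a genomic interval into IGS-local unit-orientation coordinates."""
    if not igs_span.contains(iv):
        raise ValueError("interval lies outside the IGS span")
    if igs_span.strand == FORWARD:
        start, end = iv.start - igs_span.start, iv.end - igs_span.start
        strand = iv.strand
    else:
        start, end = igs_span.end - iv.end, igs_span.end - iv.start
        strand = FORWARD if iv.strand == REVERSE else REVERSE
    return GenomicInterval("IGS", start, end, strand)


def classify_insert(
    hit: HomologyHit,
    unit: RdnaUnit,
    contig: SequenceRecord,
    blocks: Sequence[RepeatBlock] = (),
    ref_len: Optional[int] = None,
    flank_length: int = 40,
    polyA_window: int = 30,
    polyA_min_run: int = 8,
) -> FiveSInsert:
    """Characterise a 5S hit inside a unit's IGS.

    With ``ref_len`` given, the hit is first padded to the full reference
    span (local alignment clips mismatching gene ends).  The upstream flank
    is reported gene-proximal-first, ready for :func:`conserved_prefix`.
    """
    if unit.igs_span is None or not unit.igs_span.contains(hit.location):
        raise ValueError("5S hit lies outside the unit's IGS span")
    gene_iv = hit.location
    if ref_len is not None and hit.ref_end > hit.ref_start:
        gene_iv = hit.full_gene_interval(ref_len, len(contig))
    orientation = "same" if gene_iv.strand == unit.strand else "opposite"

    igs_seq, igs_span = extract_igs(unit, contig)
    local = to_igs_local(gene_iv, igs_span)
    distance = local.start  # IGS starts at the 28S 3' end

    # flank: the flank_length nt 5' of the gene in gene orientation,
    # reversed so index 0 abuts the gene start
    if local.strand == FORWARD:
        natural = igs_seq[max(0, local.start - flank_length) : local.start]
    else:
        natural = revcomp(igs_seq[local.end : local.end + flank_length])
    flank = natural[::-1]

    pa_local = polyA_downstream(igs_seq, local, polyA_window, polyA_min_run)
    pa_genomic: Optional[GenomicInterval] = None
    adjacent = ""
    after_gene = local.end if local.strand == FORWARD else local.start
    if pa_local is not None:
        if igs_span.strand == FORWARD:
            pa_genomic = GenomicInterval(
                igs_span.contig_id,
                igs_span.start + pa_local[0],
                igs_span.start + pa_local[1],
                gene_iv.strand,
            )
        else:
            pa_genomic = GenomicInterval(
                igs_span.contig_id,
                igs_span.end - pa_local[1],
                igs_span.end - pa_local[0],
                gene_iv.strand,
            )
        after_gene = pa_local[1] if local.strand == FORWARD else pa_local[0]
    for block in blocks:
        if local.strand == FORWARD and 0 <= block.location.start - after_gene <= 5:
            adjacent = block.label
        elif local.strand == REVERSE and 0 <= after_gene - block.location.end <= 5:
            adjacent = block.label
    return FiveSInsert(gene_iv, orientation, distance, flank, pa_genomic, adjacent)


def conserved_prefix(
    flanks: Sequence[str], max_mismatch_fraction: float = 0.1
) -> FlankConservationResult:
    """Longest prefix over which every column agrees with its majority base
    in at least ``1 - max_mismatch_fraction`` of the samples."""
    if len(flanks) < 2:
        raise ValueError("need at least 2 flanks")
    min_len = min(len(f) for f in flanks)
    profile: list[float] = []
    for col in range(min_len):
        bases = [f[col] for f in flanks]
        agreement = max(bases.count(b) for b in set(bases)) / len(bases)
        profile.append(agreement)
    length = 0
    for col, agreement in enumerate(profile):
        if agreement >= 1.0 - max_mismatch_fraction:
            length = col + 1
        else:
            break
    return FlankConservationResult(tuple(flanks), length, tuple(profile))


def monomer_identity(a: str, b: str) -> float:
    """Best global identity of two monomers over all rotations of ``b``.

    Tandem monomers are defined only up to cyclic rotation, so label
    harmonisation must be rotation-invariant.
    """
    best = 0.0
    for r in range(len(b)):
        rot = b[r:] + b[:r]
        best = max(best, pairwise_identity(a, rot))
        if best == 100.0:
            break
    return best


def harmonise_labels(
    block_sets: Sequence[Sequence[RepeatBlock]], min_identity: float = 80.0
) -> list[list[str]]:
    """Assign family labels (F1, F2, ...) consistent across samples.

    Blocks from different samples whose monomer consensuses are
    rotation-identical at >= ``min_identity`` share a family.  Similarity is
    reported, not homology.
    """
    flat = [(si, bi, blk) for si, blks in enumerate(block_sets) for bi, blk in enumerate(blks)]
    parent = list(range(len(flat)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(len(flat)):
        for j in range(i + 1, len(flat)):
            a, b = flat[i][2], flat[j][2]
            if min(len(a.monomer_consensus), len(b.monomer_consensus)) * 1.5 < max(
                len(a.monomer_consensus), len(b.monomer_consensus)
            ):
                continue
            if monomer_identity(a.monomer_consensus, b.monomer_consensus) >= min_identity:
                parent[find(i)] = find(j)

    family_of: dict[int, str] = {}
    out: list[list[str]] = [["" for _ in blks] for blks in block_sets]
    counter = 0
    for idx, (si, bi, _) in enumerate(flat):
        root = find(idx)
        if root not in family_of:
            counter += 1
            family_of[root] = f"F{counter}"
        out[si][bi] = family_of[root]
    return out
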