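"""Seed-and-extend homology scan for rRNA gene copies, unit assembly and
the 28S + 5S co-occurrence screen.

The scan finds exact k-mer seeds of the reference on both contig strands,
chains them along diagonals, and extends each chained cluster with a local
affine-gap alignment of the reference against the seeded contig window.
Hits pass identity and query-coverage thresholds; overlapping same-strand
hits collapse to the higher score.  Units are maximal same-strand
18S -> 5.8S -> 28S triplets in transcription order; the intergenic spacer of
a unit runs from its 28S 3' end to the next unit's 18S start (or to the
contig end, flagged partial).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

from .align import DEFAULT_SCORING, AlignmentResult, ScoringScheme, smith_waterman_local
from .types import FORWARD, REVERSE, GenomicInterval, SequenceRecord, revcomp

logger = logging.getLogger("nor5s")

GENE_NAMES = ("18S", "5.8S", "28S", "5S")


@dataclass(frozen=True)
class ScanParams:
    seed_k: int = 13
    min_identity: float = 70.0
    min_coverage: float = 50.0
    band_width: int = 32  # diagonal tolerance when chaining seeds
    window_margin: int = 60
    scoring: ScoringScheme = field(default_factory=lambda: DEFAULT_SCORING)


@dataclass(frozen=True)
class HomologyHit:
    """A located copy of a reference rRNA gene on a contig."""

    gene_name: str
    location: GenomicInterval
    identity: float
    query_coverage: float
    score: int
    ref_start: int = 0  # aligned reference span, 0-based half-open
    ref_end: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.identity <= 100 and 0 < self.query_coverage <= 100):
            raise ValueError("identity and coverage must be in (0, 100]")

    def full_gene_interval(self, ref_len: int, contig_len: int) -> GenomicInterval:
        """Pad the hit to the full reference span (local alignments clip
        mismatching gene ends); clamped to the contig."""
        head = self.ref_start          # missing at the gene 5' side
        tail = ref_len - self.ref_end  # missing at the gene 3' side
        iv = self.location
        if iv.strand == FORWARD:
            start, end = iv.start - head, iv.end + tail
        else:
            start, end = iv.start - tail, iv.end + head
        return GenomicInterval(iv.contig_id, max(0, start), min(contig_len, end), iv.strand)


@dataclass
class RdnaUnit:
    """One assembled 45S repeat: 18S, 5.8S and 28S on a common strand."""

    strand: str
    hits: dict[str, HomologyHit]  # keys 18S, 5.8S, 28S
    transcribed_span: GenomicInterval
    igs_span: Optional[GenomicInterval] = None
    igs_partial: bool = False

    @property
    def contig_id(self) -> str:
        return self.transcribed_span.contig_id


def _seed_matches(contig: str, reference: str, k: int) -> list[tuple[int, int]]:
    """Exact k-mer matches as (contig_pos, ref_pos) pairs."""
    index: dict[str, list[int]] = {}
    for i in range(len(reference) - k + 1):
        index.setdefault(reference[i : i + k], []).append(i)
    out: list[tuple[int, int]] = []
    for j in range(len(contig) - k + 1):
        positions = index.get(contig[j : j + k])
        if positions:
            for r in positions:
                out.append((j, r))
    return out


def _cluster_seeds(
    matches: list[tuple[int, int]], ref_len: int, band: int
) -> list[tuple[int, int]]:
    """Chain seeds into candidate contig windows.

    Seeds are grouped when their diagonals agree within ``band`` and their
    contig positions are within one reference length of the running
    cluster; each cluster yields the contig window implied by projecting
    the full reference through its seeds.
    """
    if not matches:
        return []
    matches = sorted(matches, key=lambda m: (m[0] - m[1], m[0]))
    clusters: list[list[tuple[int, int]]] = []
    for cpos, rpos in matches:
        placed = False
        for cl in clusters:
            c0, r0 = cl[-1]
            if abs((cpos - rpos) - (c0 - r0)) <= band and abs(cpos - c0) <= ref_len:
                cl.append((cpos, rpos))
                placed = True
                break
        if not placed:
            clusters.append([(cpos, rpos)])
    windows = []
    for cl in clusters:
        start = min(c - r for c, r in cl)
        end = max(c + (ref_len - r) for c, r in cl)
        windows.append((start, end))
    return windows


def _merge_windows(windows: list[tuple[int, int]], margin: int, limit: int) -> list[tuple[int, int]]:
    padded = sorted((max(0, s - margin), min(limit, e + margin)) for s, e in windows)
    merged: list[list[int]] = []
    for s, e in padded:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def _align_window(
    contig_seq: str,
    window: tuple[int, int],
    reference: SequenceRecord,
    params: ScanParams,
) -> list[AlignmentResult]:
    """Local alignments of the reference inside one window.

    After the best alignment is taken, the aligned contig stretch is masked
    and the window re-aligned, so tandem copies that fused into one window
    are all reported.
    """
    results = []
    sub = list(contig_seq[window[0] : window[1]])
    while True:
        aln = smith_waterman_local("".join(sub), reference.residues, params.scoring)
        if not aln.ops:
            break
        coverage = 100.0 * (aln.b_end - aln.b_start) / len(reference.residues)
        if coverage < params.min_coverage or aln.identity < params.min_identity:
            break
        results.append(aln)
        for i in range(aln.a_start, aln.a_end):
            sub[i] = "N"
    return results


def scan_gene(
    contig: SequenceRecord,
    reference: SequenceRecord,
    params: ScanParams = ScanParams(),
) -> list[HomologyHit]:
    """Locate copies of one reference gene on both strands of a contig."""
    k = params.seed_k
    if len(reference) < k:
        raise ValueError(f"reference {reference.identifier} shorter than seed k={k}")
    if len(contig) < k:
        logger.warning("contig %s shorter than seed k; skipping", contig.identifier)
        return []
    gene_name = reference.identifier
    hits: list[HomologyHit] = []
    n = len(contig)
    for strand in (FORWARD, REVERSE):
        seq = contig.residues if strand == FORWARD else revcomp(contig.residues)
        matches = _seed_matches(seq, reference.residues, k)
        windows = _merge_windows(
            _cluster_seeds(matches, len(reference), params.band_width),
            params.window_margin,
            n,
        )
        for window in windows:
            for aln in _align_window(seq, window, reference, params):
                start = window[0] + aln.a_start
                end = window[0] + aln.a_end
                iv = GenomicInterval(contig.identifier, start, end, FORWARD)
                if strand == REVERSE:
                    iv = iv.flipped(n)
                hits.append(
                    HomologyHit(
                        gene_name,
                        iv,
                        round(aln.identity, 2),
                        round(100.0 * (aln.b_end - aln.b_start) / len(reference), 2),
                        aln.score,
                        aln.b_start,
                        aln.b_end,
                    )
                )
    return _merge_overlapping(hits)


def _merge_overlapping(hits: list[HomologyHit]) -> list[HomologyHit]:
    """Keep the single highest-scoring hit per overlapping same-strand locus."""
    kept: list[HomologyHit] = []
    for hit in sorted(hits, key=lambda h: -h.score):
        if any(
            hit.location.strand == other.location.strand
            and hit.location.overlaps(other.location)
            for other in kept
        ):
            continue
        kept.append(hit)
    kept.sort(key=lambda h: h.location.start)
    return kept


def scan_genome(
    contigs: list[SequenceRecord],
    references: list[SequenceRecord],
    params: ScanParams = ScanParams(),
) -> dict[str, list[HomologyHit]]:
    """Scan every contig against every reference gene."""
    out: dict[str, list[HomologyHit]] = {}
    for contig in contigs:
        contig_hits: list[HomologyHit] = []
        for ref in references:
            contig_hits.extend(scan_gene(contig, ref, params))
        contig_hits.sort(key=lambda h: h.location.start)
        out[contig.identifier] = contig_hits
    return out


def assemble_units(
    hits: list[HomologyHit],
    contig_length: int,
    max_unit_span: int = 20_000,
) -> tuple[list[RdnaUnit], list[HomologyHit]]:
    """Group same-strand 18S -> 5.8S -> 28S hits into 45S units.

    Returns ``(units, unpaired_hits)``.  Units are ordered along the
    transcription direction of their strand; IGS spans are attached between
    consecutive units, and the last unit's IGS runs to the contig end
    (flagged partial) when no following unit exists.
    """
    units: list[RdnaUnit] = []
    unpaired: list[HomologyHit] = []
    for strand in (FORWARD, REVERSE):
        core = [h for h in hits if h.location.strand == strand and h.gene_name in ("18S", "5.8S", "28S")]
        # transcription order: ascending coordinates on +, descending on -
        core.sort(key=lambda h: h.location.start, reverse=(strand == REVERSE))
        strand_units: list[RdnaUnit] = []
        consumed: set[int] = set()
        for i, hit in enumerate(core):
            if i in consumed or hit.gene_name != "18S":
                continue
            triple = [hit]
            j = i + 1
            for want in ("5.8S", "28S"):
                while j < len(core) and (j in consumed or core[j].gene_name != want):
                    # a second 18S before the triple completes breaks the unit
                    if j not in consumed and core[j].gene_name == "18S":
                        break
                    j += 1
                if j < len(core) and core[j].gene_name == want:
                    triple.append(core[j])
                    j += 1
            if len(triple) < 3:
                continue
            span_start = min(h.location.start for h in triple)
            span_end = max(h.location.end for h in triple)
            if span_end - span_start > max_unit_span:
                continue
            consumed.update(core.index(h) for h in triple)
            strand_units.append(
                RdnaUnit(
                    strand,
                    {h.gene_name: h for h in triple},
                    GenomicInterval(hit.location.contig_id, span_start, span_end, strand),
                )
            )
        unpaired.extend(h for i, h in enumerate(core) if i not in consumed)
        # IGS spans between consecutive units in transcription order
        for idx, unit in enumerate(strand_units):
            contig_id = unit.contig_id
            if strand == FORWARD:
                igs_start = unit.hits["28S"].location.end
                if idx + 1 < len(strand_units):
                    igs_end = strand_units[idx + 1].hits["18S"].location.start
                    partial = False
                else:
                    igs_end, partial = contig_length, True
                if igs_start < igs_end:
                    unit.igs_span = GenomicInterval(contig_id, igs_start, igs_end, strand)
                    unit.igs_partial = partial
            else:
                igs_end = unit.hits["28S"].location.start
                if idx + 1 < len(strand_units):
                    igs_start = strand_units[idx + 1].hits["18S"].location.end
                    partial = False
                else:
                    igs_start, partial = 0, True
                if igs_start < igs_end:
                    unit.igs_span = GenomicInterval(contig_id, igs_start, igs_end, strand)
                    unit.igs_partial = partial
        units.extend(strand_units)
    units.sort(key=lambda u: u.transcribed_span.start)
    return units, unpaired


def screen_cooccurrence(
    hits_by_contig: dict[str, list[HomologyHit]],
    units_by_contig: dict[str, list[RdnaUnit]],
) -> list[str]:
    """Contigs carrying both 28S and a 5S copy outside every transcribed span.

    These are the NOR-5S candidates: a 5S gene sitting inside (or next to)
    a 45S array rather than inside the 18S-28S transcription unit.
    """
    flagged = []
    for contig_id, hits in hits_by_contig.items():
        has_28s = any(h.gene_name == "28S" for h in hits)
        if not has_28s:
            continue
        units = units_by_contig.get(contig_id, [])
        fives = [
            h
            for h in hits
            if h.gene_name == "5S"
            and not any(u.transcribed_span.overlaps(h.location) for u in units)
        ]
        if fives:
            flagged.append(contig_id)
    return flagged


def fives_hits_in_igs(
    hits: list[HomologyHit], units: list[RdnaUnit]
) -> list[tuple[HomologyHit, RdnaUnit]]:
    """Pair each 5S hit with the unit whose IGS span contains it."""
    out = []
    for hit in hits:
        if hit.gene_name != "5S":
            continue
        for unit in units:
            if unit.igs_span is not None and unit.igs_span.contains(hit.location):
                out.append((hit, unit))
                break
    return out
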