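"""Variant-specific read counting and the maternal-type call.

Reads are mapped semi-globally (read against a substring of the gene, both
orientations) to each 5S consensus under an error budget of
``floor(max_error_rate * read_length)`` mismatches-plus-gaps — the strictest
reading of a "1% per read" mapping policy.  A read is attributed to a
variant only when it covers at least one diagnostic site and every covered
site shows that variant's allele; conflicting, uncovered or off-allele
reads stay ambiguous rather than being split.

Per-tissue tallies then feed the maternal-type call: the NOR variant is
called maternal when its share of assigned reads is high in every
germline/embryo tissue and near zero in every somatic tissue.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import edlib

from .io import FastqRead
from .types import revcomp
from .variants import DiagnosticSite

logger = logging.getLogger("nor5s")

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


@dataclass(frozen=True)
class ReadPolicy:
    """Acceptance policy for read-to-gene alignments."""

    max_error_rate: float = 0.01
    min_overlap: int = 20

    def __post_init__(self) -> None:
        if not (0.0 <= self.max_error_rate <= 0.05):
            raise ValueError("max_error_rate must be in [0, 0.05]")
        if self.min_overlap < 1:
            raise ValueError("min_overlap must be >= 1")

    def allowed_errors(self, read_length: int) -> int:
        return int(self.max_error_rate * read_length)


@dataclass(frozen=True)
class MappedRead:
    """An accepted semi-global alignment of a read to a reference gene."""

    orientation: str  # "+" | "-"
    ref_start: int  # 0-based half-open on the reference
    ref_end: int
    n_errors: int  # mismatches + gap columns
    observed: dict[int, str]  # 1-based ref position -> read base (aligned cols only)


def _walk(cigar: str, ref_start: int, read_seq: str) -> dict[int, str]:
    observed: dict[int, str] = {}
    rpos, qpos = ref_start, 0
    for count, op in _CIGAR_RE.findall(cigar):
        count = int(count)
        if op in "=XM":
            for k in range(count):
                observed[rpos + k + 1] = read_seq[qpos + k]
            rpos += count
            qpos += count
        elif op == "I":
            qpos += count
        else:  # D
            rpos += count
    return observed


def map_read(
    read: str | FastqRead,
    reference: str,
    policy: ReadPolicy = ReadPolicy(),
) -> Optional[MappedRead]:
    """Best semi-global alignment of the read to the gene, both orientations.

    Returns None when the best alignment exceeds the error budget or covers
    less than ``min_overlap`` nt of the gene.
    """
    seq = read.residues if isinstance(read, FastqRead) else read
    if not seq:
        raise ValueError("empty read")
    budget = policy.allowed_errors(len(seq))
    best: Optional[tuple[int, str, str, dict]] = None
    for orientation, oriented in (("+", seq), ("-", revcomp(seq))):
        res = edlib.align(oriented, reference, mode="HW", task="path", k=max(budget, 0))
        if res["editDistance"] < 0:
            continue
        if best is None or res["editDistance"] < best[0]:
            best = (res["editDistance"], orientation, oriented, res)
    if best is None:
        return None
    dist, orientation, oriented, res = best
    start, end_incl = res["locations"][0]
    if end_incl - start + 1 < policy.min_overlap:
        return None
    return MappedRead(
        orientation,
        start,
        end_incl + 1,
        dist,
        _walk(res["cigar"], start, oriented),
    )


@dataclass(frozen=True)
class ReadAssignment:
    read_id: str
    label: str  # NOR | NTS | ambiguous | unassigned
    n_errors: Optional[int]  # vs the best accepted reference
    sites_covered: tuple[int, ...]  # 1-based positions
    bases_observed: tuple[str, ...]


def assign_read(
    read: FastqRead,
    nor_consensus: str,
    nts_consensus: str,
    sites: Sequence[DiagnosticSite],
    policy: ReadPolicy = ReadPolicy(),
) -> ReadAssignment:
    """Attribute one read to a 5S variant via its diagnostic-site alleles."""
    if not sites:
        raise ValueError("no diagnostic sites supplied")
    m_nts = map_read(read, nts_consensus, policy)
    m_nor = map_read(read, nor_consensus, policy)
    if m_nts is None and m_nor is None:
        return ReadAssignment(read.identifier, "unassigned", None, (), ())
    # read site alleles off the accepted alignment with fewer errors
    # (NTS frame on ties: site positions are NTS coordinates)
    if m_nor is None or (m_nts is not None and m_nts.n_errors <= m_nor.n_errors):
        mapped = m_nts
    else:
        mapped = m_nor
    covered: list[int] = []
    observed: list[str] = []
    votes: set[str] = set()
    for site in sites:
        base = mapped.observed.get(site.position)
        if base is None:
            continue
        covered.append(site.position)
        observed.append(base)
        if base == site.nor_base:
            votes.add("NOR")
        elif base == site.nts_base:
            votes.add("NTS")
        else:
            votes.add("off-allele")
    label = votes.pop() if len(votes) == 1 and votes != {"off-allele"} else "ambiguous"
    return ReadAssignment(
        read.identifier, label, mapped.n_errors, tuple(covered), tuple(observed)
    )


@dataclass
class TissueQuant:
    """Per-tissue tallies of variant-attributed reads."""

    tissue: str
    n_nor: int = 0
    n_nts: int = 0
    n_ambiguous: int = 0
    n_unassigned: int = 0

    @property
    def total(self) -> int:
        return self.n_nor + self.n_nts + self.n_ambiguous + self.n_unassigned

    @property
    def pct_nor(self) -> Optional[float]:
        """NOR share of assigned reads, percent; None when nothing assigned."""
        assigned = self.n_nor + self.n_nts
        return 100.0 * self.n_nor / assigned if assigned else None

    @property
    def pct_nor_of_total(self) -> Optional[float]:
        """NOR share over all 5S-overlapping reads (alternative denominator)."""
        return 100.0 * self.n_nor / self.total if self.total else None


def quantify_tissue(assignments: Iterable[ReadAssignment], tissue: str) -> TissueQuant:
    quant = TissueQuant(tissue)
    for a in assignments:
        if a.label == "NOR":
            quant.n_nor += 1
        elif a.label == "NTS":
            quant.n_nts += 1
        elif a.label == "ambiguous":
            quant.n_ambiguous += 1
        else:
            quant.n_unassigned += 1
    if quant.n_nor + quant.n_nts == 0:
        logger.warning("tissue %s: no variant-assigned reads; pct_nor unavailable", tissue)
    return quant


@dataclass(frozen=True)
class MaternalCall:
    """Outcome of the maternal-type test for the NOR variant."""

    variant: str
    germline_tissues: tuple[str, ...]
    somatic_tissues: tuple[str, ...]
    pct_by_tissue: dict[str, Optional[float]]
    is_maternal_type: bool
    germline_min: float
    somatic_max: float


def call_maternal(
    quants: Sequence[TissueQuant],
    germline_tissues: Sequence[str],
    somatic_tissues: Sequence[str],
    germline_min: float = 50.0,
    somatic_max: float = 5.0,
) -> MaternalCall:
    """Call the NOR variant maternal-type when it dominates every
    germline/embryo tissue and is (practically) absent from every somatic
    tissue."""
    by_tissue = {q.tissue: q for q in quants}
    for tissue in list(germline_tissues) + list(somatic_tissues):
        if tissue not in by_tissue:
            raise ValueError(f"tissue {tissue!r} missing from quantifications")
    if not germline_tissues or not somatic_tissues:
        raise ValueError("need at least one germline and one somatic tissue")
    pct = {q.tissue: q.pct_nor for q in quants}
    ok = all(
        pct[t] is not None and pct[t] >= germline_min for t in germline_tissues
    ) and all(pct[t] is not None and pct[t] <= somatic_max for t in somatic_tissues)
    return MaternalCall(
        "NOR-5S",
        tuple(germline_tissues),
        tuple(somatic_tissues),
        pct,
        ok,
        germline_min,
        somatic_max,
    )
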