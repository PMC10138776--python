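"""Consensus building and diagnostic-site calling for the two 5S classes.

Gene copies of each class (the IGS-inserted NOR-5S copies and the clustered
canonical NTS-5S copies) are multiple-aligned by the center-star method,
collapsed to a majority-rule consensus with IUPAC codes at ties, and the
two consensuses are compared end-to-end.  Substitution columns with
distinct, unambiguous bases become diagnostic sites — the positions that
let individual RNA-seq reads be attributed to one variant.  Indel and
ambiguity columns are reported separately, never as sites.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .align import DEFAULT_SCORING, ScoringScheme, global_align, pairwise_identity

# base-set -> IUPAC ambiguity code
_IUPAC = {
    frozenset("A"): "A", frozenset("C"): "C", frozenset("G"): "G", frozenset("T"): "T",
    frozenset("AG"): "R", frozenset("CT"): "Y", frozenset("CG"): "S", frozenset("AT"): "W",
    frozenset("GT"): "K", frozenset("AC"): "M",
    frozenset("CGT"): "B", frozenset("AGT"): "D", frozenset("ACT"): "H", frozenset("ACG"): "V",
    frozenset("ACGT"): "N",
}


def align_copies(
    copies: list[str], scoring: ScoringScheme = DEFAULT_SCORING
) -> list[str]:
    """Center-star multiple alignment.

    The copy with the highest summed pairwise identity to all others is the
    center; every other copy is globally aligned to it and the pairwise
    alignments are merged column-wise.  Adequate for near-identical gene
    copies; not a general-purpose aligner.
    """
    if not copies:
        raise ValueError("no copies to align")
    if len(copies) == 1:
        return [copies[0]]
    n = len(copies)
    sums = [0.0] * n
    for i in range(n):
        for j in range(i + 1, n):
            ident = pairwise_identity(copies[i], copies[j], scoring)
            sums[i] += ident
            sums[j] += ident
    center_idx = max(range(n), key=lambda i: (sums[i], -i))
    center = copies[center_idx]
    others = [c for i, c in enumerate(copies) if i != center_idx]

    pair_alns = [global_align(center, o, scoring)[1:] for o in others]

    # slot g = number of inserted columns before center position i (i=0..L)
    L = len(center)
    slots = [0] * (L + 1)
    for aln_c, _ in pair_alns:
        pos = 0
        run = 0
        for ch in aln_c:
            if ch == "-":
                run += 1
            else:
                slots[pos] = max(slots[pos], run)
                run = 0
                pos += 1
        slots[L] = max(slots[L], run)

    def expand(aln_c: str, aln_o: str) -> str:
        out: list[str] = []
        pos = 0
        buf: list[str] = []
        for cc, oc in zip(aln_c, aln_o):
            if cc == "-":
                buf.append(oc)
            else:
                out.append("-" * (slots[pos] - len(buf)) + "".join(buf))
                buf = []
                out.append(oc)
                pos += 1
        out.append("-" * (slots[L] - len(buf)) + "".join(buf))
        return "".join(out)

    center_row = "".join(
        "-" * slots[i] + (center[i] if i < L else "") for i in range(L + 1)
    )
    rows = [expand(aln_c, aln_o) for aln_c, aln_o in pair_alns]
    rows.insert(center_idx, center_row)
    assert len({len(r) for r in rows}) == 1
    return rows


@dataclass
class ConsensusVariant:
    """Majority-rule consensus of one 5S gene class."""

    label: str  # "NOR-5S" | "NTS-5S"
    sequence: str
    column_counts: list[dict[str, int]] = field(repr=False, default_factory=list)
    n_copies: int = 0


def build_consensus(msa: list[str], label: str) -> ConsensusVariant:
    """Per-column majority base; ties become IUPAC codes; columns gapped in
    more than half the rows are dropped."""
    if not msa:
        raise ValueError("empty alignment")
    n = len(msa)
    width = len(msa[0])
    seq: list[str] = []
    counts: list[dict[str, int]] = []
    for col in range(width):
        column = [row[col].upper() for row in msa]
        tally: dict[str, int] = {}
        for ch in column:
            tally[ch] = tally.get(ch, 0) + 1
        if tally.get("-", 0) * 2 > n:
            continue
        base_tally = {b: c for b, c in tally.items() if b != "-"}
        top = max(base_tally.values())
        tied = frozenset(b for b, c in base_tally.items() if c == top)
        seq.append(_IUPAC.get(tied, "N"))
        counts.append(tally)
    return ConsensusVariant(label, "".join(seq), counts, n)


@dataclass(frozen=True)
class DiagnosticSite:
    """A gene position (1-based, NTS-5S coordinates) separating the variants."""

    position: int
    nts_base: str
    nor_base: str

    def __post_init__(self) -> None:
        if self.nts_base == self.nor_base:
            raise ValueError("diagnostic site bases must differ")
        if self.nts_base not in "ACGT" or self.nor_base not in "ACGT":
            raise ValueError("diagnostic site bases must be unambiguous")


@dataclass
class DiagnosticCallResult:
    sites: list[DiagnosticSite]
    indel_columns: list[int]  # 1-based NTS positions flanking indels
    ambiguous_columns: list[int]


def call_diagnostic_sites(
    nor: ConsensusVariant,
    nts: ConsensusVariant,
    scoring: ScoringScheme = DEFAULT_SCORING,
) -> DiagnosticCallResult:
    """Global end-to-end comparison of the two consensuses.

    Positions are reported in NTS-5S gene coordinates.  Swapping the inputs
    swaps the base labels but never the positions.
    """
    _, aln_nts, aln_nor = global_align(nts.sequence, nor.sequence, scoring)
    sites: list[DiagnosticSite] = []
    indels: list[int] = []
    ambiguous: list[int] = []
    pos = 0  # 1-based NTS position of the current column
    for cn, cr in zip(aln_nts, aln_nor):
        if cn != "-":
            pos += 1
        if cn == "-" or cr == "-":
            indels.append(pos)
            continue
        if cn == cr:
            continue
        if cn in "ACGT" and cr in "ACGT":
            sites.append(DiagnosticSite(pos, cn, cr))
        else:
            ambiguous.append(pos)
    return DiagnosticCallResult(sites, indels, ambiguous)


@dataclass(frozen=True)
class IcrCoords:
    """1-based inclusive intervals of the RNA-polymerase-III internal
    control region: the TFIIIA footprint of the 5S gene."""

    a_box: tuple[int, int] = (50, 64)
    intermediate_element: tuple[int, int] = (67, 72)
    c_box: tuple[int, int] = (80, 97)

    def __post_init__(self) -> None:
        if not (self.a_box < self.intermediate_element < self.c_box):
            raise ValueError("ICR elements must be ordered A-box < IE < C-box")


@dataclass(frozen=True)
class ICRAnnotation:
    a_box: tuple[int, int]
    intermediate_element: tuple[int, int]
    c_box: tuple[int, int]
    identical_between_variants: bool


def annotate_icr(
    gene_sequence: str,
    other_variant: str | None = None,
    coords: IcrCoords = IcrCoords(),
) -> ICRAnnotation:
    """Locate the ICR at the configured canonical coordinates and, when a
    second variant is supplied, test whether the ICR is identical in both
    (substitutions in the TFIIIA binding region would question the insert's
    functionality)."""
    end_needed = coords.c_box[1]
    for seq in (gene_sequence, other_variant):
        if seq is not None and len(seq) < end_needed:
            raise ValueError(f"gene length {len(seq)} shorter than C-box end {end_needed}")
    identical = True
    if other_variant is not None:
        for lo, hi in (coords.a_box, coords.intermediate_element, coords.c_box):
            if gene_sequence[lo - 1 : hi] != other_variant[lo - 1 : hi]:
                identical = False
                break
    return ICRAnnotation(
        coords.a_box, coords.intermediate_element, coords.c_box, identical
    )
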