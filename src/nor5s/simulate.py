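"""Synthetic rDNA genomes and read sets with full ground truth.

The generator emulates the genomic situation the pipeline is built to
detect: a contig of tandem 45S units (18S-ITS1-5.8S-ITS2-28S) whose
intergenic spacer carries labelled tandem-repeat blocks and, in a unique
region, a reverse-oriented 5S gene copy preceded (in gene orientation) by a
conserved 24-nt flank and followed by a short polyA linker; a second contig
with a tandem cluster of the canonical 5S gene; and per-tissue read sets
drawn from stated mixtures of the two 5S variants with i.i.d. substitution
errors.

Background sequence is i.i.d. uniform over A/C/G/T, which makes spurious
homology maximally visible as a bug.  Every planted feature is recorded in
a :class:`TruthRecord` so downstream stages can be tested by parameter
recovery rather than by eye.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Optional

import numpy as np

from .io import FastqRead
from .structure import canonical_fives_template, can_pair
from .types import FORWARD, REVERSE, GenomicInterval, SequenceRecord, revcomp

_BASES = np.array(list("ACGT"))

# Complement choices used when building a template-compatible gene.
_WC = {"A": "T", "T": "A", "C": "G", "G": "C"}


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


@lru_cache(maxsize=1)
def default_base_gene() -> str:
    """A synthetic 119-nt 5S-like gene compatible with the canonical template.

    Paired template positions receive Watson-Crick partners; loop positions
    are random under a fixed generator, so the sequence is reproducible and
    folds into the five-helix layout.  It is a synthetic stand-in, not any
    species' real 5S sequence.
    """
    rng = np.random.default_rng(53219)
    template = canonical_fives_template()
    chars: list[Optional[str]] = [None] * 119
    for i, j in sorted(template.pairs):
        base = str(_BASES[rng.integers(0, 4)])
        chars[i - 1] = base
        chars[j - 1] = _WC[base]
    for idx in range(119):
        if chars[idx] is None:
            chars[idx] = str(_BASES[rng.integers(0, 4)])
    seq = "".join(chars)
    assert all(can_pair(seq[i - 1], seq[j - 1]) for i, j in template.pairs)
    return seq


@dataclass(frozen=True)
class Substitution:
    """A single diagnostic substitution between the two 5S variants."""

    position: int  # 1-based within the gene
    nts_base: str
    nor_base: str


@dataclass(frozen=True)
class VariantPairSpec:
    """Base 5S gene plus the substitutions separating NTS-5S from NOR-5S."""

    base_sequence: str
    substitutions: tuple[Substitution, ...]

    def __post_init__(self) -> None:
        last = 0
        for sub in self.substitutions:
            if not (1 <= sub.position <= len(self.base_sequence)):
                raise ValueError(f"substitution position {sub.position} out of range")
            if sub.position <= last:
                raise ValueError("substitution positions must be strictly increasing")
            if sub.nts_base == sub.nor_base:
                raise ValueError(f"identical bases at position {sub.position}")
            last = sub.position


def default_variant_pair() -> VariantPairSpec:
    """The study-condition variant pair: substitutions at positions 2, 23, 112.

    All three positions are loop-positioned in the canonical template, so
    the substitutions leave the secondary structure intact.
    """
    base = default_base_gene()
    subs = []
    for pos, nor_base in ((2, "G"), (23, "C"), (112, "T")):
        nts_base = base[pos - 1]
        if nts_base == nor_base:  # pragma: no cover - depends on fixed gene
            nor_base = "A" if nts_base != "A" else "G"
        subs.append(Substitution(pos, nts_base, nor_base))
    return VariantPairSpec(base, tuple(subs))


def make_variant_pair(spec: VariantPairSpec) -> tuple[str, str]:
    """Materialise (nts_sequence, nor_sequence) from a variant-pair spec."""
    nts = list(spec.base_sequence)
    nor = list(spec.base_sequence)
    for sub in spec.substitutions:
        nts[sub.position - 1] = sub.nts_base
        nor[sub.position - 1] = sub.nor_base
    return "".join(nts), "".join(nor)


@dataclass(frozen=True)
class BlockSpec:
    """One tandem-repeat block of the IGS."""

    label: str
    monomer: str
    copy_count: int

    def __post_init__(self) -> None:
        if len(self.monomer) < 2:
            raise ValueError("monomer length must be >= 2")
        if self.copy_count < 1:
            raise ValueError("copy_count must be >= 1")


@dataclass(frozen=True)
class InsertSpec:
    """Placement of the 5S copy inside the IGS.

    ``offset_from_28S`` is the distance, in unit orientation, from the 28S
    3' end to the insert boundary nearest the 28S gene.
    """

    present: bool = True
    orientation: str = "opposite"  # "same" | "opposite"
    offset_from_28S: int = 960
    polyA_length: int = 12
    conserved_flank: str = "TACCGGTTAACGCATTGGACGTCA"  # 24 nt

    def __post_init__(self) -> None:
        if self.orientation not in ("same", "opposite"):
            raise ValueError("orientation must be 'same' or 'opposite'")
        if self.polyA_length < 0 or self.offset_from_28S < 0:
            raise ValueError("negative insert geometry")


@dataclass(frozen=True)
class RdnaUnitSpec:
    """Geometry of one 45S repeat unit and its IGS."""

    len_18s: int = 1800
    len_58s: int = 160
    len_28s: int = 4000
    len_5s: int = 119
    len_its1: int = 300
    len_its2: int = 300
    igs_blocks: tuple[BlockSpec, ...] = ()
    block_gap: int = 150
    igs_tail: int = 300
    insert: InsertSpec = field(default_factory=InsertSpec)
    unit_copies: int = 3
    nts_cluster_copies: int = 8
    nts_spacer_length: int = 120
    pad: int = 400

    def __post_init__(self) -> None:
        labels = [b.label for b in self.igs_blocks]
        if len(labels) != len(set(labels)):
            raise ValueError("block labels must be unique")
        if self.unit_copies < 1:
            raise ValueError("unit_copies must be >= 1")


def default_block_specs(rng: np.random.Generator) -> tuple[BlockSpec, ...]:
    """Three generically labelled blocks mirroring the typical IGS layout:
    two repeat families between 28S and the insert, one downstream."""
    return (
        BlockSpec("NR1", _random_seq(rng, 37), 8),
        BlockSpec("NR2", _random_seq(rng, 52), 6),
        BlockSpec("NR5", _random_seq(rng, 29), 5),
    )


@dataclass(frozen=True)
class PlantedFeature:
    interval: GenomicInterval
    feature_class: str  # controlled vocabulary of types.FEATURE_TYPES
    label: str


@dataclass
class TruthRecord:
    """Ground truth of one synthetic genome."""

    features: dict[str, list[PlantedFeature]] = field(default_factory=dict)
    genes: dict[str, str] = field(default_factory=dict)  # name -> sequence

    def add(self, contig_id: str, start: int, end: int, strand: str,
            feature_class: str, label: str) -> None:
        self.features.setdefault(contig_id, []).append(
            PlantedFeature(GenomicInterval(contig_id, start, end, strand),
                           feature_class, label)
        )

    def of_class(self, contig_id: str, feature_class: str) -> list[PlantedFeature]:
        return [f for f in self.features.get(contig_id, [])
                if f.feature_class == feature_class]


def _build_igs(
    spec: RdnaUnitSpec,
    nor_gene: str,
    rng: np.random.Generator,
    unique_pool: dict[str, str],
) -> tuple[str, list[tuple[int, int, str, str, str]]]:
    """Assemble one IGS in unit orientation.

    Returns the sequence and local features ``(start, end, strand,
    feature_class, label)`` with strand relative to the unit.  Unique-region
    filler is drawn once per genome (``unique_pool``) so that every unit's
    IGS is identical, as in a homogenised tandem array.
    """
    parts: list[str] = []
    feats: list[tuple[int, int, str, str, str]] = []
    pos = 0

    def emit(seq: str, cls: str | None = None, label: str = "", strand: str = FORWARD) -> None:
        nonlocal pos
        parts.append(seq)
        if cls is not None:
            feats.append((pos, pos + len(seq), strand, cls, label))
        pos += len(seq)

    def unique(key: str, length: int) -> str:
        if key not in unique_pool:
            unique_pool[key] = _random_seq(rng, length)
        return unique_pool[key]

    segments: list[tuple[str, BlockSpec | None]] = []
    for i, block in enumerate(spec.igs_blocks):
        segments.append((f"gap{i}", None))
        segments.append((block.label, block))
    segments.append(("tail", None))

    ins = spec.insert
    cassette = ""
    cassette_feats: list[tuple[int, int, str, str, str]] = []
    insert_at = None
    if ins.present:
        flank = ins.conserved_flank
        # 8 non-A guard bases keep the planted polyA maximal, so its truth
        # interval is exactly what a tolerant run detector should return
        guard = "".join(np.array(list("CGT"))[rng.integers(0, 3, size=8)]) if ins.polyA_length else ""
        gene_oriented = flank + nor_gene + "A" * ins.polyA_length + guard
        if ins.orientation == "opposite":
            cassette = revcomp(gene_oriented)
            gstrand = REVERSE
            # genomic (unit-orientation) layout: [guard'][polyA'][gene'][flank']
            off = len(guard)
            if ins.polyA_length:
                cassette_feats.append((off, off + ins.polyA_length, gstrand, "polyA", "polyA"))
            off += ins.polyA_length
            cassette_feats.append((off, off + len(nor_gene), gstrand, "fiveS_insert", "NOR-5S"))
            off += len(nor_gene)
            cassette_feats.append((off, off + len(flank), gstrand, "unique_region", "conserved_flank"))
            insert_at = ins.offset_from_28S - ins.polyA_length - len(guard)
        else:
            cassette = gene_oriented
            gstrand = FORWARD
            off = 0
            cassette_feats.append((off, off + len(flank), gstrand, "unique_region", "conserved_flank"))
            off += len(flank)
            cassette_feats.append((off, off + len(nor_gene), gstrand, "fiveS_insert", "NOR-5S"))
            off += len(nor_gene)
            if ins.polyA_length:
                cassette_feats.append((off, off + ins.polyA_length, gstrand, "polyA", "polyA"))
            insert_at = ins.offset_from_28S - len(flank)
        if insert_at < 0:
            raise ValueError("offset_from_28S too small for the insert cassette")

    cursor = 0
    placed = not ins.present
    for key, block in segments:
        if block is None:
            length = spec.igs_tail if key == "tail" else spec.block_gap
            if not placed and cursor <= insert_at <= cursor + length:
                head = insert_at - cursor
                emit(unique(key, length)[:head])
                for s, e, st, cls, lab in cassette_feats:
                    feats.append((pos + s, pos + e, st, cls, lab))
                emit(cassette)
                emit(unique(key, length)[head:])
                placed = True
            else:
                emit(unique(key, length))
            cursor += length
        else:
            array = block.monomer * block.copy_count
            if not placed and cursor <= insert_at < cursor + len(array):
                raise ValueError(
                    f"insert offset {ins.offset_from_28S} falls inside block {block.label}"
                )
            emit(array, "tandem_repeat", block.label)
            cursor += len(array)
    if not placed:
        raise ValueError("offset_from_28S beyond the IGS span")
    return "".join(parts), feats


def build_genome(
    unit_spec: RdnaUnitSpec,
    variant_pair: VariantPairSpec,
    seed: int,
    name: str = "syn",
) -> tuple[list[SequenceRecord], TruthRecord]:
    """Generate the two-contig synthetic genome and its ground truth.

    Contig ``<name>_nor`` carries ``unit_copies`` tandem 45S units with the
    NOR-5S insert in each IGS; contig ``<name>_nts`` carries the canonical
    clustered NTS-5S genes.
    """
    rng = np.random.default_rng(seed)
    nts_gene, nor_gene = make_variant_pair(variant_pair)
    if len(nts_gene) != unit_spec.len_5s:
        raise ValueError("len_5s does not match the variant sequences supplied")

    genes = {
        "18S": _random_seq(rng, unit_spec.len_18s),
        "5.8S": _random_seq(rng, unit_spec.len_58s),
        "28S": _random_seq(rng, unit_spec.len_28s),
        "5S": nts_gene,
        "5S_NOR": nor_gene,
    }
    its1 = _random_seq(rng, unit_spec.len_its1)
    its2 = _random_seq(rng, unit_spec.len_its2)
    blocks = unit_spec.igs_blocks or default_block_specs(rng)
    unit_spec = dataclasses.replace(unit_spec, igs_blocks=blocks)

    truth = TruthRecord(genes=genes)
    nor_contig_id = f"{name}_nor"
    unique_pool: dict[str, str] = {}
    igs_seq, igs_feats = _build_igs(unit_spec, nor_gene, rng, unique_pool)

    parts = [_random_seq(rng, unit_spec.pad)]
    pos = unit_spec.pad
    for _ in range(unit_spec.unit_copies):
        for gene_name, spacer in (("18S", its1), ("5.8S", its2), ("28S", None)):
            seq = genes[gene_name]
            truth.add(nor_contig_id, pos, pos + len(seq), FORWARD, "rRNA_gene", gene_name)
            parts.append(seq)
            pos += len(seq)
            if spacer is not None:
                parts.append(spacer)
                pos += len(spacer)
        truth.add(nor_contig_id, pos, pos + len(igs_seq), FORWARD, "IGS", "IGS")
        for s, e, strand, cls, lab in igs_feats:
            truth.add(nor_contig_id, pos + s, pos + e, strand, cls, lab)
        parts.append(igs_seq)
        pos += len(igs_seq)
    parts.append(_random_seq(rng, unit_spec.pad))
    nor_contig = SequenceRecord(nor_contig_id, "".join(parts), "synthetic 45S array")

    # canonical cluster contig
    nts_contig_id = f"{name}_nts"
    spacer = _random_seq(rng, unit_spec.nts_spacer_length)
    parts = [_random_seq(rng, unit_spec.pad)]
    pos = unit_spec.pad
    for _ in range(unit_spec.nts_cluster_copies):
        truth.add(nts_contig_id, pos, pos + len(nts_gene), FORWARD, "fiveS_insert", "NTS-5S")
        parts.append(nts_gene)
        pos += len(nts_gene)
        parts.append(spacer)
        pos += len(spacer)
    parts.append(_random_seq(rng, unit_spec.pad))
    nts_contig = SequenceRecord(nts_contig_id, "".join(parts), "synthetic 5S cluster")

    return [nor_contig, nts_contig], truth


@dataclass(frozen=True)
class ReadSimSpec:
    """One tissue's read-simulation conditions."""

    tissue: str
    fraction_nor: float
    depth: int
    read_length: int = 100
    error_rate: float = 0.003
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.fraction_nor <= 1.0):
            raise ValueError("fraction_nor must be in [0, 1]")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if not (0.0 <= self.error_rate <= 0.05):
            raise ValueError("error_rate must be in [0, 0.05]")


def simulate_reads(
    spec: ReadSimSpec, nts_sequence: str, nor_sequence: str
) -> tuple[list[FastqRead], dict[str, str]]:
    """Draw single-end reads from a two-variant mixture.

    Each read comes from a uniformly random window of the variant chosen
    Bernoulli(``fraction_nor``); substitution errors are i.i.d. per base.
    Returns the reads and a read-id -> true-variant-label map.
    """
    if spec.read_length > min(len(nts_sequence), len(nor_sequence)):
        raise ValueError("read_length exceeds gene length")
    rng = np.random.default_rng(spec.seed)
    reads: list[FastqRead] = []
    labels: dict[str, str] = {}
    for i in range(spec.depth):
        is_nor = rng.random() < spec.fraction_nor
        source = nor_sequence if is_nor else nts_sequence
        start = int(rng.integers(0, len(source) - spec.read_length + 1))
        bases = list(source[start : start + spec.read_length])
        n_err = 0
        for b in range(spec.read_length):
            if rng.random() < spec.error_rate:
                choices = [c for c in "ACGT" if c != bases[b]]
                bases[b] = choices[int(rng.integers(0, 3))]
                n_err += 1
        rid = f"{spec.tissue}_{i}"
        reads.append(FastqRead(rid, "".join(bases), "I" * spec.read_length))
        labels[rid] = "NOR" if is_nor else "NTS"
    return reads, labels


def mutate_copies(
    gene: str, n_copies: int, mutation_rate: float, seed: int
) -> list[str]:
    """Independent gene copies with i.i.d. substitution noise (no indels).

    Emulates the sequencing/assembly noise seen across clustered gene
    copies in WGS contigs.
    """
    rng = np.random.default_rng(seed)
    copies = []
    for _ in range(n_copies):
        bases = list(gene)
        for i in range(len(bases)):
            if rng.random() < mutation_rate:
                choices = [c for c in "ACGT" if c != bases[i]]
                bases[i] = choices[int(rng.integers(0, 3))]
        copies.append("".join(bases))
    return copies
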