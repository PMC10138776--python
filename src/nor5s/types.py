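"""Core coordinate and sequence types shared across the pipeline.

Conventions
-----------
* All internal coordinates are 0-based, half-open ``[start, end)``.
* Emitted GFF3 coordinates are 1-based, inclusive (conversion happens in
  :mod:`nor5s.io` only).
* Strand is ``"+"`` (forward) or ``"-"`` (reverse).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

FORWARD = "+"
REVERSE = "-"

#: Controlled vocabulary for annotation feature types.
FEATURE_TYPES = (
    "rRNA_gene",
    "IGS",
    "tandem_repeat",
    "fiveS_insert",
    "polyA",
    "unique_region",
)

_COMPLEMENT = str.maketrans(
    "ACGTUNRYSWKMBDHVacgtunryswkmbdhv",
    "TGCAANYRSWMKVHDBtgcaanyrswmkvhdb",
)

IUPAC_CODES = set("ACGTUNRYSWKMBDHV")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (IUPAC aware)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SequenceRecord:
    """A named nucleotide sequence (FASTA record)."""

    identifier: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"empty sequence for record {self.identifier!r}")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A stranded half-open interval on a contig (0-based)."""

    contig_id: str
    start: int
    end: int
    strand: str = FORWARD

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.contig_id}"
            )
        if self.strand not in (FORWARD, REVERSE):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.contig_id == other.contig_id
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.contig_id == other.contig_id
            and self.start <= other.start
            and other.end <= self.end
        )

    def slice(self, residues: str) -> str:
        """Extract this interval from a contig sequence, in strand orientation."""
        s = residues[self.start : self.end]
        return revcomp(s) if self.strand == REVERSE else s

    def flipped(self, contig_length: int) -> "GenomicInterval":
        """Mirror the interval onto the reverse-complemented contig."""
        return GenomicInterval(
            self.contig_id,
            contig_length - self.end,
            contig_length - self.start,
            REVERSE if self.strand == FORWARD else FORWARD,
        )


@dataclass
class RunConfig:
    """Parameters of one end-to-end pipeline run.

    Every numeric knob is range-checked in :meth:`validate`; the seed is
    echoed in every report so that reruns are reproducible.
    """

    reference_path: Optional[Path] = None
    genome_path: Optional[Path] = None
    reads: dict[str, Path] = field(default_factory=dict)  # tissue -> FASTQ
    outdir: Path = Path("nor5s_out")
    seed: int = 42

    # homology scan
    seed_k: int = 13
    min_identity: float = 70.0
    min_coverage: float = 50.0
    max_unit_span: int = 20_000

    # repeat detection
    min_period: int = 5
    max_period: int = 2000
    min_copies: float = 2.5
    min_match: float = 0.8

    # read policy
    max_error_rate: float = 0.01
    min_overlap: int = 20

    germline_tissues: tuple[str, ...] = ("ovary", "embryo")
    somatic_tissues: tuple[str, ...] = ("testis", "liver", "kidney", "heart", "spleen")

    def validate(self) -> None:
        if self.reference_path is None or self.genome_path is None:
            raise ValueError("reference_path and genome_path are required")
        checks = [
            (1 <= self.seed_k <= 31, "seed_k must be in [1, 31]"),
            (0 < self.min_identity <= 100, "min_identity must be in (0, 100]"),
            (0 < self.min_coverage <= 100, "min_coverage must be in (0, 100]"),
            (self.max_unit_span > 0, "max_unit_span must be positive"),
            (2 <= self.min_period <= self.max_period, "bad repeat period range"),
            (self.min_copies >= 1, "min_copies must be >= 1"),
            (0 < self.min_match <= 1, "min_match must be in (0, 1]"),
            (0 <= self.max_error_rate <= 0.05, "max_error_rate must be in [0, 0.05]"),
            (self.min_overlap >= 1, "min_overlap must be >= 1"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ValueError(msg)
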