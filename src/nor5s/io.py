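"""Reading and writing the standard formats the pipeline speaks.

FASTA parsing is strict: headers and residues are validated with line
numbers so that malformed genome downloads fail loudly rather than
propagating into the scan.  FASTQ goes through Biopython's fast iterator
(gzip accepted by extension).  GFF3 output converts the package's 0-based
half-open intervals to the format's 1-based inclusive convention.
"""

from __future__ import annotations

import gzip
import logging
from pathlib import Path
from typing import Iterable, Iterator, NamedTuple, Sequence, TextIO, Union

from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .types import FEATURE_TYPES, GenomicInterval, IUPAC_CODES, SequenceRecord

logger = logging.getLogger("nor5s")

PathLike = Union[str, Path]


class ParseError(ValueError):
    """Raised on malformed input, with file and line context."""


class FastqRead(NamedTuple):
    identifier: str
    residues: str
    qualities: str


class GffFeature(NamedTuple):
    """One GFF3 row, carried internally in 0-based half-open coordinates."""

    interval: GenomicInterval
    feature_type: str
    attributes: dict[str, str]
    source: str = "nor5s"
    score: str = "."


def _open_text(path: PathLike) -> TextIO:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def read_fasta(path: PathLike) -> list[SequenceRecord]:
    """Read a FASTA file into a list of :class:`SequenceRecord`.

    Residues are upper-cased; record order is preserved.  Malformed
    headers, duplicate identifiers and non-IUPAC characters raise
    :class:`ParseError` naming the offending line.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    header: str | None = None
    desc = ""
    chunks: list[str] = []
    header_line = 0

    def flush(line_no: int) -> None:
        nonlocal header, chunks
        if header is None:
            return
        residues = "".join(chunks)
        if not residues:
            raise ParseError(f"{path}:{header_line}: record {header!r} has no sequence")
        records.append(SequenceRecord(header, residues, desc))
        header, chunks = None, []

    with _open_text(path) as fh:
        line_no = 0
        for line_no, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(">"):
                flush(line_no)
                fields = line[1:].split(maxsplit=1)
                if not fields:
                    raise ParseError(f"{path}:{line_no}: empty FASTA header")
                header, desc = fields[0], fields[1] if len(fields) > 1 else ""
                header_line = line_no
                if header in seen:
                    raise ParseError(f"{path}:{line_no}: duplicate identifier {header!r}")
                seen.add(header)
            else:
                if header is None:
                    raise ParseError(f"{path}:{line_no}: sequence before first header")
                seq = line.strip().upper()
                bad = set(seq) - IUPAC_CODES
                if bad:
                    raise ParseError(
                        f"{path}:{line_no}: illegal character(s) {sorted(bad)}"
                    )
                chunks.append(seq)
        flush(line_no)
    if not records:
        logger.warning("no records in FASTA file %s", path)
    return records


def write_fasta(records: Iterable[SequenceRecord], path: PathLike, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            head = f">{rec.identifier}"
            if rec.description:
                head += f" {rec.description}"
            fh.write(head + "\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i : i + width] + "\n")


def read_fastq(path: PathLike) -> Iterator[FastqRead]:
    """Stream reads from a (possibly gzipped) 4-line FASTQ file.

    Biopython's iterator enforces the sequence/quality length match; its
    errors are re-raised as :class:`ParseError` naming the file.
    """
    with _open_text(path) as fh:
        try:
            for title, seq, qual in FastqGeneralIterator(fh):
                yield FastqRead(title.split()[0], seq.upper(), qual)
        except ValueError as exc:
            raise ParseError(f"{path}: {exc}") from exc


def write_fastq(reads: Iterable[FastqRead], path: PathLike) -> None:
    with open(path, "w") as fh:
        for read in reads:
            fh.write(f"@{read.identifier}\n{read.residues}\n+\n{read.qualities}\n")


def write_gff3(
    features: Sequence[GffFeature],
    path: PathLike,
    contig_lengths: dict[str, int] | None = None,
) -> None:
    """Serialise annotations as GFF3 (1-based inclusive, ``+``/``-`` strand).

    Feature types must come from the controlled vocabulary; with
    ``contig_lengths`` given, intervals outside their contig abort the
    whole write.
    """
    for feat in features:
        if feat.feature_type not in FEATURE_TYPES:
            raise ValueError(f"unknown feature type {feat.feature_type!r}")
        iv = feat.interval
        if contig_lengths is not None:
            length = contig_lengths.get(iv.contig_id)
            if length is not None and iv.end > length:
                raise ValueError(
                    f"interval [{iv.start}, {iv.end}) exceeds contig "
                    f"{iv.contig_id} (length {length}); refusing to write"
                )
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for feat in features:
            iv = feat.interval
            attrs = ";".join(f"{k}={v}" for k, v in feat.attributes.items()) or "."
            fh.write(
                "\t".join(
                    [
                        iv.contig_id,
                        feat.source,
                        feat.feature_type,
                        str(iv.start + 1),  # 0-based half-open -> 1-based inclusive
                        str(iv.end),
                        feat.score,
                        iv.strand,
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )


def read_gff3(path: PathLike) -> list[GffFeature]:
    """Read a GFF3 file back into 0-based half-open :class:`GffFeature` rows."""
    feats: list[GffFeature] = []
    with _open_text(path) as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ParseError(f"{path}:{line_no}: expected 9 columns, got {len(cols)}")
            contig, source, ftype, start, end, score, strand, _, attr_col = cols
            attrs = {}
            if attr_col != ".":
                for pair in attr_col.split(";"):
                    if pair:
                        key, _, value = pair.partition("=")
                        attrs[key] = value
            feats.append(
                GffFeature(
                    GenomicInterval(contig, int(start) - 1, int(end), strand),
                    ftype,
                    attrs,
                    source=source,
                    score=score,
                )
            )
    return feats


def write_tsv(rows: Sequence[dict], path: PathLike, columns: Sequence[str]) -> None:
    """Write one-row-per-record TSV with a fixed column order (diff-stable)."""
    with open(path, "w") as fh:
        fh.write("\t".join(columns) + "\n")
        for row in rows:
            fh.write("\t".join(str(row.get(c, "")) for c in columns) + "\n")
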