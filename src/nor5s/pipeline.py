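"""End-to-end driver: scan -> unit assembly -> IGS annotation -> variant
typing -> expression quantification, with TSV/GFF3 reporting.

Every stage consumes the previous stage's in-memory products; the driver
serialises them and a run log carrying all parameters and the seed, so two
runs with the same inputs and config produce byte-identical reports.
"""

from __future__ import annotations

import logging
import traceback
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from . import io
from .igs import (
    FiveSInsert,
    IgsAnnotation,
    RepeatParams,
    annotate_igs,
    classify_insert,
    conserved_prefix,
    detect_tandem_repeats,
    extract_igs,
    to_igs_local,
)
from .quantify import ReadPolicy, assign_read, call_maternal, quantify_tissue
from .scan import (
    ScanParams,
    assemble_units,
    fives_hits_in_igs,
    scan_genome,
    screen_cooccurrence,
)
from .structure import canonical_fives_template, fold_nussinov, thread_template
from .types import FORWARD, GenomicInterval, RunConfig, SequenceRecord
from .variants import align_copies, annotate_icr, build_consensus, call_diagnostic_sites

logger = logging.getLogger("nor5s")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineResult:
    status: int
    outputs: dict[str, Path] = field(default_factory=dict)
    candidates: list[str] = field(default_factory=list)
    inserts: list[FiveSInsert] = field(default_factory=list)
    diagnostic_sites: list = field(default_factory=list)
    conserved_prefix_length: Optional[int] = None
    tissue_quants: list = field(default_factory=list)
    maternal: Optional[object] = None


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute the full analysis described by ``config``.

    Raises :class:`PipelineError` naming the failing stage; outputs written
    before the failure remain on disk next to a ``FAILED`` marker.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result = PipelineResult(status=0)
    log_lines = [f"nor5s run", f"seed\t{config.seed}"]
    for key, value in sorted(vars(config).items()):
        log_lines.append(f"param\t{key}\t{value}")

    stage = "load-inputs"
    try:
        references = io.read_fasta(config.reference_path)
        contigs = io.read_fasta(config.genome_path)
        contig_lengths = {c.identifier: len(c) for c in contigs}
        ref_by_name = {r.identifier: r for r in references}
        if "5S" not in ref_by_name:
            raise ValueError("reference set must contain a record named 5S")

        stage = "scan"
        params = ScanParams(
            seed_k=config.seed_k,
            min_identity=config.min_identity,
            min_coverage=config.min_coverage,
        )
        hits_by_contig = scan_genome(contigs, references, params)
        hit_rows = [
            {
                "contig": cid,
                "gene": h.gene_name,
                "start": h.location.start + 1,
                "end": h.location.end,
                "strand": h.location.strand,
                "identity": h.identity,
                "coverage": h.query_coverage,
                "score": h.score,
            }
            for cid, hits in sorted(hits_by_contig.items())
            for h in hits
        ]
        io.write_tsv(
            hit_rows,
            outdir / "hits.tsv",
            ["contig", "gene", "start", "end", "strand", "identity", "coverage", "score"],
        )
        result.outputs["hits"] = outdir / "hits.tsv"

        stage = "assemble-units"
        units_by_contig = {
            cid: assemble_units(hits, contig_lengths[cid], config.max_unit_span)[0]
            for cid, hits in hits_by_contig.items()
        }
        unit_feats = []
        for cid in sorted(units_by_contig):
            for unit in units_by_contig[cid]:
                for gene_name in ("18S", "5.8S", "28S"):
                    hit = unit.hits[gene_name]
                    unit_feats.append(
                        io.GffFeature(hit.location, "rRNA_gene", {"Name": gene_name})
                    )
                if unit.igs_span is not None:
                    unit_feats.append(
                        io.GffFeature(
                            unit.igs_span,
                            "IGS",
                            {"partial": str(unit.igs_partial).lower()},
                        )
                    )
        io.write_gff3(unit_feats, outdir / "units.gff3", contig_lengths)
        result.outputs["units"] = outdir / "units.gff3"

        stage = "screen-cooccurrence"
        result.candidates = screen_cooccurrence(hits_by_contig, units_by_contig)
        log_lines.append("candidates\t" + ",".join(result.candidates))

        stage = "annotate-igs"
        contig_by_id = {c.identifier: c for c in contigs}
        ref_5s_len = len(ref_by_name["5S"])
        nor_copies: list[str] = []
        flanks: list[str] = []
        igs_feats: list[io.GffFeature] = []
        for cid in sorted(result.candidates):
            contig = contig_by_id[cid]
            units = units_by_contig[cid]
            for hit, unit in fives_hits_in_igs(hits_by_contig[cid], units):
                igs_seq, igs_span = extract_igs(unit, contig)
                blocks = detect_tandem_repeats(
                    igs_seq,
                    RepeatParams(
                        config.min_period,
                        min(config.max_period, len(igs_seq) // 2),
                        config.min_copies,
                        config.min_match,
                    ),
                    contig_id=cid,
                )
                insert = classify_insert(hit, unit, contig, blocks, ref_len=ref_5s_len)
                result.inserts.append(insert)
                nor_copies.append(insert.location.slice(contig.residues))
                flanks.append(insert.upstream_flank)
                annotation = annotate_igs(
                    igs_seq, [to_igs_local(insert.location, igs_span)], blocks
                )
                igs_feats.extend(
                    _segments_to_genomic(annotation, igs_span, cid)
                )
        io.write_gff3(igs_feats, outdir / "igs_architecture.gff3", contig_lengths)
        result.outputs["igs"] = outdir / "igs_architecture.gff3"

        stage = "flank-conservation"
        if len(flanks) >= 2:
            cons = conserved_prefix(flanks)
            result.conserved_prefix_length = cons.conserved_prefix_length
            log_lines.append(f"conserved_prefix_length\t{cons.conserved_prefix_length}")

        stage = "collect-nts-copies"
        nts_copies: list[str] = []
        for cid, hits in sorted(hits_by_contig.items()):
            units = units_by_contig[cid]
            in_igs = {id(h) for h, _ in fives_hits_in_igs(hits, units)}
            for hit in hits:
                if hit.gene_name != "5S" or id(hit) in in_igs:
                    continue
                if any(u.transcribed_span.overlaps(hit.location) for u in units):
                    continue
                iv = hit.full_gene_interval(ref_5s_len, contig_lengths[cid])
                nts_copies.append(iv.slice(contig_by_id[cid].residues))

        stage = "type-variants"
        sites = []
        nor_cons = nts_cons = None
        if nor_copies and nts_copies:
            nor_cons = build_consensus(align_copies(nor_copies), "NOR-5S")
            nts_cons = build_consensus(align_copies(nts_copies), "NTS-5S")
            io.write_fasta(
                [
                    SequenceRecord("NOR-5S", nor_cons.sequence, f"n={nor_cons.n_copies}"),
                    SequenceRecord("NTS-5S", nts_cons.sequence, f"n={nts_cons.n_copies}"),
                ],
                outdir / "consensus.fasta",
            )
            result.outputs["consensus"] = outdir / "consensus.fasta"
            call = call_diagnostic_sites(nor_cons, nts_cons)
            sites = call.sites
            result.diagnostic_sites = sites
            io.write_tsv(
                [
                    {"position": s.position, "nts_base": s.nts_base, "nor_base": s.nor_base}
                    for s in sites
                ],
                outdir / "diagnostic_sites.tsv",
                ["position", "nts_base", "nor_base"],
            )
            result.outputs["sites"] = outdir / "diagnostic_sites.tsv"

            icr = annotate_icr(nts_cons.sequence, nor_cons.sequence)
            template = (
                canonical_fives_template()
                if len(nts_cons.sequence) == 119
                else None
            )
            with open(outdir / "variant_report.txt", "w") as fh:
                fh.write(f"diagnostic_sites\t{[s.position for s in sites]}\n")
                fh.write(f"indel_columns\t{call.indel_columns}\n")
                fh.write(f"ambiguous_columns\t{call.ambiguous_columns}\n")
                fh.write(f"icr_identical\t{icr.identical_between_variants}\n")
                for cons in (nts_cons, nor_cons):
                    fold = fold_nussinov(cons.sequence.replace("N", "A"))
                    fh.write(f"{cons.label}_fold_pairs\t{len(fold.pairs)}\n")
                    fh.write(f"{cons.label}_dotbracket\t{fold.dot_bracket()}\n")
                    if template is not None:
                        fh.write(
                            f"{cons.label}_template_score\t"
                            f"{thread_template(cons.sequence, template)}"
                            f"/{len(template.pairs)}\n"
                        )
            result.outputs["variant_report"] = outdir / "variant_report.txt"

        stage = "quantify"
        if config.reads and nor_cons is not None and nts_cons is not None and sites:
            policy = ReadPolicy(config.max_error_rate, config.min_overlap)
            quants = []
            for tissue in sorted(config.reads):
                assignments = [
                    assign_read(read, nor_cons.sequence, nts_cons.sequence, sites, policy)
                    for read in io.read_fastq(config.reads[tissue])
                ]
                quants.append(quantify_tissue(assignments, tissue))
            result.tissue_quants = quants
            io.write_tsv(
                [
                    {
                        "tissue": q.tissue,
                        "n_nor": q.n_nor,
                        "n_nts": q.n_nts,
                        "n_ambiguous": q.n_ambiguous,
                        "n_unassigned": q.n_unassigned,
                        "pct_nor": "NA" if q.pct_nor is None else f"{q.pct_nor:.2f}",
                        "pct_nor_of_total": "NA"
                        if q.pct_nor_of_total is None
                        else f"{q.pct_nor_of_total:.2f}",
                    }
                    for q in quants
                ],
                outdir / "tissue_quant.tsv",
                ["tissue", "n_nor", "n_nts", "n_ambiguous", "n_unassigned", "pct_nor", "pct_nor_of_total"],
            )
            result.outputs["tissue_quant"] = outdir / "tissue_quant.tsv"

            present = {q.tissue for q in quants}
            germ = [t for t in config.germline_tissues if t in present]
            soma = [t for t in config.somatic_tissues if t in present]
            if germ and soma:
                result.maternal = call_maternal(quants, germ, soma)
                with open(outdir / "maternal_call.txt", "w") as fh:
                    fh.write(f"variant\t{result.maternal.variant}\n")
                    fh.write(f"is_maternal_type\t{result.maternal.is_maternal_type}\n")
                    fh.write(f"germline\t{','.join(germ)}\n")
                    fh.write(f"somatic\t{','.join(soma)}\n")
                    for tissue in sorted(result.maternal.pct_by_tissue):
                        pct = result.maternal.pct_by_tissue[tissue]
                        fh.write(
                            f"pct_nor\t{tissue}\t{'NA' if pct is None else f'{pct:.2f}'}\n"
                        )
                    fh.write(
                        "note\trRNA-depleted libraries underestimate 5S abundance; "
                        "percentages compare variants, not absolute expression\n"
                    )
                result.outputs["maternal"] = outdir / "maternal_call.txt"
    except Exception as exc:
        (outdir / "FAILED").write_text(
            f"stage: {stage}\n{traceback.format_exc()}"
        )
        log_lines.append(f"status\tFAILED at {stage}")
        (outdir / "run_log.txt").write_text("\n".join(log_lines) + "\n")
        raise PipelineError(stage, exc) from exc

    log_lines.append("status\tOK")
    (outdir / "run_log.txt").write_text("\n".join(log_lines) + "\n")
    result.outputs["log"] = outdir / "run_log.txt"
    return result


def _segments_to_genomic(
    annotation: IgsAnnotation, igs_span: GenomicInterval, contig_id: str
) -> list[io.GffFeature]:
    """Map IGS-local segments back to genomic coordinates."""
    feats = []
    class_to_type = {
        "repeat": "tandem_repeat",
        "unique": "unique_region",
        "polyA": "polyA",
        "fiveS_insert": "fiveS_insert",
    }
    for seg in annotation.segments:
        local = seg.interval
        if igs_span.strand == FORWARD:
            start, end = igs_span.start + local.start, igs_span.start + local.end
            strand = local.strand
        else:
            start, end = igs_span.end - local.end, igs_span.end - local.start
            strand = FORWARD if local.strand == "-" else "-"
        attrs = {}
        if seg.block_label:
            attrs["Name"] = seg.block_label
        feats.append(
            io.GffFeature(
                GenomicInterval(contig_id, start, end, strand),
                class_to_type[seg.seg_class],
                attrs,
            )
        )
    return feats
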