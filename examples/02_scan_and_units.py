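"""Locate rRNA genes, assemble 45S units and screen for NOR-5S candidates.

The screen flags contigs where a 5S copy co-occurs with 28S but lies
outside the 18S-5.8S-28S transcription unit — the signature of a 5S gene
inserted into the intergenic spacer.
"""

from nor5s.scan import assemble_units, scan_genome, screen_cooccurrence
from nor5s.simulate import RdnaUnitSpec, build_genome, default_variant_pair
from nor5s.types import SequenceRecord

contigs, truth = build_genome(RdnaUnitSpec(), default_variant_pair(), seed=42)
references = [SequenceRecord(n, truth.genes[n]) for n in ("18S", "5.8S", "28S", "5S")]

hits_by = scan_genome(contigs, references)
units_by = {}
for contig in contigs:
    hits = hits_by[contig.identifier]
    print(f"{contig.identifier}: {len(hits)} hits")
    for h in hits:
        print(
            f"  {h.gene_name:5s} {h.location.start:>6}-{h.location.end:<6} "
            f"{h.location.strand}  identity {h.identity:.1f}%  coverage {h.query_coverage:.1f}%"
        )
    units, unpaired = assemble_units(hits, len(contig))
    units_by[contig.identifier] = units
    for u in units:
        igs = "no IGS" if u.igs_span is None else (
            f"IGS {u.igs_span.start}-{u.igs_span.end}" + (" (partial)" if u.igs_partial else "")
        )
        print(f"  unit on {u.strand}: {u.transcribed_span.start}-{u.transcribed_span.end}, {igs}")

flagged = screen_cooccurrence(hits_by, units_by)
print(f"\nNOR-5S candidate contigs: {flagged}")
print("(the 45S-array contig is flagged; the plain 5S cluster is not)")
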