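"""Annotate the internal architecture of an intergenic spacer.

Finds the tandem-repeat blocks, segments the IGS, characterises the 5S
insert (orientation, distance to 28S, polyA linker) and measures how far
the sequence 5' of the insert is conserved across simulated species.
"""

from nor5s.igs import (
    annotate_igs,
    classify_insert,
    conserved_prefix,
    detect_tandem_repeats,
    extract_igs,
    to_igs_local,
)
from nor5s.scan import assemble_units, fives_hits_in_igs, scan_genome
from nor5s.simulate import RdnaUnitSpec, build_genome, default_variant_pair
from nor5s.types import SequenceRecord

pair = default_variant_pair()
flanks = []
for species in range(5):
    name = f"sp{species}"
    contigs, truth = build_genome(RdnaUnitSpec(), pair, seed=42 + species, name=name)
    refs = [SequenceRecord(n, truth.genes[n]) for n in ("18S", "5.8S", "28S", "5S")]
    hits_by = scan_genome(contigs, refs)
    units, _ = assemble_units(hits_by[f"{name}_nor"], len(contigs[0]))
    hit, unit = fives_hits_in_igs(hits_by[f"{name}_nor"], units)[0]
    igs_seq, igs_span = extract_igs(unit, contigs[0])
    blocks = detect_tandem_repeats(igs_seq, contig_id="IGS")
    insert = classify_insert(hit, unit, contigs[0], blocks, ref_len=119)
    flanks.append(insert.upstream_flank)

    if species == 0:
        print(f"IGS of {name}: {len(igs_seq)} nt, {len(blocks)} repeat blocks")
        for b in blocks:
            print(
                f"  {b.label}: period {b.period} nt x {b.copy_number} copies "
                f"at {b.location.start}-{b.location.end}"
            )
        print(
            f"insert: orientation {insert.orientation_vs_unit} vs unit, "
            f"{insert.distance_to_28S} nt from the 28S 3' end"
        )
        if insert.polyA is not None:
            print(f"polyA linker: {len(insert.polyA)} nt at the gene 3' side")
        ann = annotate_igs(igs_seq, [to_igs_local(insert.location, igs_span)], blocks)
        print("segmentation:", " | ".join(
            f"{s.seg_class}[{len(s.interval)}]" for s in ann.segments
        ))

res = conserved_prefix(flanks)
print(
    f"\nflank conservation over {len(flanks)} species: the first "
    f"{res.conserved_prefix_length} nt 5' of the insert are conserved"
)
print("(flanks are compared gene-proximal-first, anchored at the gene start)")
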