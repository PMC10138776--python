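"""Generate a synthetic rDNA dataset with full ground truth.

Builds a contig of three tandem 45S units whose intergenic spacer carries a
reverse-oriented 5S insert (flank + gene + polyA), plus a second contig
with the canonical clustered 5S gene, and prints what was planted where.
"""

from nor5s.simulate import RdnaUnitSpec, build_genome, default_variant_pair

pair = default_variant_pair()
print("planted substitutions (NTS -> NOR):")
for sub in pair.substitutions:
    print(f"  position {sub.position:3d}: {sub.nts_base} -> {sub.nor_base}")

contigs, truth = build_genome(RdnaUnitSpec(), pair, seed=42)
for contig in contigs:
    print(f"\ncontig {contig.identifier}: {len(contig)} nt")
    for feat in truth.features[contig.identifier][:10]:
        iv = feat.interval
        print(f"  {feat.feature_class:14s} {feat.label:16s} {iv.start:>6}-{iv.end:<6} {iv.strand}")
    extra = len(truth.features[contig.identifier]) - 10
    if extra > 0:
        print(f"  ... and {extra} more planted features")

# The truth record is the oracle every downstream stage is tested against:
# each interval, sliced from the contig, reproduces the planted sequence.
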