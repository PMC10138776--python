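"""IGS segmentation: repeat arrays, polyA linker, insert geometry and the
conserved 5' flank."""

from __future__ import annotations

import random

import pytest

from nor5s.igs import (
    RepeatParams,
    annotate_igs,
    classify_insert,
    conserved_prefix,
    detect_polyA,
    detect_tandem_repeats,
    extract_igs,
    harmonise_labels,
    monomer_identity,
    to_igs_local,
)
from nor5s.scan import assemble_units, fives_hits_in_igs, scan_genome
from nor5s.simulate import InsertSpec, RdnaUnitSpec, build_genome
from nor5s.types import GenomicInterval, SequenceRecord, revcomp


def random_seq(rng, n):
    return "".join(rng.choice("ACGT") for _ in range(n))


@pytest.fixture(scope="module")
def igs_context(genome, scanned):
    contigs, truth = genome
    hits_by, units_by = scanned
    cid = contigs[0].identifier
    hit, unit = fives_hits_in_igs(hits_by[cid], units_by[cid])[0]
    return contigs[0], truth, hit, unit


class TestExtractIgs:
    def test_forward_unit_matches_planted_igs(self, igs_context):
        contig, truth, _, unit = igs_context
        seq, span = extract_igs(unit, contig)
        planted = next(
            f for f in truth.of_class(contig.identifier, "IGS")
            if f.interval.start == span.start
        )
        assert seq == planted.interval.slice(contig.residues)

    def test_reverse_unit_gives_revcomp_slice(self, references, genome):
        contigs, _ = genome
        flipped = SequenceRecord("flip", revcomp(contigs[0].residues))
        hits_by = scan_genome([flipped], references)
        units, _ = assemble_units(hits_by["flip"], len(flipped))
        unit = next(u for u in units if u.igs_span is not None and not u.igs_partial)
        seq, span = extract_igs(unit, flipped)
        assert seq == revcomp(flipped.residues[span.start : span.end])

    def test_igs_ends_at_next_units_18s(self, igs_context, scanned):
        contig, truth, _, unit = igs_context
        _, units_by = scanned
        units = units_by[contig.identifier]
        complete = [u for u in units if not u.igs_partial]
        for u in complete:
            nxt = next(
                v for v in units if v.transcribed_span.start == u.igs_span.end
            )
            assert u.igs_span.end == nxt.hits["18S"].location.start

    def test_missing_igs_raises(self, igs_context):
        from nor5s.scan import RdnaUnit

        contig, _, _, unit = igs_context
        broken = RdnaUnit(unit.strand, unit.hits, unit.transcribed_span, None)
        with pytest.raises(ValueError, match="IGS"):
            extract_igs(broken, contig)


class TestTandemRepeats:
    def test_exact_array_recovered(self):
        rng = random.Random(31)
        monomer = random_seq(rng, 37)
        seq = random_seq(rng, 180) + monomer * 8 + random_seq(rng, 180)
        blocks = detect_tandem_repeats(seq)
        assert len(blocks) == 1
        b = blocks[0]
        assert b.period == 37
        # boundaries may shift by flank bases that genuinely match at the
        # period, so the contract is exactness of period and near-exact span
        assert abs(b.copy_number - 8.0) <= 0.2
        assert abs(b.location.start - 180) <= 4
        assert abs(b.location.end - (180 + 37 * 8)) <= 4
        assert monomer_identity(b.monomer_consensus, monomer) == 100.0

    def test_homopolymer_reported_as_period_one(self):
        rng = random.Random(32)
        seq = random_seq(rng, 100) + "A" * 50 + random_seq(rng, 100)
        blocks = detect_tandem_repeats(seq)
        assert len(blocks) == 1
        assert blocks[0].period == 1
        assert blocks[0].monomer_consensus == "A"

    def test_noisy_array_period_exact_copies_close(self):
        rng = random.Random(33)
        monomer = random_seq(rng, 41)
        array = list(monomer * 6)
        for i in range(len(array)):
            if rng.random() < 0.02:
                array[i] = rng.choice("ACGT")
        seq = random_seq(rng, 150) + "".join(array) + random_seq(rng, 150)
        blocks = detect_tandem_repeats(seq)
        assert len(blocks) == 1
        assert blocks[0].period == 41
        assert abs(blocks[0].copy_number - 6.0) <= 0.5

    def test_planted_arrays_recovered_across_random_periods(self):
        """Period exact and boundaries within one period for error-free
        arrays over a wide period range."""
        rng = random.Random(34)
        for _ in range(40):
            period = rng.randint(5, 500)
            copies = rng.randint(3, 6)
            monomer = random_seq(rng, period)
            left = rng.randint(50, 150)
            seq = random_seq(rng, left) + monomer * copies + random_seq(rng, 150)
            blocks = detect_tandem_repeats(seq)
            matches = [
                b
                for b in blocks
                if b.period == period
                and abs(b.location.start - left) <= period
                and abs(b.location.end - (left + period * copies)) <= period
            ]
            assert matches, (period, copies, [(b.period, b.location) for b in blocks])

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            detect_tandem_repeats("ACGTAC")


class TestPolyA:
    @pytest.mark.parametrize(
        "seq,min_run,expected",
        [
            ("AAAAAAAAAA", 8, (0, 10)),
            ("AAAAAAA", 8, None),
            ("AAAAGAAAAA", 8, (0, 10)),  # one interruption per ten allowed
            ("GGGGAAAAAAAACC", 8, (4, 12)),
        ],
    )
    def test_run_detection(self, seq, min_run, expected):
        assert detect_polyA(seq, window=30, min_run=min_run) == expected


class TestAnnotate:
    def test_segmentation_matches_truth(self, igs_context):
        contig, truth, hit, unit = igs_context
        seq, span = extract_igs(unit, contig)
        blocks = detect_tandem_repeats(seq, contig_id="IGS")
        gene_iv = hit.full_gene_interval(119, len(contig))
        ann = annotate_igs(seq, [to_igs_local(gene_iv, span)], blocks)
        by_class = {}
        for seg in ann.segments:
            by_class.setdefault(seg.seg_class, []).append(seg)
        assert len(by_class["fiveS_insert"]) == 1
        assert len(by_class["polyA"]) == 1
        ins_seg = by_class["fiveS_insert"][0].interval
        truth_ins = min(
            truth.of_class(contig.identifier, "fiveS_insert"),
            key=lambda f: abs(f.interval.start - (span.start + ins_seg.start)),
        )
        assert span.start + ins_seg.start == truth_ins.interval.start
        assert span.start + ins_seg.end == truth_ins.interval.end
        # planted blocks present with exact spans for the two 5'-side arrays
        repeat_spans = {
            (span.start + s.interval.start, span.start + s.interval.end)
            for s in by_class["repeat"]
        }
        planted = {
            (f.interval.start, f.interval.end)
            for f in truth.of_class(contig.identifier, "tandem_repeat")
            if span.contains(f.interval)
        }
        exact = planted & repeat_spans
        assert len(exact) >= 2

    def test_tiling_invariant(self, igs_context):
        contig, _, hit, unit = igs_context
        seq, span = extract_igs(unit, contig)
        blocks = detect_tandem_repeats(seq, contig_id="IGS")
        ann = annotate_igs(seq, [to_igs_local(hit.location, span)], blocks)
        pos = 0
        for seg in ann.segments:
            assert seg.interval.start == pos
            pos = seg.interval.end
        assert pos == len(seq)

    def test_no_insert_no_fives_class(self):
        rng = random.Random(41)
        monomer = random_seq(rng, 20)
        seq = random_seq(rng, 100) + monomer * 4 + random_seq(rng, 100)
        ann = annotate_igs(seq, [], detect_tandem_repeats(seq))
        assert all(seg.seg_class != "fiveS_insert" for seg in ann.segments)

    def test_blocks_covering_everything_leave_no_unique(self):
        rng = random.Random(42)
        monomer = random_seq(rng, 25)
        seq = monomer * 8
        blocks = [
            b for b in detect_tandem_repeats(seq)
        ]
        # force exact full-coverage block to test the tiling rule
        from nor5s.igs import RepeatBlock

        blocks = [
            RepeatBlock(GenomicInterval("seq", 0, len(seq)), 25, 8.0, monomer, "R1")
        ]
        ann = annotate_igs(seq, [], blocks)
        assert all(seg.seg_class != "unique" for seg in ann.segments)


class TestClassifyInsert:
    def test_opposite_orientation_detected(self, igs_context):
        contig, _, hit, unit = igs_context
        insert = classify_insert(hit, unit, contig, ref_len=119)
        assert insert.orientation_vs_unit == "opposite"

    def test_same_orientation_control(self, variant_pair):
        spec = RdnaUnitSpec(insert=InsertSpec(orientation="same"), unit_copies=2)
        contigs, truth = build_genome(spec, variant_pair, seed=77, name="fwd")
        refs = [
            SequenceRecord(n, truth.genes[n]) for n in ("18S", "5.8S", "28S", "5S")
        ]
        hits_by = scan_genome(contigs, refs)
        units, _ = assemble_units(hits_by["fwd_nor"], len(contigs[0]))
        hit, unit = fives_hits_in_igs(hits_by["fwd_nor"], units)[0]
        insert = classify_insert(hit, unit, contigs[0], ref_len=119)
        assert insert.orientation_vs_unit == "same"

    def test_distance_matches_planted_offset(self, variant_pair):
        spec = RdnaUnitSpec(insert=InsertSpec(offset_from_28S=500), unit_copies=2)
        contigs, truth = build_genome(spec, variant_pair, seed=78, name="d")
        refs = [
            SequenceRecord(n, truth.genes[n]) for n in ("18S", "5.8S", "28S", "5S")
        ]
        hits_by = scan_genome(contigs, refs)
        units, _ = assemble_units(hits_by["d_nor"], len(contigs[0]))
        hit, unit = fives_hits_in_igs(hits_by["d_nor"], units)[0]
        insert = classify_insert(hit, unit, contigs[0], ref_len=119)
        assert insert.distance_to_28S == 500

    def test_polyA_interval_matches_truth(self, igs_context):
        contig, truth, hit, unit = igs_context
        insert = classify_insert(hit, unit, contig, ref_len=119)
        planted = min(
            truth.of_class(contig.identifier, "polyA"),
            key=lambda f: abs(f.interval.start - insert.polyA.start),
        )
        assert insert.polyA == planted.interval

    def test_orientation_invariant_under_contig_revcomp(self, references, genome):
        contigs, _ = genome
        flipped = SequenceRecord("flip", revcomp(contigs[0].residues))
        hits_by = scan_genome([flipped], references)
        units, _ = assemble_units(hits_by["flip"], len(flipped))
        pairs = fives_hits_in_igs(hits_by["flip"], units)
        assert pairs
        for hit, unit in pairs:
            insert = classify_insert(hit, unit, flipped, ref_len=119)
            assert insert.orientation_vs_unit == "opposite"

    def test_hit_outside_igs_rejected(self, igs_context, scanned):
        contig, _, hit, unit = igs_context
        _, units_by = scanned
        other = next(
            u for u in units_by[contig.identifier] if u.igs_span != unit.igs_span
        )
        with pytest.raises(ValueError, match="outside"):
            classify_insert(hit, other, contig)


class TestConservedPrefix:
    def test_identical_flanks_full_length(self):
        flanks = ["ACGTACGTACGTACGTACGTACGTACGTAC"] * 4
        res = conserved_prefix(flanks)
        assert res.conserved_prefix_length == 30

    def test_conserved_then_random(self):
        rng = random.Random(55)
        core = random_seq(rng, 24)
        flanks = [core + random_seq(rng, 16) for _ in range(5)]
        res = conserved_prefix(flanks)
        assert res.conserved_prefix_length == 24

    def test_disagreement_at_first_column(self):
        flanks = ["AAAA", "AAAA", "TAAA", "TAAA"]
        assert conserved_prefix(flanks).conserved_prefix_length == 0

    def test_monotone_in_threshold(self):
        rng = random.Random(56)
        flanks = [random_seq(rng, 30) for _ in range(6)]
        lengths = [
            conserved_prefix(flanks, t).conserved_prefix_length
            for t in (0.0, 0.2, 0.5, 0.9)
        ]
        assert lengths == sorted(lengths)

    def test_fewer_than_two_rejected(self):
        with pytest.raises(ValueError):
            conserved_prefix(["ACGT"])


class TestHarmonise:
    def test_rotated_monomers_share_family(self):
        rng = random.Random(61)
        monomer = random_seq(rng, 30)
        rotated = monomer[7:] + monomer[:7]
        assert monomer_identity(monomer, rotated) == 100.0
        from nor5s.igs import RepeatBlock

        a = RepeatBlock(GenomicInterval("x", 0, 90), 30, 3.0, monomer, "R1")
        b = RepeatBlock(GenomicInterval("y", 0, 90), 30, 3.0, rotated, "R1")
        c = RepeatBlock(GenomicInterval("y", 100, 190), 30, 3.0, random_seq(rng, 30), "R2")
        fams = harmonise_labels([[a], [b, c]])
        assert fams[0][0] == fams[1][0]
        assert fams[1][1] != fams[1][0]
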