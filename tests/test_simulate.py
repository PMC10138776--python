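"""Self-consistency of the generator: planted features must be recoverable
verbatim from the generated sequence, and read mixtures must follow their
nominal proportions."""

from __future__ import annotations

import math

import numpy as np
import pytest

from nor5s.simulate import (
    BlockSpec,
    InsertSpec,
    RdnaUnitSpec,
    ReadSimSpec,
    Substitution,
    VariantPairSpec,
    build_genome,
    default_base_gene,
    default_variant_pair,
    make_variant_pair,
    simulate_reads,
)
from nor5s.types import REVERSE


class TestVariantPair:
    def test_no_substitutions_identical(self):
        nts, nor = make_variant_pair(VariantPairSpec(default_base_gene(), ()))
        assert nts == nor == default_base_gene()

    def test_default_pair_hamming_three_at_stated_positions(self):
        nts, nor = make_variant_pair(default_variant_pair())
        diffs = [i + 1 for i, (a, b) in enumerate(zip(nts, nor)) if a != b]
        assert diffs == [2, 23, 112]

    def test_boundary_positions(self):
        base = default_base_gene()
        spec = VariantPairSpec(
            base,
            (
                Substitution(1, "A" if base[0] != "A" else "C", "G" if base[0] != "G" else "T"),
                Substitution(len(base), "A" if base[-1] != "A" else "C", "G" if base[-1] != "G" else "T"),
            ),
        )
        nts, nor = make_variant_pair(spec)
        assert nts[0] != nor[0] and nts[-1] != nor[-1]
        assert sum(a != b for a, b in zip(nts, nor)) == 2

    @pytest.mark.parametrize(
        "subs",
        [
            ((5, "A", "A"),),  # identical bases
            ((23, "A", "G"), (2, "C", "T")),  # not increasing
            ((500, "A", "G"),),  # out of range
        ],
    )
    def test_invalid_specs_rejected(self, subs):
        with pytest.raises(ValueError):
            VariantPairSpec(default_base_gene(), tuple(Substitution(*s) for s in subs))


class TestBuildGenome:
    def test_unit_copy_number(self, genome):
        contigs, truth = genome
        nor_id = contigs[0].identifier
        for gene in ("18S", "5.8S", "28S"):
            assert sum(1 for f in truth.of_class(nor_id, "rRNA_gene") if f.label == gene) == 3

    def test_opposite_insert_is_reverse_of_unit_strand(self, genome):
        contigs, truth = genome
        inserts = truth.of_class(contigs[0].identifier, "fiveS_insert")
        assert len(inserts) == 3
        assert all(f.interval.strand == REVERSE for f in inserts)

    def test_polyA_planted_in_gene_orientation(self, genome):
        contigs, truth = genome
        for f in truth.of_class(contigs[0].identifier, "polyA"):
            assert len(f.interval) == 12
            assert f.interval.slice(contigs[0].residues) == "A" * 12

    def test_planted_sequences_recoverable_from_contig(self, genome):
        """Truth intervals, extracted from the contig, reproduce the
        planted sequences exactly (generator self-consistency)."""
        contigs, truth = genome
        seq = {c.identifier: c.residues for c in contigs}
        pair = make_variant_pair(default_variant_pair())
        for cid, feats in truth.features.items():
            for f in feats:
                extracted = f.interval.slice(seq[cid])
                if f.label in ("18S", "5.8S", "28S"):
                    assert extracted == truth.genes[f.label]
                elif f.label == "NOR-5S":
                    assert extracted == pair[1]
                elif f.label == "NTS-5S":
                    assert extracted == pair[0]
                elif f.feature_class == "polyA":
                    assert set(extracted) == {"A"}

    def test_block_order_follows_spec_for_random_specs(self, variant_pair):
        rng = np.random.default_rng(99)
        bases = np.array(list("ACGT"))
        for rep in range(15):
            n_blocks = int(rng.integers(1, 4))
            blocks = tuple(
                BlockSpec(
                    f"B{k}",
                    "".join(bases[rng.integers(0, 4, int(rng.integers(10, 60)))]),
                    int(rng.integers(2, 6)),
                )
                for k in range(n_blocks)
            )
            spec = RdnaUnitSpec(
                igs_blocks=blocks,
                unit_copies=1,
                insert=InsertSpec(offset_from_28S=100, polyA_length=10),
            )
            contigs, truth = build_genome(spec, variant_pair, seed=1000 + rep)
            planted = [
                f
                for f in truth.of_class(contigs[0].identifier, "tandem_repeat")
            ]
            planted.sort(key=lambda f: f.interval.start)
            assert [f.label for f in planted] == [b.label for b in blocks]

    def test_insert_inside_block_rejected(self, variant_pair):
        blocks = (BlockSpec("B0", "ACGTACGTAA", 5),)
        spec = RdnaUnitSpec(
            igs_blocks=blocks,
            insert=InsertSpec(offset_from_28S=170, polyA_length=10),
        )
        with pytest.raises(ValueError, match="inside block"):
            build_genome(spec, variant_pair, seed=0)

    def test_duplicate_block_labels_rejected(self):
        with pytest.raises(ValueError, match="unique"):
            RdnaUnitSpec(
                igs_blocks=(BlockSpec("B", "ACGTA", 2), BlockSpec("B", "TTTTT", 2))
            )


class TestSimulateReads:
    def test_pure_nor_no_errors_gives_exact_substrings(self, gene_pair):
        nts, nor = gene_pair
        reads, labels = simulate_reads(
            ReadSimSpec("t", 1.0, 50, read_length=60, error_rate=0.0, seed=4), nts, nor
        )
        assert all(r.residues in nor for r in reads)
        assert set(labels.values()) == {"NOR"}

    def test_label_counts_within_binomial_bound(self, gene_pair):
        nts, nor = gene_pair
        _, labels = simulate_reads(
            ReadSimSpec("t", 0.5, 10_000, error_rate=0.0, seed=8), nts, nor
        )
        n_nor = sum(1 for v in labels.values() if v == "NOR")
        assert abs(n_nor - 5000) <= 3 * math.sqrt(10_000 * 0.25)

    def test_same_seed_reproduces_reads(self, gene_pair):
        nts, nor = gene_pair
        spec = ReadSimSpec("t", 0.3, 200, seed=12)
        assert simulate_reads(spec, nts, nor) == simulate_reads(spec, nts, nor)

    def test_read_longer_than_gene_rejected(self, gene_pair):
        nts, nor = gene_pair
        with pytest.raises(ValueError, match="read_length"):
            simulate_reads(ReadSimSpec("t", 0.5, 10, read_length=500), nts, nor)

    def test_label_frequency_converges(self, gene_pair):
        nts, nor = gene_pair
        for frac in (0.1, 0.9):
            _, labels = simulate_reads(
                ReadSimSpec("t", frac, 5000, error_rate=0.0, seed=21), nts, nor
            )
            observed = sum(1 for v in labels.values() if v == "NOR") / 5000
            assert abs(observed - frac) <= 3 * math.sqrt(frac * (1 - frac) / 5000)
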