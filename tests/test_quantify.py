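"""Read mapping policy, diagnostic-site assignment and the maternal call."""

from __future__ import annotations

import math

import pytest

from nor5s.io import FastqRead
from nor5s.quantify import (
    ReadPolicy,
    TissueQuant,
    assign_read,
    call_maternal,
    map_read,
    quantify_tissue,
)
from nor5s.simulate import ReadSimSpec, simulate_reads
from nor5s.types import revcomp
from nor5s.variants import DiagnosticSite


@pytest.fixture(scope="module")
def sites(variant_pair):
    return [
        DiagnosticSite(s.position, s.nts_base, s.nor_base)
        for s in variant_pair.substitutions
    ]


def with_errors(seq: str, positions: list[int]) -> str:
    out = list(seq)
    for p in positions:
        out[p] = "A" if out[p] != "A" else "G"
    return "".join(out)


class TestMapRead:
    def test_exact_substring_accepted(self, gene_pair):
        nts, _ = gene_pair
        mapped = map_read(nts[10:110], nts)
        assert mapped is not None
        assert mapped.n_errors == 0
        assert (mapped.ref_start, mapped.ref_end) == (10, 110)

    def test_one_error_in_100nt_accepted_two_rejected(self, gene_pair):
        """floor(0.01 * 100) = 1 allowed error under the 1% policy."""
        nts, _ = gene_pair
        read = nts[10:110]
        assert map_read(with_errors(read, [50]), nts) is not None
        assert map_read(with_errors(read, [50, 70]), nts) is None

    def test_reverse_complement_read_accepted(self, gene_pair):
        nts, _ = gene_pair
        mapped = map_read(revcomp(nts[10:110]), nts)
        assert mapped is not None and mapped.orientation == "-"
        assert mapped.n_errors == 0

    def test_min_overlap_enforced(self, gene_pair):
        nts, _ = gene_pair
        assert map_read(nts[0:30], nts, ReadPolicy(min_overlap=20)) is not None
        assert map_read(nts[0:15], nts, ReadPolicy(min_overlap=20)) is None

    def test_observed_bases_indexed_one_based(self, gene_pair):
        nts, _ = gene_pair
        mapped = map_read(nts[0:50], nts)
        assert mapped.observed[1] == nts[0]
        assert mapped.observed[50] == nts[49]


class TestAssignRead:
    def test_nor_alleles_give_nor(self, gene_pair, sites):
        nts, nor = gene_pair
        read = FastqRead("r", nor[0:60], "I" * 60)  # covers sites 2 and 23
        assert assign_read(read, nor, nts, sites).label == "NOR"

    def test_nts_alleles_give_nts(self, gene_pair, sites):
        nts, nor = gene_pair
        read = FastqRead("r", nts[0:60], "I" * 60)
        assert assign_read(read, nor, nts, sites).label == "NTS"

    def test_read_covering_no_site_is_ambiguous(self, gene_pair, sites):
        nts, nor = gene_pair
        read = FastqRead("r", nts[30:100], "I" * 70)  # sites are at 2, 23, 112
        res = assign_read(read, nor, nts, sites)
        assert res.label == "ambiguous"
        assert res.sites_covered == ()

    def test_conflicting_sites_are_ambiguous(self, gene_pair, sites):
        nts, nor = gene_pair
        chimera = nor[0:60] + nts[60:119]  # NOR at 2/23, NTS at 112
        read = FastqRead("r", chimera[0:119], "I" * 119)
        res = assign_read(read, nor, nts, sites)
        assert res.label == "ambiguous"
        assert set(res.sites_covered) == {2, 23, 112}

    def test_unmappable_read_unassigned(self, gene_pair, sites):
        nts, nor = gene_pair
        read = FastqRead("r", "TGCA" * 25, "I" * 100)
        assert assign_read(read, nor, nts, sites).label == "unassigned"

    def test_no_sites_rejected(self, gene_pair):
        nts, nor = gene_pair
        with pytest.raises(ValueError):
            assign_read(FastqRead("r", nts[:50], "I" * 50), nor, nts, [])


class TestQuantify:
    def test_percentage_arithmetic(self):
        quant = TissueQuant("t", n_nor=80, n_nts=20)
        assert quant.pct_nor == 80.0
        assert TissueQuant("t", n_nor=0, n_nts=50).pct_nor == 0.0

    def test_only_ambiguous_reads_gives_na(self, caplog):
        from nor5s.quantify import ReadAssignment

        assignments = [ReadAssignment(f"r{i}", "ambiguous", 0, (), ()) for i in range(5)]
        with caplog.at_level("WARNING", logger="nor5s"):
            quant = quantify_tissue(assignments, "t")
        assert quant.pct_nor is None
        assert "pct_nor unavailable" in caplog.text

    def test_labels_partition_reads(self, gene_pair, sites):
        nts, nor = gene_pair
        reads, _ = simulate_reads(ReadSimSpec("t", 0.5, 400, seed=9), nts, nor)
        quant = quantify_tissue(
            (assign_read(r, nor, nts, sites) for r in reads), "t"
        )
        assert quant.n_nor + quant.n_nts + quant.n_ambiguous + quant.n_unassigned == 400

    def test_error_free_assignment_is_perfect(self, gene_pair, sites):
        nts, nor = gene_pair
        reads, labels = simulate_reads(
            ReadSimSpec("t", 0.4, 500, error_rate=0.0, seed=10), nts, nor
        )
        for read in reads:
            res = assign_read(read, nor, nts, sites)
            if res.sites_covered:
                assert res.label == labels[read.identifier]

    def test_tighter_policy_never_assigns_more(self, gene_pair, sites):
        nts, nor = gene_pair
        reads, _ = simulate_reads(
            ReadSimSpec("t", 0.5, 300, error_rate=0.01, seed=11), nts, nor
        )
        assigned = []
        for rate in (0.03, 0.01, 0.0):
            quant = quantify_tissue(
                (
                    assign_read(r, nor, nts, sites, ReadPolicy(max_error_rate=rate))
                    for r in reads
                ),
                "t",
            )
            assigned.append(quant.n_nor + quant.n_nts)
        assert assigned == sorted(assigned, reverse=True)

    def test_mixture_recovered_within_wald_band(self, gene_pair, sites):
        nts, nor = gene_pair
        frac = 0.8
        reads, _ = simulate_reads(
            ReadSimSpec("t", frac, 2000, error_rate=0.003, seed=12), nts, nor
        )
        quant = quantify_tissue((assign_read(r, nor, nts, sites) for r in reads), "t")
        est = quant.pct_nor / 100.0
        n = quant.n_nor + quant.n_nts
        se = math.sqrt(est * (1 - est) / n)
        assert abs(est - frac) <= 3 * se


class TestMaternalCall:
    def quants(self, pcts):
        return [
            TissueQuant(t, n_nor=round(p * 10), n_nts=1000 - round(p * 10))
            for t, p in pcts.items()
        ]

    def test_germline_high_somatic_low_is_maternal(self):
        call = call_maternal(
            self.quants({"ovary": 95, "embryo": 90, "testis": 1, "liver": 0}),
            ["ovary", "embryo"],
            ["testis", "liver"],
        )
        assert call.is_maternal_type

    def test_uniform_half_everywhere_is_not(self):
        call = call_maternal(
            self.quants({"ovary": 50, "liver": 50}), ["ovary"], ["liver"]
        )
        assert not call.is_maternal_type

    def test_high_somatic_tissue_blocks_call(self):
        call = call_maternal(
            self.quants({"ovary": 95, "liver": 40}), ["ovary"], ["liver"]
        )
        assert not call.is_maternal_type

    def test_missing_tissue_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            call_maternal(self.quants({"ovary": 95}), ["ovary"], ["liver"])

    def test_thresholds_echoed(self):
        call = call_maternal(
            self.quants({"ovary": 95, "liver": 1}), ["ovary"], ["liver"],
            germline_min=60.0, somatic_max=2.0,
        )
        assert (call.germline_min, call.somatic_max) == (60.0, 2.0)
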