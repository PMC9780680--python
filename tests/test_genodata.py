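"""Panel ingestion, filtering, polarity and interval I/O."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sweepscan.genodata import (
    ANCESTRAL_UNKNOWN,
    EmptyPanelError,
    GeneModel,
    concat_panels,
    polarize_panel,
    read_genes,
    read_pop_map,
    read_vcf,
    sites_in_window,
    subset_panel,
    write_vcf,
)

from conftest import make_panel, random_panel


class TestReadVcf:
    def test_ingests_biallelic_phased_records(self, small_vcf):
        panel = read_vcf(small_vcf)
        assert panel.matrix.shape == (4, 3)
        assert list(panel.positions) == [100, 200, 300]
        assert panel.sample_ids == ["sampleA", "sampleB"]
        # GT columns: row order is (A hap1, A hap2, B hap1, B hap2)
        assert list(panel.matrix[:, 0]) == [0, 1, 1, 1]

    def test_ancestral_from_aa_tag(self, small_vcf):
        panel = read_vcf(small_vcf)
        # site 1: AA=REF -> 0; site 2: AA=ALT -> 1; site 3: no tag -> unknown
        assert list(panel.ancestral) == [0, 1, ANCESTRAL_UNKNOWN]

    def test_unphased_record_is_skipped(self, tmp_path, small_vcf):
        text = small_vcf.read_text().replace("0|1\t1|1", "0/1\t1|1")
        p = tmp_path / "unphased.vcf"
        p.write_text(text)
        panel = read_vcf(p)
        assert panel.n_sites == 2
        assert 100 not in panel.positions

    def test_multiallelic_and_indel_skipped(self, tmp_path, small_vcf):
        extra = (
            "1\t400\t.\tA\tG,T\t.\t.\t.\tGT\t0|1\t0|2\n"
            "1\t500\t.\tAT\tA\t.\t.\t.\tGT\t0|1\t0|0\n"
        )
        p = tmp_path / "multi.vcf"
        p.write_text(small_vcf.read_text() + extra)
        assert read_vcf(p).n_sites == 3

    def test_aa_matching_neither_allele_is_unknown(self, tmp_path):
        body = (
            "##fileformat=VCFv4.2\n"
            '##INFO=<ID=AA,Number=1,Type=String,Description="AA">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\n"
            "1\t100\t.\tA\tG\t.\t.\tAA=T\tGT\t0|1\n"
        )
        p = tmp_path / "badaa.vcf"
        p.write_text(body)
        assert read_vcf(p).ancestral[0] == ANCESTRAL_UNKNOWN

    def test_empty_result_raises(self, tmp_path):
        p = tmp_path / "empty.vcf"
        p.write_text(
            "##fileformat=VCFv4.2\n#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\n"
            "1\t100\t.\tA\tG\t.\t.\t.\tGT\t0/1\n"
        )
        with pytest.raises(EmptyPanelError):
            read_vcf(p)

    def test_region_filter(self, small_vcf):
        panel = read_vcf(small_vcf, region="1:150-250")
        assert list(panel.positions) == [200]

    def test_write_read_roundtrip_bytes(self, small_vcf, tmp_path):
        panel = read_vcf(small_vcf)
        out1 = tmp_path / "rt1.vcf"
        out2 = tmp_path / "rt2.vcf"
        write_vcf(panel, out1)
        write_vcf(read_vcf(out1), out2)
        assert out1.read_bytes() == out2.read_bytes()
        again = read_vcf(out2)
        assert np.array_equal(again.matrix, panel.matrix)
        assert np.array_equal(again.ancestral, panel.ancestral)
        assert again.alleles == panel.alleles


class TestPopMap:
    def test_basic(self, tmp_path):
        p = tmp_path / "map.tsv"
        p.write_text("s1\tpopA\ns2\tpopA\ns3\tpopB\n")
        m = read_pop_map(p)
        assert m == {"s1": "popA", "s2": "popA", "s3": "popB"}

    def test_empty_rejected(self, tmp_path):
        p = tmp_path / "map.tsv"
        p.write_text("")
        with pytest.raises(ValueError):
            read_pop_map(p)

    def test_duplicate_sample_rejected(self, tmp_path):
        p = tmp_path / "map.tsv"
        p.write_text("s1\tpopA\ns1\tpopB\n")
        with pytest.raises(ValueError, match="duplicated"):
            read_pop_map(p)


class TestSubsetPanel:
    def test_singleton_removed_at_default_maf(self):
        mat = np.zeros((60, 2), dtype=np.uint8)
        mat[0, 0] = 1          # freq 1/60 = 0.0167 <= 0.05 -> removed
        mat[:30, 1] = 1        # freq 0.5 -> retained
        panel = make_panel(mat)
        sub = subset_panel(panel, "pop1", 0.05)
        assert sub.n_sites == 1 and sub.positions[0] == panel.positions[1]

    def test_monomorphic_removed_even_at_zero_maf(self):
        mat = np.zeros((4, 2), dtype=np.uint8)
        mat[:, 1] = [0, 1, 1, 0]
        sub = subset_panel(make_panel(mat), "pop1", 0.0)
        assert sub.n_sites == 1

    def test_unknown_population_lists_valid_labels(self):
        panel = make_panel(np.eye(4, dtype=np.uint8), pops=["A", "B"])
        with pytest.raises(KeyError, match="valid labels"):
            subset_panel(panel, "C", 0.0)

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 2**31 - 1), st.floats(0.0, 0.45))
    def test_idempotent_and_maf_bounded(self, seed, maf_min):
        rng = np.random.default_rng(seed)
        panel = random_panel(rng, n_hap=16, n_sites=25)
        try:
            once = subset_panel(panel, "pop1", maf_min)
        except EmptyPanelError:
            return
        twice = subset_panel(once, "pop1", maf_min)
        assert np.array_equal(once.matrix, twice.matrix)
        p = once.alt_freq()
        assert np.all((p > maf_min) & (p < 1 - maf_min))


class TestReadGenes:
    def test_bed_half_open(self, tmp_path):
        p = tmp_path / "g.bed"
        p.write_text("1\t100\t200\tgeneA\n")
        (g,) = read_genes(p)
        assert g == GeneModel("geneA", "1", 100, 200)

    def test_gff3_closed_to_half_open_and_type_filter(self, tmp_path):
        p = tmp_path / "g.gff3"
        p.write_text(
            "##gff-version 3\n"
            "1\tsrc\tgene\t101\t200\t.\t+\t.\tID=geneB;Name=GENEB\n"
            "1\tsrc\texon\t101\t150\t.\t+\t.\tID=exon1\n"
        )
        (g,) = read_genes(p)
        assert (g.start, g.end, g.name) == (100, 200, "GENEB")

    def test_malformed_row_rejected(self, tmp_path):
        p = tmp_path / "g.bed"
        p.write_text("1\t200\t100\tbad\n1\t10\t20\tok\n")
        genes = read_genes(p)
        assert [g.name for g in genes] == ["ok"]


class TestCoordinateRule:
    def test_one_based_position_in_half_open_window(self):
        pos = np.array([1, 100, 101, 200, 201])
        sl = sites_in_window(pos, 100, 200)
        # window [100,200): holds p with 100 < p <= 200
        assert list(pos[sl]) == [101, 200]

    def test_adjacent_windows_partition_sites(self, rng):
        pos = np.sort(rng.choice(np.arange(1, 1001), 60, replace=False))
        counted = sum(
            sites_in_window(pos, a, a + 100).stop - sites_in_window(pos, a, a + 100).start
            for a in range(0, 1000, 100)
        )
        assert counted == pos.size


class TestPolarize:
    def test_ref_policy_fills_unknown_only(self):
        panel = make_panel(np.eye(4, dtype=np.uint8), ancestral=[1, -1, -1, 0])
        out = polarize_panel(panel, "ref")
        assert list(out.ancestral) == [1, 0, 0, 0]

    def test_outgroup_major_policy(self):
        mat = np.array([[0, 1], [1, 0], [1, 0], [1, 0]], dtype=np.uint8)
        panel = make_panel(mat, ancestral=[-1, -1], pops=["in", "out"])
        out = polarize_panel(panel, "outgroup-major", outgroup_pop="out")
        assert list(out.ancestral) == [1, 0]

    def test_skip_policy_drops_unpolarized(self):
        panel = make_panel(np.eye(4, dtype=np.uint8), ancestral=[0, -1, 0, -1])
        assert polarize_panel(panel, "skip").n_sites == 2


def test_concat_panels_requires_shared_frame():
    a = make_panel(np.eye(4, dtype=np.uint8))
    b = make_panel(np.eye(4, dtype=np.uint8), positions=[5, 10, 15, 20])
    with pytest.raises(ValueError):
        concat_panels([a, b])
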