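import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import make_table
from milupop.genome_io import (GenomeIOError, HET, HOM_ALT, HOM_REF, MISSING,
                               ScaffoldSet, complement_intervals,
                               filter_variants, merge_intervals, read_bed,
                               read_features, read_vcf, subtract_intervals,
                               write_bed)
from milupop.simulate import write_vcf

VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    "##contig=<ID=scf1,length=100000>\n"
    '##INFO=<ID=DP,Number=1,Type=Integer,Description="depth">\n'
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
    "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2\n"
)


def _write(tmp_path, body, name="t.vcf"):
    p = tmp_path / name
    p.write_text(VCF_HEADER + body)
    return p


class TestReadVcf:
    def test_non_snp_records_dropped(self, tmp_path):
        body = (
            "scf1\t100\t.\tA\tG\t50\tPASS\tDP=20\tGT\t0/1\t0/0\n"
            "scf1\t200\t.\tAT\tA\t50\tPASS\tDP=20\tGT\t0/1\t0/0\n"   # indel
            "scf1\t300\t.\tA\tG,C\t50\tPASS\tDP=20\tGT\t0/1\t0/2\n"  # multi-allelic
            "scf1\t400\t.\tC\tT\t50\tPASS\tDP=20\tGT\t1/1\t./.\n"
            "scf1\t500\t.\tG\tA\t50\tPASS\tDP=20\tGT\t0/0\t0/1\n"
        )
        t = read_vcf(_write(tmp_path, body))
        assert len(t) == 3
        assert list(t.pos) == [100, 400, 500]

    def test_genotype_mapping(self, tmp_path):
        body = "scf1\t100\t.\tA\tG\t50\tPASS\tDP=20\tGT\t0/1\t./.\n" \
               "scf1\t200\t.\tA\tG\t50\tPASS\tDP=20\tGT\t1/1\t0/0\n"
        t = read_vcf(_write(tmp_path, body))
        assert t.genotypes.tolist() == [[HET, MISSING], [HOM_ALT, HOM_REF]]
        assert t.qual[0] == 50.0 and t.depth[0] == 20.0

    def test_unsorted_input_names_offender(self, tmp_path):
        body = "scf1\t500\t.\tA\tG\t50\tPASS\tDP=20\tGT\t0/1\t0/0\n" \
               "scf1\t100\t.\tA\tG\t50\tPASS\tDP=20\tGT\t0/1\t0/0\n"
        with pytest.raises(GenomeIOError, match="scf1:100"):
            read_vcf(_write(tmp_path, body))

    def test_absent_sample_rejected(self, tmp_path):
        body = "scf1\t100\t.\tA\tG\t50\tPASS\tDP=20\tGT\t0/1\t0/0\n"
        with pytest.raises(GenomeIOError, match="nosuch"):
            read_vcf(_write(tmp_path, body), samples=["nosuch"])

    def test_synthetic_roundtrip(self, tmp_path, small_genome):
        """A generated VCF re-read through the reader reproduces the table."""
        path = tmp_path / "rt.vcf"
        write_vcf(small_genome.variants, small_genome.scaffolds, path)
        t = read_vcf(path)
        v = small_genome.variants
        assert t.samples == v.samples
        assert np.array_equal(t.pos, v.pos)
        assert np.array_equal(t.genotypes, v.genotypes)
        assert np.allclose(t.qual, v.qual)
        assert np.allclose(t.depth, v.depth)
        assert list(t.scaffold) == list(v.scaffold)


class TestFilterVariants:
    def test_study_thresholds_drop_high_depth(self):
        t = make_table([100, 200], [[HOM_REF], [HOM_REF]],
                       qual=[30, 30], depth=[87, 40])
        out = filter_variants(t, 20, 6, 86)
        assert list(out.pos) == [200]

    def test_no_thresholds_is_identity(self):
        t = make_table([100, 200, 300], [[HET], [HOM_ALT], [MISSING]],
                       qual=[5, 50, 500], depth=[1, 10, 100])
        out = filter_variants(t, 0, 0, np.inf)
        assert np.array_equal(out.pos, t.pos)

    def test_count_matches_direct_scan(self):
        rng = np.random.default_rng(0)
        depth = np.concatenate([rng.integers(0, 6, 40),
                                rng.integers(6, 80, 60)]).astype(float)
        rng.shuffle(depth)
        t = make_table(np.arange(1, 101) * 10, np.zeros((100, 1), np.int8),
                       qual=np.full(100, 99.0), depth=depth)
        out = filter_variants(t, 20, 6, 86)
        assert len(out) == int((depth >= 6).sum()) == 60

    def test_missing_fields_pass(self):
        t = make_table([100], [[HET]])    # NaN qual/depth
        assert len(filter_variants(t, 20, 6, 86)) == 1

    @given(st.lists(st.tuples(st.floats(0, 100), st.floats(0, 100)),
                    min_size=1, max_size=30))
    @settings(max_examples=25, deadline=None)
    def test_idempotent_and_order_preserving(self, qd):
        qual = np.array([x[0] for x in qd])
        depth = np.array([x[1] for x in qd])
        t = make_table(np.arange(1, len(qd) + 1) * 7,
                       np.zeros((len(qd), 1), np.int8), qual=qual, depth=depth)
        once = filter_variants(t, 30, 10, 80)
        twice = filter_variants(once, 30, 10, 80)
        assert np.array_equal(once.pos, twice.pos)
        assert np.all(np.diff(once.pos) > 0)


class TestFeatures:
    GFF = ("##gff-version 3\n"
           "scf1\tsrc\tgene\t1001\t2000\t.\t+\t.\tID=g1\n"
           "scf1\tsrc\texon\t1001\t1200\t.\t+\t.\tID=g1.e1;Parent=g1\n"
           "scf1\tsrc\texon\t1801\t2000\t.\t+\t.\tID=g1.e2;Parent=g1\n")

    def test_intron_derivation(self, tmp_path):
        p = tmp_path / "f.gff3"
        p.write_text(self.GFF)
        scf = ScaffoldSet(("scf1",), (10_000,))
        fs = read_features(p, "gff3", scf)
        assert fs.intron["scf1"].tolist() == [[1200, 1800]]
        assert fs.exon["scf1"].tolist() == [[1000, 1200], [1800, 2000]]

    def test_geneless_scaffold_is_all_other(self, tmp_path):
        p = tmp_path / "f.gff3"
        p.write_text(self.GFF)
        scf = ScaffoldSet(("scf1", "scf2"), (10_000, 5_000))
        fs = read_features(p, "gff3", scf)
        assert fs.other["scf2"].tolist() == [[0, 5_000]]
        assert len(fs.exon["scf2"]) == 0

    def test_partition_covers_genome(self, small_genome):
        fs = small_genome.features
        total = sum(fs.class_length(c) for c in fs.CLASSES)
        assert total == small_genome.scaffolds.total_length
        # classes pairwise disjoint on each scaffold
        for scf in small_genome.scaffolds.names:
            merged = merge_intervals(np.vstack([fs.exon[scf], fs.intron[scf],
                                                fs.other[scf]]))
            lengths = sum(len(fs.intervals(c)[scf]) and
                          int((fs.intervals(c)[scf][:, 1]
                               - fs.intervals(c)[scf][:, 0]).sum())
                          for c in fs.CLASSES)
            assert int((merged[:, 1] - merged[:, 0]).sum()) == lengths

    def test_exon_outside_gene_rejected(self, tmp_path):
        p = tmp_path / "f.gff3"
        p.write_text("##gff-version 3\n"
                     "scf1\tsrc\tgene\t1001\t2000\t.\t+\t.\tID=g1\n"
                     "scf1\tsrc\texon\t500\t1200\t.\t+\t.\tID=g1.e1;Parent=g1\n")
        with pytest.raises(GenomeIOError, match="exon outside"):
            read_features(p, "gff3", ScaffoldSet(("scf1",), (10_000,)))


class TestBed:
    def test_format_and_empty(self, tmp_path):
        p = tmp_path / "a.bed"
        write_bed([("scf1", 0, 100, "L")], p)
        assert p.read_text() == "scf1\t0\t100\tL\n"
        write_bed([], tmp_path / "e.bed")
        assert (tmp_path / "e.bed").read_text() == ""

    def test_roundtrip_random(self, tmp_path):
        rng = np.random.default_rng(3)
        records = []
        for scf in ("a", "b", "c"):
            starts = np.sort(rng.choice(10**6, size=333, replace=False))
            for s in starts:
                records.append((scf, int(s), int(s) + int(rng.integers(1, 500)),
                                f"x{int(s)%7}"))
        p = tmp_path / "r.bed"
        write_bed(records, p)
        assert read_bed(p) == records

    def test_unsorted_rejected(self, tmp_path):
        with pytest.raises(GenomeIOError, match="unsorted"):
            write_bed([("s", 100, 200, "L"), ("s", 50, 80, "H")],
                      tmp_path / "u.bed")


class TestIntervalOps:
    @given(st.lists(st.tuples(st.integers(0, 500), st.integers(1, 50)),
                    max_size=20),
           st.lists(st.tuples(st.integers(0, 500), st.integers(1, 50)),
                    max_size=20))
    @settings(max_examples=50, deadline=None)
    def test_subtract_complement_against_masks(self, a_raw, b_raw):
        """Interval arithmetic agrees with boolean-mask arithmetic."""
        L = 600
        def to_iv(raw):
            return merge_intervals(np.array([[s, min(s + l, L)]
                                             for s, l in raw], np.int64).reshape(-1, 2))
        def to_mask(iv):
            m = np.zeros(L, bool)
            for s, e in iv:
                m[s:e] = True
            return m
        a, b = to_iv(a_raw), to_iv(b_raw)
        assert np.array_equal(to_mask(subtract_intervals(a, b)),
                              to_mask(a) & ~to_mask(b))
        assert np.array_equal(to_mask(complement_intervals(a, L)), ~to_mask(a))
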