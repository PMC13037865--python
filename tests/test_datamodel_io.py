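import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from paleodiff.datamodel import (
    ANC_ALT,
    ANC_REF,
    GeneticMap,
    IntervalTrack,
    SiteTable,
    is_transversion,
)
from paleodiff import io as pio
from conftest import build_table


class TestIntervalTrack:
    def test_merge_overlapping_is_union(self):
        t = IntervalTrack.from_records(
            [("chr1", 10, 20), ("chr1", 15, 30), ("chr1", 40, 50)]
        )
        m = t.merged()
        assert list(map(tuple, m.df[["start", "end"]].to_numpy())) == [
            (10, 30),
            (40, 50),
        ]
        assert m.total_length() == 30

    def test_single_record_length(self):
        t = IntervalTrack.from_records([("chr1", 10, 20)])
        assert t.total_length() == 10

    def test_intersect_and_subtract(self):
        a = IntervalTrack.from_records([("chr1", 0, 100), ("chr2", 0, 50)])
        b = IntervalTrack.from_records([("chr1", 50, 150)])
        assert a.intersect(b).total_length() == 50
        sub = a.subtract(b)
        assert sub.total_length() == 100  # chr1:0-50 + chr2:0-50
        # intersect and subtract partition a
        assert a.intersect(b).total_length() + sub.total_length() == a.total_length()

    def test_contains(self):
        t = IntervalTrack.from_records([("chr1", 10, 20)])
        got = t.contains(np.array(["chr1", "chr1", "chr1", "chr2"], dtype=object),
                         np.array([9, 10, 19, 15]))
        assert list(got) == [False, True, True, False]

    def test_rejects_empty_interval(self):
        with pytest.raises(ValueError):
            IntervalTrack.from_records([("chr1", 20, 20)])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        st.lists(
            st.tuples(st.integers(0, 500), st.integers(1, 50)),
            min_size=1,
            max_size=20,
        )
    )
    def test_merge_idempotent_and_sorted(self, raw):
        t = IntervalTrack.from_records([("chr1", s, s + l) for s, l in raw])
        m = t.merged()
        assert m.df.equals(m.merged().df)
        starts = m.df["start"].to_numpy()
        ends = m.df["end"].to_numpy()
        assert (np.diff(starts) > 0).all()
        assert (starts[1:] > ends[:-1]).all()  # disjoint after merge


class TestGeneticMap:
    def test_linear_midpoint_and_endpoints(self):
        gm = GeneticMap({"chr1": ([0, 1_000_000], [0.0, 1.0])})
        assert gm.interpolate_cm("chr1", 500_000) == pytest.approx(0.5)
        assert gm.interpolate_cm("chr1", 0) == 0.0
        # clamping beyond the mapped range
        assert gm.interpolate_cm("chr1", 2_000_000) == pytest.approx(1.0)

    def test_inverse_interpolation(self):
        gm = GeneticMap({"chr1": ([0, 1_000_000, 3_000_000], [0.0, 1.0, 1.5])})
        for bp in [0, 250_000, 1_000_000, 2_500_000]:
            cm = gm.interpolate_cm("chr1", bp)
            assert gm.interpolate_bp("chr1", cm) == pytest.approx(bp, abs=1)

    def test_unknown_chromosome(self):
        gm = GeneticMap.uniform({"chr1": 1000})
        with pytest.raises(KeyError):
            gm.interpolate_cm("chrX", 10)

    def test_rejects_decreasing(self):
        with pytest.raises(ValueError):
            GeneticMap({"chr1": ([0, 10, 5], [0, 1, 2])})
        with pytest.raises(ValueError):
            GeneticMap({"chr1": ([0, 10, 20], [0, 2, 1])})

    def test_tsv_round_trip(self, tmp_path):
        gm = GeneticMap({"chr1": ([0, 500, 1000], [0.0, 0.2, 1.0]),
                         "chr2": ([0, 2000], [0.0, 3.0])})
        pio.write_genetic_map(gm, tmp_path / "map.tsv")
        back = pio.read_genetic_map(tmp_path / "map.tsv")
        assert back.chromosomes == ["chr1", "chr2"]
        assert back.interpolate_cm("chr1", 750) == pytest.approx(0.6)


class TestVcf:
    def test_round_trip(self, tmp_path):
        t = build_table({"s1": [0, 1, 2], "s2": [2, -1, 0]}, anc="alt")
        pio.write_vcf(t, tmp_path / "x.vcf")
        back = pio.read_genotypes(tmp_path / "x.vcf")
        assert back.samples == t.samples
        assert (back.gt == t.gt).all()
        assert (back.pos == t.pos).all()
        assert (back.anc == t.anc).all()
        assert list(back.ref) == list(t.ref) and list(back.alt) == list(t.alt)

    def test_indels_and_multiallelics_dropped(self, tmp_path):
        text = "\n".join(
            [
                "##fileformat=VCFv4.2",
                '##INFO=<ID=AA,Number=1,Type=String,Description="x">',
                '##FORMAT=<ID=GT,Number=1,Type=String,Description="x">',
                "##contig=<ID=chr1,length=1000>",
                "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1",
                "chr1\t10\t.\tA\tG\t.\tPASS\tAA=A\tGT\t0/1",
                "chr1\t20\t.\tAT\tA\t.\tPASS\t.\tGT\t0/1",      # indel
                "chr1\t30\t.\tC\tG,T\t.\tPASS\t.\tGT\t1/2",      # multiallelic
                "chr1\t40\t.\tC\tT\t.\tPASS\tAA=T\tGT\t1/1",
                "",
            ]
        )
        p = tmp_path / "y.vcf"
        p.write_text(text)
        with pytest.warns(UserWarning, match="dropped 2"):
            t = pio.read_genotypes(p)
        assert t.n_sites == 2
        assert list(t.pos) == [10, 40]

    def test_polarization_to_alt_ancestral(self, tmp_path):
        # REF=A ALT=G, ancestral G, genotype A/G: one derived (A) copy
        t = build_table({"s1": [1]}, ref="A", alt="G", anc="alt")
        assert t.derived_dosage(["s1"])[0, 0] == 1.0
        assert not t.transversion[0]  # A<->G is a transition

    def test_missing_sample_lists_available(self, tmp_path):
        t = build_table({"s1": [0], "s2": [1]})
        pio.write_vcf(t, tmp_path / "z.vcf")
        with pytest.raises(KeyError, match="s1"):
            pio.read_genotypes(tmp_path / "z.vcf", samples=["nope"])

    def test_unparsable_ancestral_kept_unknown(self, tmp_path):
        t = build_table({"s1": [1]}, anc="unknown")
        pio.write_vcf(t, tmp_path / "u.vcf")
        back = pio.read_genotypes(tmp_path / "u.vcf")
        assert back.n_sites == 1
        assert np.isnan(back.derived_dosage(["s1"])[0, 0])


class TestBed:
    def test_round_trip(self, tmp_path):
        t = IntervalTrack.from_records([("chr1", 0, 10), ("chr2", 5, 9)])
        pio.write_bed(t, tmp_path / "a.bed")
        back = pio.read_bed(tmp_path / "a.bed")
        assert back.df[["chrom", "start", "end"]].equals(
            t.df[["chrom", "start", "end"]]
        )

    def test_malformed_records_skipped(self, tmp_path):
        p = tmp_path / "b.bed"
        p.write_text("chr1\t10\t20\nchr1\t30\t30\nchr1\t50\t40\n")
        with pytest.warns(UserWarning, match="skipped 2"):
            t = pio.read_bed(p)
        assert len(t) == 1

    def test_merge_on_read(self, tmp_path):
        p = tmp_path / "c.bed"
        p.write_text("chr1\t10\t20\nchr1\t15\t30\n")
        t = pio.read_bed(p, merge=True)
        assert t.total_length() == 20


class TestPolarization:
    def test_transversion_classification(self):
        assert is_transversion("A", "C")
        assert is_transversion("G", "T")
        assert not is_transversion("C", "T")
        assert not is_transversion("A", "G")

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.lists(st.integers(0, 2), min_size=1, max_size=30))
    def test_ref_alt_swap_leaves_derived_dosage_unchanged(self, dosages):
        t1 = build_table({"s": dosages}, ref="A", alt="C", anc="ref")
        # swap ref/alt, flip genotypes, mark ancestral as the (new) alt
        swapped = [2 - d for d in dosages]
        t2 = build_table({"s": swapped}, ref="C", alt="A", anc="alt")
        np.testing.assert_array_equal(
            t1.derived_dosage(["s"]), t2.derived_dosage(["s"])
        )

    def test_sites_must_increase(self):
        with pytest.raises(ValueError, match="increasing"):
            SiteTable(
                np.array(["chr1", "chr1"], dtype=object),
                np.array([10, 10]),
                np.array(["A", "A"], dtype=object),
                np.array(["C", "C"], dtype=object),
                np.array([0, 0], dtype=np.int8),
                ["s"],
                np.zeros((2, 1), dtype=np.int8),
            )
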