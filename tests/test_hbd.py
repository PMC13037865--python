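import numpy as np
import pandas as pd
import pytest

from paleodiff.datamodel import GeneticMap, IntervalTrack
from paleodiff.hbd import (
    HBDParams,
    HBDTrackSet,
    compute_heterozygosity,
    detect_hbd_tracts,
    full_span_track,
    summarize_hbd,
)
from paleodiff.simulate import panmictic_config, simulate_dataset, simulate_inbred_individual
from conftest import build_table


def tracks_from(lengths_cm, callable_cm=100.0, sample="s"):
    rows = []
    pos = 0
    for L in lengths_cm:
        bp = int(L * 1e6)
        rows.append(
            {
                "chrom": "chr1", "start": pos, "end": pos + bp,
                "start_cM": pos / 1e6, "end_cM": (pos + bp) / 1e6,
                "length_cM": L, "mean_posterior": 1.0,
            }
        )
        pos += bp + int(1e6)
    df = pd.DataFrame(rows) if rows else pd.DataFrame(
        columns=["chrom", "start", "end", "start_cM", "end_cM",
                 "length_cM", "mean_posterior"]
    )
    return HBDTrackSet(sample, df, callable_cm)


class TestSummarize:
    def test_two_tract_arithmetic(self):
        s = summarize_hbd(tracks_from([3.0, 12.0]))
        assert s["f_hbd"] == pytest.approx(0.15)
        assert s["mass_small"] == pytest.approx(0.03)
        assert s["mass_large"] == pytest.approx(0.12)

    def test_empty(self):
        s = summarize_hbd(tracks_from([]))
        assert s["f_hbd"] == 0 and s["n_tracts"] == 0

    def test_classes_sum_to_f(self):
        s = summarize_hbd(tracks_from([2.6, 4.0, 9.9, 10.0, 30.0]))
        assert s["mass_small"] + s["mass_large"] == pytest.approx(s["f_hbd"])

    def test_subthreshold_tracts_excluded(self):
        s = summarize_hbd(tracks_from([1.0, 2.4, 5.0]))
        assert s["f_hbd"] == pytest.approx(0.05)

    def test_zero_callable_rejected(self):
        with pytest.raises(ValueError):
            summarize_hbd(tracks_from([3.0], callable_cm=0.0))


class TestHeterozygosity:
    def test_rate_arithmetic(self):
        # 120 het sites over 1e6 callable bases -> 1.2 per 10,000
        gt = [1] * 120 + [0] * 30
        t = build_table({"s": gt}, spacing=5000)
        mask = IntervalTrack.from_records([("chr1", 0, 1_000_000)])
        est = compute_heterozygosity(t, "s", mask)
        assert est.rate_per_10kb == pytest.approx(1.2)

    def test_all_homozygous_is_zero(self):
        t = build_table({"s": [0, 2, 0, 2]})
        mask = IntervalTrack.from_records([("chr1", 0, 10_000)])
        assert compute_heterozygosity(t, "s", mask).rate_per_10kb == 0.0

    def test_hbd_exclusion_raises_rate(self):
        # hets cluster outside the HBD tract, so exclusion must raise the rate
        gt = [1] * 50 + [0] * 50
        t = build_table({"s": gt}, spacing=1000)  # hets in first 50 kb
        mask = IntervalTrack.from_records([("chr1", 0, 200_000)])
        hbd = tracks_from([], callable_cm=0.2)
        hbd.tracts = pd.DataFrame(
            [{"chrom": "chr1", "start": 100_000, "end": 200_000,
              "start_cM": 0.1, "end_cM": 0.2, "length_cM": 2.6,
              "mean_posterior": 1.0}]
        )
        est = compute_heterozygosity(t, "s", mask, exclude=hbd)
        assert est.rate_per_10kb_excl > est.rate_per_10kb

    def test_empty_mask_rejected(self):
        t = build_table({"s": [1]})
        with pytest.raises(ValueError):
            compute_heterozygosity(t, "s", IntervalTrack.empty())


class TestDetector:
    def test_zero_het_genome_gives_one_tract_per_chromosome(self):
        gt = {"s": [0, 2, 0, 2, 0, 2, 0, 2]}
        t1 = build_table(gt, chrom="chr1", spacing=1_000_000)
        t2 = build_table(gt, chrom="chr2", spacing=1_000_000, start=2)
        import pandas as pd
        from paleodiff.datamodel import SiteTable

        t = SiteTable(
            np.concatenate([t1.chrom, t2.chrom]),
            np.concatenate([t1.pos, t2.pos]),
            np.concatenate([t1.ref, t2.ref]),
            np.concatenate([t1.alt, t2.alt]),
            np.concatenate([t1.anc, t2.anc]),
            ["s"],
            np.vstack([t1.gt, t2.gt]),
        )
        gmap = GeneticMap.uniform({"chr1": 10_000_000, "chr2": 10_000_000})
        tracks = detect_hbd_tracts(t, "s", full_span_track(gmap), gmap)
        rep = tracks.reported()
        assert len(rep) == 2
        assert set(rep["chrom"]) == {"chr1", "chr2"}
        assert tracks.f_hbd == pytest.approx(1.0, abs=0.01)

    def test_outbred_genome_has_little_hbd(self):
        cfg = panmictic_config(6, N=10_000, n_diploid=1, n_chrom=3,
                               chrom_length=10e6)
        t, gmap, _ = simulate_dataset(cfg)
        tracks = detect_hbd_tracts(t, "POP_0", full_span_track(gmap), gmap)
        assert tracks.f_hbd < 0.02

    def test_inbred_recovery(self):
        """Truth tracts >= 2.5 cM are found with near-matching f_hbd."""
        recs, errs = [], []
        for seed in (51, 52):
            t, gmap, truth = simulate_inbred_individual(
                25, 10, 1e-3, seed=seed, n_chrom=10, chrom_length=10e6
            )
            tracks = detect_hbd_tracts(t, t.samples[0], full_span_track(gmap), gmap)
            tdf = truth.with_lengths_cm(gmap)
            tdf = tdf[tdf["length_cM"] >= 2.5]
            det = tracks.reported()
            found = 0
            for _, tr in tdf.iterrows():
                d = det[det["chrom"] == tr["chrom"]]
                found += bool(
                    (
                        (abs(d["start_cM"] - tr["start_cM"]) < 0.5)
                        & (abs(d["end_cM"] - tr["end_cM"]) < 0.5)
                    ).any()
                )
            recs.append(found / max(len(tdf), 1))
            errs.append(tracks.f_hbd - tdf["length_cM"].sum() / 100.0)
        assert np.mean(recs) >= 0.7
        assert abs(np.mean(errs)) < 0.1

    def test_unmapped_chromosome_skipped_with_warning(self):
        t = build_table({"s": [0, 1, 0]}, chrom="chrZ")
        gmap = GeneticMap.uniform({"chr1": 1_000_000})
        mask = IntervalTrack.from_records([("chrZ", 0, 10_000), ("chr1", 0, 1_000_000)])
        with pytest.warns(UserWarning, match="chrZ"):
            tracks = detect_hbd_tracts(t, "s", mask, gmap)
        assert (tracks.tracts["chrom"] != "chrZ").all()
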