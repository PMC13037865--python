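import numpy as np
import pytest

from paleodiff.datamodel import ANC_ALT, ANC_REF
from paleodiff.simulate import (
    inbred_config,
    introgression_config,
    panmictic_config,
    simulate_dataset,
    simulate_inbred_individual,
)


class TestDeterminism:
    def test_same_seed_bit_identical(self):
        cfg = panmictic_config(7, N=5000, n_diploid=2, n_chrom=2, chrom_length=2e6)
        t1, _, _ = simulate_dataset(cfg)
        cfg2 = panmictic_config(7, N=5000, n_diploid=2, n_chrom=2, chrom_length=2e6)
        t2, _, _ = simulate_dataset(cfg2)
        np.testing.assert_array_equal(t1.gt, t2.gt)
        np.testing.assert_array_equal(t1.pos, t2.pos)
        assert list(t1.ref) == list(t2.ref)

    def test_different_seed_differs(self):
        t1, _, _ = simulate_dataset(
            panmictic_config(1, n_chrom=1, chrom_length=2e6)
        )
        t2, _, _ = simulate_dataset(
            panmictic_config(2, n_chrom=1, chrom_length=2e6)
        )
        assert t1.n_sites != t2.n_sites or not (t1.pos == t2.pos).all()


class TestNeutralExpectations:
    def test_heterozygosity_matches_4Nmu(self):
        """Pairwise heterozygosity of a panmictic diploid ~ 4*N*mu."""
        N, mu, L = 10_000, 1.25e-8, 5e6
        theta = 4 * N * mu
        rates = []
        for seed in range(1, 6):
            cfg = panmictic_config(seed, N=N, n_diploid=1, n_chrom=2,
                                   chrom_length=L, mut_rate=mu)
            t, _, _ = simulate_dataset(cfg)
            rates.append((t.gt == 1).sum() / (2 * L))
        mean = np.mean(rates)
        se = np.std(rates, ddof=1) / np.sqrt(len(rates))
        assert abs(mean - theta) < 3 * se + 1e-6

    def test_singleton_fraction(self):
        """Neutral SFS: P(singleton) = 1 / a_{n-1} among segregating sites."""
        n_hap = 8
        cfg = panmictic_config(3, N=10_000, n_diploid=n_hap // 2, n_chrom=4,
                               chrom_length=5e6)
        t, _, _ = simulate_dataset(cfg)
        d = t.derived_dosage()
        counts = d.sum(axis=1).astype(int)
        seg = (counts > 0) & (counts < n_hap)
        p_single = (counts[seg] == 1).mean()
        a_n = sum(1.0 / i for i in range(1, n_hap))
        expected = (1.0 / a_n)
        se = np.sqrt(expected * (1 - expected) / seg.sum())
        assert abs(p_single - expected) < 3 * se + 0.01


class TestTruth:
    def test_zero_admixture_gives_no_introgressed_segments(self):
        cfg = introgression_config(5, fraction=0.0, n_chrom=1, chrom_length=5e6)
        _, _, truth = simulate_dataset(cfg)
        assert all(len(tr) == 0 for tr in truth.introgressed.values())

    def test_positive_admixture_gives_segments_within_bounds(self):
        cfg = introgression_config(5, fraction=0.05, n_chrom=2, chrom_length=5e6)
        _, _, truth = simulate_dataset(cfg)
        tr = truth.introgressed["TARGET_0"]
        assert len(tr) > 0
        assert (tr.df["start"] >= 0).all()
        assert (tr.df["end"] <= 5e6).all()
        # homozygous truth is contained in the any-copy truth
        hom = truth.introgressed_hom["TARGET_0"]
        if len(hom):
            assert hom.intersect(tr).total_length() == hom.total_length()

    def test_hap_union_equals_any(self):
        cfg = introgression_config(8, fraction=0.1, n_chrom=1, chrom_length=5e6)
        _, _, truth = simulate_dataset(cfg)
        a, b = truth.introgressed_hap["TARGET_0"]
        import pandas as pd

        union = (
            pd.concat([a.df, b.df], ignore_index=True)
            if len(a) and len(b)
            else (a.df if len(a) else b.df)
        )
        from paleodiff.datamodel import IntervalTrack

        u = IntervalTrack(union[["chrom", "start", "end"]].copy()).merged()
        assert u.total_length() == truth.introgressed["TARGET_0"].total_length()

    def test_polarization_consistency(self):
        """Derived dosage is invariant to whether REF or ALT is ancestral."""
        cfg = panmictic_config(11, n_diploid=2, n_chrom=1, chrom_length=2e6)
        cfg.p_ref_ancestral = 0.5
        t, _, _ = simulate_dataset(cfg)
        assert set(np.unique(t.anc)) <= {ANC_REF, ANC_ALT}
        d = t.derived_dosage()
        g = t.gt.astype(float)
        flip = t.anc == ANC_ALT
        np.testing.assert_array_equal(d[flip], 2 - g[flip])
        np.testing.assert_array_equal(d[~flip], g[~flip])


class TestInbred:
    def test_hbd_fraction_monotone_in_deme_size(self):
        """Smaller demes put more genome mass into long (>=2.5 cM) HBD
        tracts; rank test over replicates."""
        from scipy.stats import spearmanr

        sizes = [25, 100, 400]
        ns, fs = [], []
        for rep in range(7):
            for N in sizes:
                _, gmap, hbd = simulate_inbred_individual(
                    N, 10, 1e-3, seed=100 + rep, n_chrom=2, chrom_length=10e6
                )
                df = hbd.with_lengths_cm(gmap)
                ns.append(N)
                fs.append(df[df["length_cM"] >= 2.5]["length_cM"].sum() / 20.0)
        rho, p = spearmanr(ns, fs)
        assert rho < 0 and p < 0.01
        by_size = {N: np.mean([f for n, f in zip(ns, fs) if n == N]) for N in sizes}
        assert by_size[25] > by_size[400]

    def test_high_migration_approaches_panmixia(self):
        """m = 0.1 with N*d = 20,000 behaves like one large population."""
        _, _, hbd = simulate_inbred_individual(
            2000, 10, 0.1, seed=3, n_chrom=2, chrom_length=10e6
        )
        assert hbd.total_length() / 2e7 < 0.1

    def test_single_deme_degenerates_to_panmictic(self):
        t, _, hbd = simulate_inbred_individual(
            10_000, 1, 0.0, seed=4, n_chrom=1, chrom_length=5e6
        )
        assert t.n_sites > 0
        assert hbd.total_length() / 5e6 < 0.1

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            inbred_config(1, deme_size=1)
        with pytest.raises(ValueError):
            inbred_config(1, migration=2.0)


class TestErrors:
    def test_sampling_older_than_population_origin(self):
        cfg = panmictic_config(1, n_chrom=1, chrom_length=1e5)
        # island demes are founded 5,000 generations ago; sampling at
        # 6,000 generations inside a deme is impossible
        cfg = inbred_config(1, n_chrom=1, chrom_length=1e5, t_found=1000)
        cfg.samples[0].time = 2000.0
        with pytest.raises(Exception):
            simulate_dataset(cfg)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            panmictic_config(1, mut_rate=-1e-8)
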