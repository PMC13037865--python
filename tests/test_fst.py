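import numpy as np
import pytest

from paleodiff.fst import hudson_fst, pairwise_fst_matrix, subsample_single_genome_fst
from paleodiff.hbd import full_span_track
from paleodiff.simulate import simulate_dataset, split_config
from conftest import build_table


def brute_force_hudson(gA, gB, fA=None, fB=None):
    """Independent per-site loop implementation of the ratio-of-sums
    Hudson estimator with design-effect allele counts."""
    fA = fA or [0.0] * gA.shape[1]
    fB = fB or [0.0] * gB.shape[1]
    neffA = sum(2.0 / (1 + f) for f in fA)
    neffB = sum(2.0 / (1 + f) for f in fB)
    num = den = 0.0
    for i in range(gA.shape[0]):
        a, b = gA[i], gB[i]
        if (a < 0).any() or (b < 0).any():
            continue
        p1 = a.sum() / (2 * len(a))
        p2 = b.sum() / (2 * len(b))
        x = a.sum() + b.sum()
        if x == 0 or x == 2 * (len(a) + len(b)):
            continue
        num += (
            (p1 - p2) ** 2
            - p1 * (1 - p1) / (neffA - 1)
            - p2 * (1 - p2) / (neffB - 1)
        )
        den += p1 * (1 - p2) + p2 * (1 - p1)
    return num / den


class TestSingleSite:
    def test_fixed_difference(self):
        t = build_table({"a": [2], "b": [0]})
        est = hudson_fst(t, ["a"], ["b"])
        assert est.fst == pytest.approx(1.0)
        assert est.num_sum == pytest.approx(1.0)
        assert est.den_sum == pytest.approx(1.0)

    def test_shared_intermediate_frequency_is_negative(self):
        # p1 = p2 = 0.5 with n1 = n2 = 4: N = -1/6, D = 1/2, ratio -1/3
        t = build_table({"a1": [1], "a2": [1], "b1": [1], "b2": [1]})
        est = hudson_fst(t, ["a1", "a2"], ["b1", "b2"])
        assert est.num_sum == pytest.approx(-1 / 6)
        assert est.den_sum == pytest.approx(0.5)
        assert est.fst == pytest.approx(-1 / 3)  # negative, not clamped

    def test_no_informative_sites(self):
        t = build_table({"a": [0, 0], "b": [0, 0]})
        with pytest.raises(ValueError, match="no informative sites"):
            hudson_fst(t, ["a"], ["b"])

    def test_fully_autozygous_rejected(self):
        t = build_table({"a": [2], "b": [0]})
        with pytest.raises(ValueError, match="effective allele count"):
            hudson_fst(t, ["a"], ["b"], autozygosity={"a": 1.0})


class TestBruteForceOracle:
    def test_matches_brute_force_with_missing_and_autozygosity(self):
        rng = np.random.default_rng(0)
        nA, nB, S = 5, 4, 400
        gA = rng.integers(0, 3, size=(S, nA)).astype(np.int8)
        gB = rng.integers(0, 3, size=(S, nB)).astype(np.int8)
        gA[rng.random((S, nA)) < 0.05] = -1
        g = np.hstack([gA, gB])
        t = build_table({f"s{i}": g[:, i] for i in range(nA + nB)})
        A = [f"s{i}" for i in range(nA)]
        B = [f"s{i}" for i in range(nA, nA + nB)]
        f = {s: 0.3 for s in A}
        est = hudson_fst(t, A, B, autozygosity=f)
        expected = brute_force_hudson(gA, gB, fA=[0.3] * nA)
        assert est.fst == pytest.approx(expected, abs=1e-12)


class TestMatrix:
    def test_symmetry_and_zero_diagonal(self):
        rng = np.random.default_rng(1)
        g = rng.integers(0, 3, size=(200, 3)).astype(np.int8)
        t = build_table({f"s{i}": g[:, i] for i in range(3)})
        mat, details = pairwise_fst_matrix(t, ["s0", "s1", "s2"])
        assert np.allclose(mat.to_numpy(), mat.to_numpy().T)
        assert np.allclose(np.diag(mat.to_numpy()), 0.0)
        assert len(details) == 3

    def test_three_population_ordering(self):
        """Recently split pair is less differentiated than either is from
        the outgroup population."""
        cfg = split_config(9, T_split=1000, three_pops=True, T_split2=8000,
                           n_per_pop=4, n_chrom=4, chrom_length=5e6)
        t, gmap, _ = simulate_dataset(cfg)
        A = [s for s in t.samples if s.startswith("A")]
        B = [s for s in t.samples if s.startswith("B")]
        C = [s for s in t.samples if s.startswith("C")]
        ab = hudson_fst(t, A, B).fst
        ac = hudson_fst(t, A, C).fst
        bc = hudson_fst(t, B, C).fst
        assert ab < ac and ab < bc


class TestJackknife:
    def test_ci_brackets_estimate_and_shrinks_with_length(self):
        ses = []
        for n_chrom in (3, 12):
            cfg = split_config(17, T_split=3000, n_per_pop=3,
                               n_chrom=n_chrom, chrom_length=10e6)
            t, gmap, _ = simulate_dataset(cfg)
            A = [s for s in t.samples if s.startswith("A")]
            B = [s for s in t.samples if s.startswith("B")]
            est = hudson_fst(t, A, B, gmap=gmap)
            assert est.ci_low <= est.fst <= est.ci_high
            assert est.n_blocks > 1
            ses.append(est.se)
        # quadrupling the genome should roughly halve the jackknife SE
        assert ses[0] > 1.4 * ses[1]


class TestSubsampling:
    def test_same_population_mean_near_zero(self):
        cfg = split_config(23, T_split=2000, n_per_pop=6, n_chrom=4,
                           chrom_length=5e6)
        t, gmap, _ = simulate_dataset(cfg)
        A = [s for s in t.samples if s.startswith("A")]
        res = subsample_single_genome_fst(t, A[:3], A[3:], 12, seed=5)
        se = res["sd"] / np.sqrt(12)
        assert abs(res["mean"]) < 2 * se + 0.01

    def test_deterministic_given_seed(self):
        t = build_table(
            {f"s{i}": np.random.default_rng(2).integers(0, 3, 50) for i in range(4)}
        )
        r1 = subsample_single_genome_fst(t, ["s0", "s1"], ["s2", "s3"], 5, seed=9)
        r2 = subsample_single_genome_fst(t, ["s0", "s1"], ["s2", "s3"], 5, seed=9)
        assert r1["estimates"] == r2["estimates"]

    def test_rejects_zero_pairs(self):
        t = build_table({"a": [1], "b": [1]})
        with pytest.raises(ValueError):
            subsample_single_genome_fst(t, ["a"], ["b"], 0, seed=1)
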