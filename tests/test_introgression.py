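import itertools

import numpy as np
import pandas as pd
import pytest

from paleodiff.datamodel import GeneticMap, IntervalTrack
from paleodiff.hmm import expected_transitions, forward_backward
from paleodiff.introgression import (
    AncestryHMMParams,
    call_ancestry_segments,
    estimate_introgression_time,
    informative_sites,
    overlap_bootstrap_test,
    segment_tmrca,
)
from conftest import build_table


def brute_force_posteriors(emissions, transitions, init):
    """Path enumeration oracle for forward-backward."""
    n, K = emissions.shape
    homogeneous = np.asarray(transitions).ndim == 2
    post = np.zeros((n, K))
    total = 0.0
    for path in itertools.product(range(K), repeat=n):
        p = init[path[0]] * emissions[0, path[0]]
        for t in range(1, n):
            T = transitions if homogeneous else transitions[t - 1]
            p *= T[path[t - 1], path[t]] * emissions[t, path[t]]
        total += p
        for t, s in enumerate(path):
            post[t, s] += p
    return post / total


class TestForwardBackward:
    def test_matches_path_enumeration(self):
        rng = np.random.default_rng(0)
        n, K = 8, 3
        e = rng.random((n, K)) + 0.05
        T = rng.random((n - 1, K, K)) + 0.1
        T /= T.sum(axis=2, keepdims=True)
        init = np.array([0.5, 0.3, 0.2])
        post, _ = forward_backward(e, T, init)
        expected = brute_force_posteriors(e, T, init)
        np.testing.assert_allclose(post, expected, atol=1e-10)

    def test_homogeneous_two_state(self):
        rng = np.random.default_rng(1)
        e = rng.random((10, 2)) + 0.05
        T = np.array([[0.9, 0.1], [0.3, 0.7]])
        init = np.array([0.6, 0.4])
        post, _ = forward_backward(e, T, init)
        np.testing.assert_allclose(
            post, brute_force_posteriors(e, T, init), atol=1e-10
        )

    def test_posteriors_sum_to_one(self):
        rng = np.random.default_rng(2)
        e = rng.random((500, 3)) + 0.01
        T = rng.random((3, 3)) + 0.1
        T /= T.sum(axis=1, keepdims=True)
        post, _ = forward_backward(e, T, np.full(3, 1 / 3))
        np.testing.assert_allclose(post.sum(axis=1), 1.0, atol=1e-9)

    def test_expected_transitions_match_enumeration(self):
        rng = np.random.default_rng(3)
        n, K = 6, 2
        e = rng.random((n, K)) + 0.05
        T = np.array([[0.8, 0.2], [0.4, 0.6]])
        init = np.array([0.5, 0.5])
        xi = expected_transitions(e, T, init)
        # enumeration
        expected = np.zeros((K, K))
        total = 0.0
        for path in itertools.product(range(K), repeat=n):
            p = init[path[0]] * e[0, path[0]]
            for t in range(1, n):
                p *= T[path[t - 1], path[t]] * e[t, path[t]]
            total += p
            for t in range(n - 1):
                expected[path[t], path[t + 1]] += p
        np.testing.assert_allclose(xi, expected / total, atol=1e-10)


def toy_dataset(target_dosage, n_sites=300, spacing=10_000):
    """Diagnostic-site table: donor homozygous ALT, background homozygous
    REF; the target carries `target_dosage` at every site."""
    t = build_table(
        {
            "target": [target_dosage] * n_sites,
            "donor": [2] * n_sites,
            "bg": [0] * n_sites,
        },
        spacing=spacing,
    )
    gmap = GeneticMap.uniform({"chr1": n_sites * spacing + 1})
    return t, gmap


class TestSegmentCalling:
    def test_target_identical_to_background_gives_nothing(self):
        t, gmap = toy_dataset(0)
        seg = call_ancestry_segments(t, "target", ["donor"], ["bg"], gmap)
        assert len(seg.segments) == 0

    def test_target_identical_to_donor_spans_chromosome(self):
        t, gmap = toy_dataset(2)
        seg = call_ancestry_segments(t, "target", ["donor"], ["bg"], gmap)
        assert len(seg.segments) == 1
        row = seg.segments.iloc[0]
        assert row["length_cM"] > 2.5
        assert row["mean_posterior"] > 0.99

    def test_hom_state_calls_two_copy_runs_only(self):
        t, gmap = toy_dataset(1)  # heterozygous donor ancestry throughout
        any_seg = call_ancestry_segments(t, "target", ["donor"], ["bg"], gmap)
        hom_seg = call_ancestry_segments(
            t, "target", ["donor"], ["bg"], gmap, state="hom"
        )
        assert len(any_seg.segments) == 1
        assert len(hom_seg.segments) == 0

    def test_posterior_marginals_sum_to_one(self):
        t, gmap = toy_dataset(1, n_sites=100)
        seg = call_ancestry_segments(t, "target", ["donor"], ["bg"], gmap)
        p = seg.posteriors[["p0", "p1", "p2"]].to_numpy()
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-9)

    def test_informative_site_definition(self):
        t = build_table(
            {"target": [0, 0, 0, 0], "donor": [1, 2, 0, 0], "bg": [0, 0, 0, 1]}
        )
        mask, alt_diag = informative_sites(t, ["donor"], ["bg"])
        assert list(mask) == [True, True, False, False]
        assert list(alt_diag) == [True, True]

    def test_no_informative_sites_rejected(self):
        t = build_table({"target": [1], "donor": [1], "bg": [1]})
        gmap = GeneticMap.uniform({"chr1": 10_000})
        with pytest.raises(ValueError, match="informative"):
            call_ancestry_segments(t, "target", ["donor"], ["bg"], gmap)


def seg_track(records):
    return IntervalTrack.from_records(records)


class TestOverlapTest:
    def setup_method(self):
        self.gmap = GeneticMap.uniform({"chr1": 10_000_000})
        self.callable = seg_track([("chr1", 0, 10_000_000)])

    def test_self_overlap_is_maximal(self):
        a = seg_track([("chr1", 1_000_000, 2_000_000), ("chr1", 5_000_000, 5_600_000)])
        r = overlap_bootstrap_test(a, a, self.callable, self.gmap,
                                   n_permutations=99, seed=1)
        assert r["observed_cm"] == pytest.approx(1.6)
        assert r["p"] == pytest.approx(1 / 100)

    def test_empty_set_gives_p_one(self):
        a = seg_track([("chr1", 0, 1_000_000)])
        r = overlap_bootstrap_test(a, IntervalTrack.empty(), self.callable,
                                   self.gmap, n_permutations=49, seed=2)
        assert r["observed_cm"] == 0.0
        assert r["p"] == 1.0

    def test_deterministic_given_seed(self):
        a = seg_track([("chr1", 0, 500_000)])
        b = seg_track([("chr1", 400_000, 900_000)])
        r1 = overlap_bootstrap_test(a, b, self.callable, self.gmap, 50, seed=3)
        r2 = overlap_bootstrap_test(a, b, self.callable, self.gmap, 50, seed=3)
        assert r1["p"] == r2["p"]
        np.testing.assert_array_equal(r1["null"], r2["null"])

    def test_oversized_segment_rejected(self):
        a = seg_track([("chr1", 0, 9_999_999)])
        small = seg_track([("chr1", 0, 1_000_000)])
        with pytest.raises(ValueError, match="exceeds"):
            overlap_bootstrap_test(a, a, small, self.gmap, 10, seed=4)


class TestTimeEstimator:
    def test_moment_formula(self):
        # mean length 1.2 cM at cutoff 0.2 -> excess 0.01 Morgans
        # -> 100 generations -> 2,900 years
        seg = pd.DataFrame({"length_cM": [1.2] * 20})
        est = estimate_introgression_time(seg, cutoff_cm=0.2, seed=0)
        assert est.t_generations == pytest.approx(100.0)
        assert est.years == pytest.approx(2900.0)

    def test_ci_brackets_point(self):
        rng = np.random.default_rng(5)
        seg = pd.DataFrame({"length_cM": 0.2 + 100 * rng.exponential(1 / 800, 200)})
        est = estimate_introgression_time(seg, cutoff_cm=0.2, seed=1)
        lo, hi = est.ci_generations
        assert lo <= est.t_generations <= hi
        assert abs(est.t_generations - 800) / 800 < 0.3

    def test_too_few_segments(self):
        seg = pd.DataFrame({"length_cM": [0.5] * 5})
        with pytest.raises(ValueError, match="segments"):
            estimate_introgression_time(seg)

    def test_inconsistent_tail(self):
        seg = pd.DataFrame({"length_cM": [0.2] * 20})
        with pytest.raises(ValueError, match="exponential tail"):
            estimate_introgression_time(seg, cutoff_cm=0.2)


class TestSegmentTmrca:
    def test_zero_divergence_is_introgressed(self):
        t = build_table({"t": [2] * 10, "d": [2] * 10}, spacing=10_000)
        seg = pd.DataFrame([{"chrom": "chr1", "start": 0, "end": 100_000}])
        r = segment_tmrca(t, "t", "d", seg, mu_per_year=5e-10,
                          split_time_years=400_000)
        assert r[0].tmrca_years == 0.0
        assert r[0].classification == "introgressed"

    def test_divergence_arithmetic(self):
        # 40 fixed differences over 100 kb -> d = 4e-4; mu = 5e-10 -> 400 ky
        tt = [2] * 40 + [2] * 10
        dd = [0] * 40 + [2] * 10
        t = build_table({"t": tt, "d": dd}, spacing=2000)
        seg = pd.DataFrame([{"chrom": "chr1", "start": 0, "end": 100_000}])
        r = segment_tmrca(t, "t", "d", seg, mu_per_year=5e-10,
                          split_time_years=10_000_000)
        assert r[0].divergence == pytest.approx(4e-4)
        assert r[0].tmrca_years == pytest.approx(400_000)
        assert r[0].classification == "introgressed"
        # deep split in the other direction
        r2 = segment_tmrca(t, "t", "d", seg, mu_per_year=5e-10,
                           split_time_years=100_000)
        assert r2[0].classification == "ancestral"

    def test_short_segment_uninformative(self):
        t = build_table({"t": [2], "d": [0]})
        seg = pd.DataFrame([{"chrom": "chr1", "start": 0, "end": 10_000}])
        r = segment_tmrca(t, "t", "d", seg, mu_per_year=5e-10,
                          split_time_years=400_000)
        assert r[0].classification == "uninformative"
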