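"""Parameter-recovery benchmark experiments.

Each function simulates data with known ground truth, runs the
corresponding inference end to end, and returns summary metrics. They
back both the acceptance test suite and ``scripts/acceptance.py``; problem
sizes default to desk-scale genomes (tens to hundreds of Mb) chosen so a
full pass stays within minutes per experiment while leaving each property
clearly resolvable.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Tuple

import numpy as np

from .datamodel import IntervalTrack
from .dating import branch_shortening_age
from .dstats import d_statistic
from .fst import hudson_fst, subsample_single_genome_fst
from .hbd import detect_hbd_tracts, full_span_track
from .introgression import (
    AncestryHMMParams,
    call_ancestry_segments,
    estimate_introgression_time,
    overlap_bootstrap_test,
    segment_tmrca,
)
from .metapop import DEFAULT_GRID_N, GenomeSpec, fit_metapop
from .simulate import (
    DEFAULT_BANDS,
    inbred_config,
    introgression_config,
    panmictic_config,
    simulate_dataset,
    split_config,
    trio_config,
)


def _spawn_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.default_rng(seed).integers(1, 2**31 - 1, size=n)


# ---------------------------------------------------------------------------
# F_ST
# ---------------------------------------------------------------------------

def fst_calibration(seed: int, n_reps: int = 20, n_chrom: int = 10) -> Dict:
    """Single-genome Hudson F_ST with and without autozygosity correction
    against the full-cohort estimate, on band-structured populations whose
    single genomes carry f_hbd around 0.2."""
    seeds = _spawn_seeds(seed, n_reps)
    cohort, uncorr, corr, fs = [], [], [], []
    for s in seeds:
        cfg = split_config(
            int(s), T_split=3500, N=10_000, n_per_pop=11,
            substructure=dict(DEFAULT_BANDS), n_chrom=n_chrom,
            chrom_length=10e6,
        )
        table, gmap, _ = simulate_dataset(cfg)
        A = [n for n in table.samples if n.startswith("Ab")]
        B = [n for n in table.samples if n.startswith("Bb")]
        single_a, single_b = A[-1], B[-1]
        mask = full_span_track(gmap)
        f = {
            g: detect_hbd_tracts(table, g, mask, gmap).f_hbd
            for g in (single_a, single_b)
        }
        cohort.append(hudson_fst(table, A[:-1], B[:-1], gmap=gmap).fst)
        uncorr.append(hudson_fst(table, [single_a], [single_b], gmap=gmap).fst)
        corr.append(
            hudson_fst(table, [single_a], [single_b], gmap=gmap, autozygosity=f).fst
        )
        fs.append(np.mean(list(f.values())))
    return {
        "n_reps": n_reps,
        "cohort_mean": float(np.mean(cohort)),
        "uncorrected_mean": float(np.mean(uncorr)),
        "corrected_mean": float(np.mean(corr)),
        "corrected_minus_cohort": float(np.mean(corr) - np.mean(cohort)),
        "uncorrected_minus_cohort": float(np.mean(uncorr) - np.mean(cohort)),
        "frac_uncorrected_above_cohort": float(
            np.mean([u > c for u, c in zip(uncorr, cohort)])
        ),
        "mean_f_hbd": float(np.mean(fs)),
    }


def fst_outbred_subsampling(
    seed: int, n_pairs: int = 50, n_chrom: int = 8, n_per_pop: int = 10
) -> Dict:
    """Single-genome pairs from outbred cohorts reproduce the cohort
    estimate (the modern-human validation design)."""
    cfg = split_config(
        seed, T_split=3500, N=10_000, n_per_pop=n_per_pop,
        n_chrom=n_chrom, chrom_length=10e6,
    )
    table, gmap, _ = simulate_dataset(cfg)
    A = [n for n in table.samples if n.startswith("A")]
    B = [n for n in table.samples if n.startswith("B")]
    coh = hudson_fst(table, A, B, gmap=gmap)
    sub = subsample_single_genome_fst(table, A, B, n_pairs, seed=seed + 1, gmap=gmap)
    se = float(np.sqrt(coh.se**2 + (sub["sd"] / np.sqrt(n_pairs)) ** 2))
    return {
        "cohort_fst": coh.fst,
        "cohort_ci": [coh.ci_low, coh.ci_high],
        "pair_mean": sub["mean"],
        "pair_sd": sub["sd"],
        "n_pairs": n_pairs,
        "combined_se": se,
        "abs_deviation": abs(sub["mean"] - coh.fst),
    }


def hudson_brute_force_check(seed: int, n_chrom: int = 2) -> Dict:
    """Vectorized Hudson sums against an explicit per-site loop."""
    cfg = split_config(seed, T_split=2000, n_per_pop=50, n_chrom=n_chrom,
                       chrom_length=5e6)
    table, _, _ = simulate_dataset(cfg)
    A = [n for n in table.samples if n.startswith("A")]
    B = [n for n in table.samples if n.startswith("B")]
    est = hudson_fst(table, A, B)

    gA = table.gt[:, [table.sample_index(s) for s in A]]
    gB = table.gt[:, [table.sample_index(s) for s in B]]
    num = den = 0.0
    nA, nB = 2 * len(A), 2 * len(B)
    for i in range(table.n_sites):
        a, b = gA[i], gB[i]
        if (a < 0).any() or (b < 0).any():
            continue
        x = int(a.sum() + b.sum())
        if x == 0 or x == nA + nB:
            continue
        p1 = a.sum() / nA
        p2 = b.sum() / nB
        num += (p1 - p2) ** 2 - p1 * (1 - p1) / (nA - 1) - p2 * (1 - p2) / (nB - 1)
        den += p1 * (1 - p2) + p2 * (1 - p1)
    return {
        "fst": est.fst,
        "brute_force": num / den,
        "abs_diff": abs(est.fst - num / den),
        "n_sites": est.n_sites,
    }


# ---------------------------------------------------------------------------
# HBD
# ---------------------------------------------------------------------------

def hbd_recovery(seed: int, n_reps: int = 20, n_chrom: int = 30) -> Dict:
    """Truth-tract recovery and f_hbd calibration on inbred island-model
    genomes (deme size 25, 10 demes, migration 1e-3)."""
    seeds = _spawn_seeds(seed, n_reps)
    n_truth = n_found = 0
    errs = []
    for s in seeds:
        cfg = inbred_config(int(s), deme_size=25, n_demes=10, migration=1e-3,
                            n_chrom=n_chrom, chrom_length=10e6)
        table, gmap, truth = simulate_dataset(cfg)
        name = cfg.sample_names()[0]
        tracks = detect_hbd_tracts(table, name, full_span_track(gmap), gmap)
        tdf = truth.hbd[name].with_lengths_cm(gmap)
        tdf = tdf[tdf["length_cM"] >= 2.5]
        det = tracks.reported()
        for _, tr in tdf.iterrows():
            d = det[det["chrom"] == tr["chrom"]]
            hit = (
                (abs(d["start_cM"] - tr["start_cM"]) < 0.5)
                & (abs(d["end_cM"] - tr["end_cM"]) < 0.5)
            ).any()
            n_found += bool(hit)
        n_truth += len(tdf)
        errs.append(tracks.f_hbd - tdf["length_cM"].sum() / (n_chrom * 10.0))
    return {
        "n_reps": n_reps,
        "n_truth_tracts": n_truth,
        "recovery_rate": n_found / max(n_truth, 1),
        "mean_f_error": float(np.mean(errs)),
    }


# ---------------------------------------------------------------------------
# metapopulation
# ---------------------------------------------------------------------------

def metapop_recovery(
    seed: int,
    n_obs: int = 10,
    R: int = 6,
    n_chrom: int = 15,
    truth_N: float = 25,
    migration: float = 1e-3,
) -> Dict:
    """Deme-size recovery at known migration, plus the panmictic control."""
    gs = GenomeSpec(n_chrom=n_chrom, chrom_length=10e6)
    grid = [(N, 10, migration) for N in DEFAULT_GRID_N]
    seeds = _spawn_seeds(seed, n_obs + 1)
    expected: Dict = {}
    step_ok = 0
    mles = []
    grid_N = sorted(N for N, _, _ in grid)
    i_truth = grid_N.index(truth_N)
    neighbors = set(grid_N[max(0, i_truth - 1) : i_truth + 2])
    for s in seeds[:-1]:
        cfg = inbred_config(int(s), deme_size=truth_N, n_demes=10,
                            migration=migration, n_chrom=n_chrom,
                            chrom_length=10e6)
        cfg.hbd_truth_samples = []
        table, gmap, _ = simulate_dataset(cfg)
        obs = detect_hbd_tracts(table, cfg.sample_names()[0],
                                full_span_track(gmap), gmap)
        fit = fit_metapop(obs, grid=grid, genome_spec=gs, R=R, seed=seed,
                          expected=expected)
        expected = fit.expected_bins
        mles.append(fit.mle_N)
        step_ok += fit.mle_N in neighbors
    # panmictic control: grid free in (N, m)
    cfg = panmictic_config(int(seeds[-1]), N=10_000, n_diploid=1,
                           n_chrom=n_chrom, chrom_length=10e6)
    table, gmap, _ = simulate_dataset(cfg)
    obs = detect_hbd_tracts(table, "POP_0", full_span_track(gmap), gmap)
    pan_grid = [(N, 10, m) for N in DEFAULT_GRID_N for m in (1e-3, 1e-2, 1e-1)]
    pan = fit_metapop(obs, grid=pan_grid, genome_spec=gs, R=max(3, R - 2),
                      seed=seed + 1, expected=expected)
    return {
        "n_obs": n_obs,
        "mle_N": mles,
        "recovery_rate": step_ok / n_obs,
        "panmictic_mle_N": pan.mle_N,
        "panmictic_small_group": bool(pan.small_group),
    }


# ---------------------------------------------------------------------------
# introgression
# ---------------------------------------------------------------------------

def introgression_segment_recovery(
    seed: int, n_reps: int = 20, n_chrom: int = 10
) -> Dict:
    """HMM segment calling against census truth (>= 0.2 cM class)."""
    seeds = _spawn_seeds(seed, n_reps)
    rec, fp = [], []
    for s in seeds:
        cfg = introgression_config(int(s), n_chrom=n_chrom, chrom_length=10e6)
        table, gmap, truth = simulate_dataset(cfg)
        tr = truth.introgressed["TARGET_0"]
        tdf = tr.with_lengths_cm(gmap)
        big = tdf[tdf["length_cM"] >= 0.2]
        if len(big) == 0:
            continue
        trbig = IntervalTrack(big[["chrom", "start", "end"]].copy())
        seg = call_ancestry_segments(table, "TARGET_0", ["DONOR_0"], ["SIB_0"], gmap)
        det = seg.track()
        rec.append(det.intersect(trbig).total_length() / trbig.total_length())
        fp.append(
            (det.total_length() - det.intersect(tr).total_length())
            / max(det.total_length(), 1)
        )
    return {
        "n_reps": len(rec),
        "recovered_cm_fraction": float(np.mean(rec)),
        "false_positive_cm_fraction": float(np.mean(fp)),
    }


def introgression_dating(
    seed: int,
    n_reps: int = 20,
    n_chrom: int = 16,
    t_pulse: float = 1000.0,
    age_gap: float = 276.0,
) -> Dict:
    """Admixture-time recovery from segment lengths, plus the two-sample
    ordering: a genome sampled ``age_gap`` generations earlier must show a
    shorter time since the shared pulse."""
    seeds = _spawn_seeds(seed, n_reps)
    pooled: List[float] = []
    per_rep = []
    wins = comps = 0
    # one decoding pass per genome at the finer 0.1 cM floor; the
    # conservative 0.2 cM cutoff is applied inside the estimator
    fine = AncestryHMMParams(min_cm=0.1)
    for s in seeds:
        cfg = introgression_config(
            int(s), t_pulse=t_pulse, N_target=10_000, N_donor=2_000,
            n_chrom=n_chrom, chrom_length=10e6,
            target_times=[0.0, age_gap],
        )
        table, gmap, _ = simulate_dataset(cfg)
        segs = {
            name: call_ancestry_segments(
                table, name, ["DONOR_0"], ["SIB_0"], gmap, fine
            ).segments
            for name in ("TARGET_0", "TARGET_1")
        }
        pooled.extend(
            segs["TARGET_0"][segs["TARGET_0"]["length_cM"] >= 0.2]["length_cM"]
        )
        try:
            per_rep.append(
                estimate_introgression_time(segs["TARGET_0"], cutoff_cm=0.2,
                                            seed=int(s), min_segments=5
                                            ).t_generations
            )
        except ValueError:
            pass
        # ordering at the finer cutoff (more segments, sharper comparison)
        ests = []
        for name in ("TARGET_0", "TARGET_1"):
            try:
                ests.append(
                    estimate_introgression_time(
                        segs[name], cutoff_cm=0.1, seed=int(s), min_segments=5
                    ).t_generations
                )
            except ValueError:
                ests.append(None)
        if None not in ests:
            comps += 1
            wins += ests[1] < ests[0]
    import pandas as pd

    pooled_est = estimate_introgression_time(
        pd.DataFrame({"length_cM": pooled}), seed=seed
    )
    return {
        "n_reps": n_reps,
        "truth_generations": t_pulse,
        "pooled_t_generations": pooled_est.t_generations,
        "pooled_relative_error": abs(pooled_est.t_generations - t_pulse) / t_pulse,
        "mean_t_generations": float(np.mean(per_rep)) if per_rep else float("nan"),
        "ordering_fraction": wins / comps if comps else float("nan"),
        "n_order_comparisons": comps,
    }


def tmrca_classification(
    seed: int,
    n_reps: int = 20,
    n_chrom: int = 8,
    generation_time: float = 29.0,
) -> Dict:
    """Introgressed vs incomplete-lineage-sorting classification of
    homozygous segments by TMRCA against the population split."""
    seeds = _spawn_seeds(seed, n_reps)
    T_split = 14_000.0
    mu_year = 1.25e-8 / generation_time
    split_years = T_split * generation_time
    intro_total = intro_ok = ils_total = ils_bad = 0
    for s in seeds:
        cfg = introgression_config(
            int(s), T_split=T_split, t_pulse=1500.0, N_donor=1_000,
            n_chrom=n_chrom, chrom_length=10e6,
        )
        table, gmap, truth = simulate_dataset(cfg)
        hom = truth.introgressed_hom["TARGET_0"].df
        hom = hom[(hom["end"] - hom["start"]) >= 50_000]
        rng = np.random.default_rng(int(s))
        # ILS controls: 100 kb windows clear of any introgressed ancestry
        any_tr = truth.introgressed["TARGET_0"]
        controls = []
        for _ in range(3 * n_chrom):
            chrom = f"chr{rng.integers(1, n_chrom + 1)}"
            start = int(rng.integers(0, int(10e6 - 100_000)))
            iv = IntervalTrack.from_records([(chrom, start, start + 100_000)])
            if iv.intersect(any_tr).total_length() == 0:
                controls.append((chrom, start, start + 100_000))
            if len(controls) >= 5:
                break
        import pandas as pd

        for frame, is_intro in (
            (hom, True),
            (pd.DataFrame(controls, columns=["chrom", "start", "end"]), False),
        ):
            if len(frame) == 0:
                continue
            res = segment_tmrca(
                table, "TARGET_0", "DONOR_0", frame,
                mu_per_year=mu_year, split_time_years=split_years,
            )
            for r in res:
                if r.classification == "uninformative":
                    continue
                if is_intro:
                    intro_total += 1
                    intro_ok += r.classification == "introgressed"
                else:
                    ils_total += 1
                    ils_bad += r.classification == "introgressed"
    return {
        "n_introgressed": intro_total,
        "frac_introgressed_correct": intro_ok / max(intro_total, 1),
        "n_ils": ils_total,
        "frac_ils_misclassified": ils_bad / max(ils_total, 1),
    }


def overlap_null_uniformity(
    seed: int, n_pairs: int = 200, n_permutations: int = 99
) -> Dict:
    """p-values of the overlap test on independent random segment sets
    should be uniform; Kolmogorov-Smirnov check."""
    from scipy.stats import kstest

    from paleodiff.datamodel import GeneticMap

    gmap = GeneticMap.uniform({"chr1": 25_000_000, "chr2": 25_000_000})
    callable_track = IntervalTrack.from_records(
        [("chr1", 0, 25_000_000), ("chr2", 0, 25_000_000)]
    )
    rng = np.random.default_rng(seed)

    def random_set():
        rows = []
        for chrom in ("chr1", "chr2"):
            placed = []
            for _ in range(5):
                L = int((0.2 + rng.exponential(0.5)) * 1e6)
                for _ in range(100):
                    start = int(rng.integers(0, 25_000_000 - L))
                    if all(start + L <= s or start >= e for s, e in placed):
                        placed.append((start, start + L))
                        rows.append((chrom, start, start + L))
                        break
        return IntervalTrack.from_records(rows)

    pvals = []
    for i in range(n_pairs):
        r = overlap_bootstrap_test(
            random_set(), random_set(), callable_track, gmap,
            n_permutations=n_permutations, seed=int(rng.integers(1, 2**31 - 1)),
        )
        pvals.append(r["p"])
    stat, p = kstest(pvals, "uniform")
    return {"ks_stat": float(stat), "ks_p": float(p), "n_pairs": n_pairs}


# ---------------------------------------------------------------------------
# dating and D-statistics
# ---------------------------------------------------------------------------

def dating_recovery(
    seed: int,
    n_reps: int = 6,
    n_chrom: int = 8,
    age_generations: float = 4000.0,
    generation_time: float = 29.0,
) -> Dict:
    """Branch-shortening recovery of a known sampling age, plus the
    present-day-genome null."""
    seeds = _spawn_seeds(seed, n_reps)
    truth_ky = age_generations * generation_time / 1e3
    mu_tv = (2.0 / 3.0) * 1.25e-8 / generation_time
    ages, sds, zeros, zero_sds = [], [], [], []
    for s in seeds:
        cfg = panmictic_config(
            int(s), N=10_000, sample_times=[0.0, 0.0, age_generations],
            n_chrom=n_chrom, chrom_length=10e6,
        )
        table, gmap, _ = simulate_dataset(cfg)
        mask = full_span_track(gmap)
        est = branch_shortening_age(table, "POP_2", "POP_0", mask=mask,
                                    mu_tv_per_year=mu_tv)
        ages.append(est.raw_age_ky)
        sds.append(est.sd_ky)
        est0 = branch_shortening_age(table, "POP_1", "POP_0", mask=mask,
                                     mu_tv_per_year=mu_tv)
        zeros.append(est0.raw_age_ky)
        zero_sds.append(est0.sd_ky)
    n = len(ages)
    sd_mean = max(float(np.mean(sds)), float(np.std(ages, ddof=1))) / np.sqrt(n)
    sd0_mean = max(float(np.mean(zero_sds)), float(np.std(zeros, ddof=1))) / np.sqrt(n)
    return {
        "truth_ky": truth_ky,
        "mean_age_ky": float(np.mean(ages)),
        "sd_of_mean_ky": sd_mean,
        "z_vs_truth": (float(np.mean(ages)) - truth_ky) / sd_mean,
        "present_day_mean_ky": float(np.mean(zeros)),
        "present_day_sd_of_mean_ky": sd0_mean,
        "present_day_z": float(np.mean(zeros)) / sd0_mean,
        "n_reps": n,
    }


def dstat_calibration(
    seed: int, n_sym: int = 20, n_asym: int = 3, n_chrom: int = 6
) -> Dict:
    """Symmetric trios should rarely reach |Z| >= 3; an asymmetric topology
    always should, with the sign pointing at the true sister pair."""
    seeds = _spawn_seeds(seed, n_sym + n_asym)
    sym_z = []
    for s in seeds[:n_sym]:
        cfg = trio_config(int(s), topology="symmetric", n_chrom=n_chrom,
                          chrom_length=10e6)
        table, gmap, _ = simulate_dataset(cfg)
        r = d_statistic(table, "P1_0", "P2_0", "P3_0", "OUT_0", gmap=gmap)
        sym_z.append(r.z)
    asym = []
    for s in seeds[n_sym:]:
        cfg = trio_config(int(s), topology="asymmetric", n_chrom=n_chrom,
                          chrom_length=10e6)
        table, gmap, _ = simulate_dataset(cfg)
        r = d_statistic(table, "P1_0", "P2_0", "P3_0", "OUT_0", gmap=gmap)
        asym.append((r.d, r.z))
    return {
        "sym_abs_z": [abs(z) for z in sym_z],
        "frac_sym_below_3": float(np.mean([abs(z) < 3 for z in sym_z])),
        "asym_d": [d for d, _ in asym],
        "asym_z": [z for _, z in asym],
        "asym_all_significant": bool(all(abs(z) >= 3 for _, z in asym)),
        "asym_all_positive": bool(all(d > 0 for d, _ in asym)),
    }
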