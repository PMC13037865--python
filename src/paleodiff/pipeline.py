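"""End-to-end pipeline driver with a reproducibility manifest.

Runs the full analysis flow on either a bundled synthetic scenario or
user-supplied inputs: simulate -> heterozygosity/HBD -> F_ST matrix ->
D-statistics / F(A|B) -> branch-shortening dating -> introgression
(call, overlap, date, TMRCA). Each stage writes a JSON summary; the
manifest records the config snapshot, the seed every stochastic stage
consumed, input checksums and per-stage outputs, so a rerun with the same
manifest reproduces identical outputs for deterministic stages.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np

from . import io as pio
from .datamodel import GeneticMap, IntervalTrack, SiteTable
from .dating import branch_shortening_age
from .dstats import d_statistic, f_a_given_b
from .fst import hudson_fst, pairwise_fst_matrix
from .hbd import compute_heterozygosity, detect_hbd_tracts, full_span_track, summarize_hbd
from .introgression import (
    AncestryHMMParams,
    call_ancestry_segments,
    estimate_introgression_time,
    overlap_bootstrap_test,
    segment_tmrca,
)
from .simulate import introgression_config, simulate_dataset

ALL_STAGES = ("simulate", "het_hbd", "fst", "dstats", "dating", "introgression")


def default_config(seed: int = 1) -> Dict:
    """Demo configuration: two Neandertal-like target genomes (one ancient),
    an unadmixed sister genome, a Denisovan-like donor and an outgroup,
    with a 5% donor pulse 1,500 generations ago."""
    return {
        "seed": seed,
        "scenario": {
            "t_pulse": 1500.0,
            "fraction": 0.05,
            "target_times": [0.0, 300.0],
            "n_chrom": 6,
            "chrom_length": 10e6,
        },
        "generation_time": 29.0,
        "mu_per_year": 1.25e-8 / 29.0,
        "split_time_years": 14000 * 29.0,
        "overlap_permutations": 200,
    }


def run_pipeline(
    config: Dict,
    out_dir,
    stages: Optional[Sequence[str]] = None,
) -> Dict:
    """Execute the pipeline and return the run manifest.

    ``stages`` restricts execution; earlier stages are then loaded from the
    files a previous run left in ``out_dir``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages = list(stages) if stages is not None else list(ALL_STAGES)
    unknown = set(stages) - set(ALL_STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    seed = int(config.get("seed", 1))
    manifest: Dict = {
        "config": config,
        "seeds": {"simulate": seed, "overlap": seed + 1},
        "stages_run": stages,
        "outputs": {},
        "checksums": {},
    }

    current = "simulate"
    try:
        # -- stage: simulate (or load) ----------------------------------
        if "simulate" in stages:
            sc = config["scenario"]
            cfg = introgression_config(
                seed,
                t_pulse=sc.get("t_pulse", 1500.0),
                fraction=sc.get("fraction", 0.05),
                target_times=sc.get("target_times", [0.0]),
                n_chrom=int(sc.get("n_chrom", 6)),
                chrom_length=float(sc.get("chrom_length", 10e6)),
            )
            table, gmap, truth = simulate_dataset(cfg)
            pio.write_vcf(table, out / "sites.vcf")
            pio.write_genetic_map(gmap, out / "genetic_map.tsv")
            for name, track in truth.introgressed.items():
                pio.write_bed(track, out / f"truth_introgressed_{name}.bed")
            _register(manifest, "simulate", out, ["sites.vcf", "genetic_map.tsv"])
        else:
            table = pio.read_genotypes(out / "sites.vcf")
            gmap = pio.read_genetic_map(out / "genetic_map.tsv")

        mask = full_span_track(gmap)
        targets = [s for s in table.samples if s.startswith("TARGET")]
        sib = [s for s in table.samples if s.startswith("SIB")]
        donor = [s for s in table.samples if s.startswith("DONOR")]
        outg = [s for s in table.samples if s.startswith("OUT")]

        # -- stage: heterozygosity and HBD ------------------------------
        current = "het_hbd"
        if "het_hbd" in stages:
            het_summary = {}
            autozygosity = {}
            for s in table.samples:
                tracks = detect_hbd_tracts(table, s, mask, gmap)
                est = compute_heterozygosity(table, s, mask, exclude=tracks)
                summ = summarize_hbd(tracks)
                autozygosity[s] = summ["f_hbd"]
                het_summary[s] = {
                    "het_per_10kb": est.rate_per_10kb,
                    "het_per_10kb_excl_hbd": est.rate_per_10kb_excl,
                    **summ,
                }
                pio.write_bed(tracks.track(), out / f"hbd_{s}.bed")
            _write_json(out / "het_hbd.json", het_summary)
            _register(manifest, "het_hbd", out, ["het_hbd.json"])
        else:
            het_summary = json.loads((out / "het_hbd.json").read_text())
            autozygosity = {s: v["f_hbd"] for s, v in het_summary.items()}

        # -- stage: F_ST -------------------------------------------------
        current = "fst"
        if "fst" in stages:
            samples = targets + sib
            mat, details = pairwise_fst_matrix(
                table, samples, autozygosity=autozygosity, gmap=gmap
            )
            fst_out = {
                "samples": samples,
                "matrix": mat.to_numpy().tolist(),
                "cells": {
                    f"{a}|{b}": {"fst": e.fst, "ci": [e.ci_low, e.ci_high]}
                    for (a, b), e in details.items()
                },
            }
            _write_json(out / "fst.json", fst_out)
            _register(manifest, "fst", out, ["fst.json"])

        # -- stage: D-statistics and F(A|B) ------------------------------
        current = "dstats"
        if "dstats" in stages and len(targets) >= 2:
            d = d_statistic(table, targets[0], sib[0], targets[1], outg[0], gmap=gmap)
            share = f_a_given_b(table, targets[0], [targets[1], sib[0]])
            _write_json(
                out / "dstats.json",
                {
                    "D(ind1,ind2;ind3,out)": {
                        "ind1": targets[0], "ind2": sib[0],
                        "ind3": targets[1], "outgroup": outg[0],
                        "D": d.d, "Z": d.z, "abba": d.abba, "baba": d.baba,
                        "significant": d.significant,
                    },
                    "F(A|B)": {
                        "A": targets[0],
                        "B": share.description,
                        "fraction": share.fraction,
                        "n_sites": share.n_conditioning,
                    },
                },
            )
            _register(manifest, "dstats", out, ["dstats.json"])

        # -- stage: branch-shortening dating -----------------------------
        current = "dating"
        if "dating" in stages and len(targets) >= 2:
            gen_time = float(config.get("generation_time", 29.0))
            mu_tv = (2.0 / 3.0) * 1.25e-8 / gen_time
            age = branch_shortening_age(
                table, targets[1], sib[0], mask=mask, mu_tv_per_year=mu_tv
            )
            _write_json(
                out / "dating.json",
                {
                    "ancient": targets[1],
                    "modern_ref": sib[0],
                    "age_ky": age.age_ky,
                    "sd_ky": age.sd_ky,
                    "interval_ky": list(age.interval_ky),
                },
            )
            _register(manifest, "dating", out, ["dating.json"])

        # -- stage: introgression ----------------------------------------
        current = "introgression"
        if "introgression" in stages:
            gen_time = float(config.get("generation_time", 29.0))
            seg_sets = {}
            for s in targets:
                seg = call_ancestry_segments(table, s, donor, sib, gmap)
                seg_sets[s] = seg
                pio.write_bed(seg.track(), out / f"segments_{s}.bed")
            summary: Dict = {
                "n_segments": {s: int(len(v.segments)) for s, v in seg_sets.items()}
            }
            if len(targets) >= 2:
                ov = overlap_bootstrap_test(
                    seg_sets[targets[0]].track(),
                    seg_sets[targets[1]].track(),
                    mask,
                    gmap,
                    n_permutations=int(config.get("overlap_permutations", 200)),
                    seed=manifest["seeds"]["overlap"],
                )
                summary["overlap"] = {
                    "observed_cm": ov["observed_cm"],
                    "null_mean_cm": ov["null_mean_cm"],
                    "p": ov["p"],
                }
            for s in targets:
                try:
                    t_est = estimate_introgression_time(
                        seg_sets[s].segments,
                        generation_time=gen_time,
                        seed=seed + 2,
                        min_segments=5,
                    )
                    summary.setdefault("time_since_admixture", {})[s] = {
                        "generations": t_est.t_generations,
                        "years": t_est.years,
                        "ci_generations": list(t_est.ci_generations),
                    }
                except ValueError as exc:
                    summary.setdefault("time_since_admixture", {})[s] = str(exc)
            hom = call_ancestry_segments(
                table, targets[0], donor, sib, gmap, state="hom"
            )
            tm = segment_tmrca(
                table,
                targets[0],
                donor[0],
                hom.segments,
                mu_per_year=float(config.get("mu_per_year", 1.25e-8 / 29.0)),
                split_time_years=float(config.get("split_time_years", 14000 * 29.0)),
            )
            summary["tmrca"] = [
                {
                    "chrom": t.chrom, "start": t.start, "end": t.end,
                    "tmrca_years": t.tmrca_years, "class": t.classification,
                }
                for t in tm
            ]
            _write_json(out / "introgression.json", summary)
            _register(
                manifest,
                "introgression",
                out,
                ["introgression.json"] + [f"segments_{s}.bed" for s in targets],
            )
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {current!r} failed: {exc}") from exc

    _write_json(out / "manifest.json", manifest)
    return manifest


def _register(manifest: Dict, stage: str, out: Path, files: List[str]) -> None:
    manifest["outputs"][stage] = files
    for f in files:
        manifest["checksums"][f] = _sha256(out / f)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=2, default=_json_default) + "\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
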