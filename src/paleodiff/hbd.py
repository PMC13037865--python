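"""Heterozygosity and homozygosity-by-descent (HBD) tract detection.

An individual born to related parents carries long chromosomal stretches
where its two haplotypes descend from a recent common ancestor and are
therefore devoid of heterozygous sites except for genotyping error and very
recent mutation. The genome fraction in such tracts (autozygosity, f) and
the tract-length distribution carry information about recent group size and
isolation.

Detection uses a two-state HMM over heterozygous-site counts in fixed
genetic-distance windows (default 0.05 cM): window counts are Poisson with
mean proportional to the callable bases in the window, at per-bp rate
theta_out outside tracts and eps * theta_out inside. theta_out is refined
by a short EM loop so that highly autozygous genomes (where the naive
genome-wide rate is badly biased downward) are still decoded correctly.
Tract lengths are measured on the genetic map; the reporting cutoff is
2.5 cM with a 10 cM class boundary, the convention used for comparing
archaic and modern genomes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np
import pandas as pd

from .datamodel import GeneticMap, IntervalTrack
from .hmm import forward_backward

DEFAULT_MIN_CM = 2.5
DEFAULT_CLASS_BREAK_CM = 10.0


@dataclass
class HetEstimate:
    """Genome-wide heterozygosity, optionally recomputed excluding HBD."""

    n_het: int
    callable_bp: int
    rate_per_10kb: float
    n_het_excl: Optional[int] = None
    callable_bp_excl: Optional[int] = None
    rate_per_10kb_excl: Optional[float] = None


@dataclass
class HBDParams:
    window_cm: float = 0.05
    eps: float = 0.1               # residual het rate inside HBD, x theta_out
    posterior_threshold: float = 0.9
    mean_tract_cm: float = 5.0     # transition prior: mean HBD tract length
    mean_gap_cm: float = 50.0      # transition prior: mean non-HBD stretch
    min_cm: float = DEFAULT_MIN_CM
    em_iterations: int = 3


@dataclass
class HBDTrackSet:
    """Detected HBD tracts for one individual.

    ``tracts`` holds every decoded tract (chrom, start, end, start_cM,
    end_cM, length_cM, mean_posterior); summaries apply the >= min_cm
    reporting cutoff.
    """

    sample: str
    tracts: pd.DataFrame
    callable_cm: float
    min_cm: float = DEFAULT_MIN_CM

    def reported(self) -> pd.DataFrame:
        return self.tracts[self.tracts["length_cM"] >= self.min_cm]

    @property
    def f_hbd(self) -> float:
        if self.callable_cm <= 0:
            return 0.0
        return float(self.reported()["length_cM"].sum() / self.callable_cm)

    def track(self, reported_only: bool = True) -> IntervalTrack:
        df = self.reported() if reported_only else self.tracts
        if len(df) == 0:
            return IntervalTrack.empty()
        return IntervalTrack(df[["chrom", "start", "end"]].copy())


def full_span_track(gmap: GeneticMap) -> IntervalTrack:
    """Callability track covering the full mapped range of every chromosome."""
    rows = []
    for c in gmap.chromosomes:
        bp, _ = gmap._get(c)
        rows.append((c, int(bp[0]), int(bp[-1])))
    return IntervalTrack.from_records(rows)


def compute_heterozygosity(
    sites,
    sample: str,
    mask: IntervalTrack,
    exclude: Optional[HBDTrackSet] = None,
) -> HetEstimate:
    """Heterozygous sites per 10,000 callable bases inside ``mask``.

    With ``exclude``, the rate is also recomputed after subtracting the
    reported HBD tracts from both numerator and denominator.
    """
    if len(mask) == 0:
        raise ValueError("callability mask is empty")
    callable_bp = mask.total_length()
    if callable_bp == 0:
        raise ValueError("zero callable bases in mask")
    j = sites.sample_index(sample)
    het = sites.gt[:, j] == 1
    inside = mask.contains(sites.chrom, sites.pos - 1)
    n_het = int((het & inside & sites.callable_site).sum())
    est = HetEstimate(n_het, callable_bp, 1e4 * n_het / callable_bp)

    if exclude is not None:
        kept = mask.subtract(exclude.track())
        bp_excl = kept.total_length()
        in_kept = kept.contains(sites.chrom, sites.pos - 1)
        n_excl = int((het & in_kept & sites.callable_site).sum())
        est.n_het_excl = n_excl
        est.callable_bp_excl = bp_excl
        est.rate_per_10kb_excl = 1e4 * n_excl / bp_excl if bp_excl else 0.0
    return est


def detect_hbd_tracts(
    sites,
    sample: str,
    mask: IntervalTrack,
    gmap: GeneticMap,
    params: Optional[HBDParams] = None,
) -> HBDTrackSet:
    """Decode HBD tracts for one diploid sample.

    Chromosomes absent from the genetic map are skipped. Returns every
    decoded tract; length-class summaries apply the reporting cutoff.
    """
    import warnings

    p = params or HBDParams()
    j = sites.sample_index(sample)
    mask = mask.merged()

    inside_mask = mask.contains(sites.chrom, sites.pos - 1)
    het_all = (sites.gt[:, j] == 1) & inside_mask & sites.callable_site

    rows = []
    chrom_data = []
    for chrom in sites.chromosomes:
        if chrom not in gmap.chromosomes:
            warnings.warn(f"no genetic map for {chrom}; skipped")
            continue
        c0, c1 = gmap.span_cm(chrom)
        n_win = max(1, int(np.ceil((c1 - c0) / p.window_cm)))
        edges_cm = c0 + np.arange(n_win + 1) * p.window_cm
        edges_cm[-1] = c1
        edges_bp = gmap.interpolate_bp(chrom, edges_cm)

        sel = (sites.chrom == chrom) & het_all
        het_pos = sites.pos[sel] - 1
        counts = np.histogram(het_pos, bins=edges_bp)[0]

        callable_w = _callable_per_window(mask, chrom, edges_bp)
        chrom_data.append((chrom, edges_cm, edges_bp, counts, callable_w))

    if not chrom_data:
        return HBDTrackSet(sample, _empty_tracts(), 0.0, p.min_cm)

    # Initial outside-HBD rate from the top decile of per-window het rates:
    # robust when most of the genome is autozygous, where the genome-wide
    # mean rate would be biased far downward. EM then refines it.
    win_rates = np.concatenate(
        [
            counts[callable_w > 0] / callable_w[callable_w > 0]
            for _, _, _, counts, callable_w in chrom_data
        ]
    )
    theta0 = 0.0
    if len(win_rates) and win_rates.sum() > 0:
        top = np.sort(win_rates)[-max(1, len(win_rates) // 10):]
        theta0 = float(top.mean())

    theta = theta0
    for _ in range(max(1, p.em_iterations)):
        posts = [
            _decode_chrom(counts, callable_w, theta, p)
            for _, _, _, counts, callable_w in chrom_data
        ]
        if theta0 == 0:
            break
        # re-estimate theta_out from windows weighted by P(outside)
        num = sum(
            float((po[:, 0] * c).sum()) for po, (_, _, _, c, _) in zip(posts, chrom_data)
        )
        den = sum(
            float((po[:, 0] * w).sum()) for po, (_, _, _, _, w) in zip(posts, chrom_data)
        )
        theta = num / den if den > 0 else theta0

    callable_cm = 0.0
    for (chrom, edges_cm, edges_bp, counts, callable_w), post in zip(chrom_data, posts):
        frac = np.divide(
            callable_w,
            np.diff(edges_bp),
            out=np.zeros_like(callable_w, dtype=float),
            where=np.diff(edges_bp) > 0,
        )
        callable_cm += float((np.diff(edges_cm) * frac).sum())
        hbd_win = post[:, 1] >= p.posterior_threshold
        for s_i, e_i in _runs(hbd_win):
            start_bp, end_bp = int(edges_bp[s_i]), int(edges_bp[e_i])
            if end_bp <= start_bp:
                continue
            rows.append(
                {
                    "chrom": chrom,
                    "start": start_bp,
                    "end": end_bp,
                    "start_cM": float(edges_cm[s_i]),
                    "end_cM": float(edges_cm[e_i]),
                    "length_cM": float(edges_cm[e_i] - edges_cm[s_i]),
                    "mean_posterior": float(post[s_i:e_i, 1].mean()),
                }
            )

    tracts = pd.DataFrame(rows) if rows else _empty_tracts()
    return HBDTrackSet(sample, tracts, callable_cm, p.min_cm)


def summarize_hbd(
    tracks: HBDTrackSet,
    callable_cm: Optional[float] = None,
    class_break_cm: float = DEFAULT_CLASS_BREAK_CM,
) -> Dict[str, float]:
    """f_hbd and length-class masses as fractions of the callable genome.

    Classes: [min_cm, class_break) and [class_break, inf) cM; the two masses
    sum to f_hbd by construction.
    """
    cm = callable_cm if callable_cm is not None else tracks.callable_cm
    if cm <= 0:
        raise ValueError("callable genetic length must be positive")
    rep = tracks.reported()
    lo = rep[rep["length_cM"] < class_break_cm]["length_cM"].sum()
    hi = rep[rep["length_cM"] >= class_break_cm]["length_cM"].sum()
    return {
        "f_hbd": float((lo + hi) / cm),
        "mass_small": float(lo / cm),
        "mass_large": float(hi / cm),
        "n_tracts": int(len(rep)),
    }


# ---------------------------------------------------------------------------

def _decode_chrom(counts, callable_w, theta, p: HBDParams):
    n = len(counts)
    if theta <= 0:
        post = np.zeros((n, 2))
        post[:, 1] = 1.0  # no heterozygosity anywhere: everything HBD
        return post
    lam_out = np.maximum(theta * callable_w, 1e-12)
    lam_in = np.maximum(p.eps * theta * callable_w, 1e-12)
    # Poisson emission ratios; constant factors cancel row-wise
    k = counts.astype(float)
    log_e = np.stack(
        [k * np.log(lam_out) - lam_out, k * np.log(lam_in) - lam_in], axis=1
    )
    log_e -= log_e.max(axis=1, keepdims=True)
    e = np.exp(log_e)
    uninformative = callable_w <= 0
    e[uninformative] = 1.0

    a = 1.0 - np.exp(-p.window_cm / p.mean_gap_cm)
    b = 1.0 - np.exp(-p.window_cm / p.mean_tract_cm)
    T = np.array([[1 - a, a], [b, 1 - b]])
    init = np.array([b, a]) / (a + b)
    post, _ = forward_backward(e, T, init)
    return post


def _callable_per_window(mask: IntervalTrack, chrom: str, edges_bp: np.ndarray):
    iv = mask.df[mask.df["chrom"] == chrom][["start", "end"]].to_numpy()
    out = np.zeros(len(edges_bp) - 1)
    if len(iv) == 0:
        return out
    for s, e in iv:
        lo = np.clip(edges_bp[:-1], s, e)
        hi = np.clip(edges_bp[1:], s, e)
        out += np.maximum(hi - lo, 0)
    return out


def _runs(flags: np.ndarray):
    """(start, end) index pairs of True runs; end is exclusive."""
    if len(flags) == 0:
        return
    d = np.diff(flags.astype(int))
    starts = list(np.where(d == 1)[0] + 1)
    ends = list(np.where(d == -1)[0] + 1)
    if flags[0]:
        starts = [0] + starts
    if flags[-1]:
        ends = ends + [len(flags)]
    yield from zip(starts, ends)


def _empty_tracts() -> pd.DataFrame:
    return pd.DataFrame(
        columns=[
            "chrom",
            "start",
            "end",
            "start_cM",
            "end_cM",
            "length_cM",
            "mean_posterior",
        ]
    )
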